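import warnings

import numpy as np
import pandas as pd
import pytest

from ctdynamics.synthetic import SimulationConfig, simulate_cohort


def make_variant_row(patient_id="P1", timepoint="C1D1", gene="KRAS",
                     variant_class="SNV", chrom="synth1", pos=100,
                     ref="C", alt="T", vaf=0.1, protein_change=None):
    return dict(patient_id=patient_id, timepoint=timepoint, gene=gene,
                variant_class=variant_class, chrom=chrom, pos=pos,
                ref=ref, alt=alt, vaf=vaf, protein_change=protein_change)


def variant_frame(rows):
    from ctdynamics.io import VARIANT_COLUMNS
    if not rows:
        return pd.DataFrame(columns=VARIANT_COLUMNS)
    return pd.DataFrame([make_variant_row(**r) for r in rows])


@pytest.fixture(scope="session")
def small_cohort():
    """One moderate simulated cohort shared across read-only tests."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_cohort(SimulationConfig(seed=7, n_patients_per_arm=30))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
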