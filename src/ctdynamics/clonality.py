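"""Clonality of alterations at end of treatment.

maxVAF — the highest variant allele frequency among all VAF-bearing somatic
alterations in a sample — serves as a tumor-fraction proxy.  The clonality
of an alteration is its EoT VAF divided by the sample maxVAF; alterations
with ratio <= 0.3 are called subclonal.  maxVAF is computed inclusively
(the alteration being normalised participates), so exactly one alteration
per sample attains ratio 1 unless tied.  Amplifications and fusions carry
no VAF and are excluded.

A sample with no VAF-bearing calls has no detectable ctDNA and is reported
as undetected (None), which is distinct from a maxVAF of zero.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "SUBCLONAL_THRESHOLD",
    "compute_max_vaf",
    "compute_clonality",
    "compare_clonality",
]

SUBCLONAL_THRESHOLD = 0.3


def compute_max_vaf(calls: pd.DataFrame) -> float | None:
    """Maximum VAF over the sample's VAF-bearing somatic alterations.

    Returns None (undetected) when no call carries a VAF — e.g. an
    amplification-only sample — mirroring the exclusion of patients with
    no ctDNA detected.
    """
    vafs = pd.to_numeric(calls["vaf"], errors="coerce").dropna()
    if vafs.empty:
        return None
    return float(vafs.max())


def compute_clonality(status_records: pd.DataFrame,
                      eot_calls: pd.DataFrame,
                      threshold: float = SUBCLONAL_THRESHOLD) -> pd.DataFrame:
    """Per-alteration EoT VAF / maxVAF ratios with subclonal flags.

    Parameters
    ----------
    status_records
        One patient's alteration-status records (acquired/maintained/lost).
        Lost alterations have no EoT VAF and are skipped.
    eot_calls
        The same patient's EoT variant table, defining the sample maxVAF.

    Returns
    -------
    DataFrame with ``patient_id, gene, variant_class, status, eot_vaf,
    max_vaf, ratio, subclonal``; the flag is inclusive at the threshold.
    """
    max_vaf = compute_max_vaf(eot_calls)
    if max_vaf is None:
        raise ValidationError("EoT sample has no detectable ctDNA (no VAFs)")
    if max_vaf <= 0:
        raise ValidationError("EoT maxVAF is zero")
    rows = []
    for _, rec in status_records.iterrows():
        eot_vaf = rec["eot_vaf"]
        if pd.isna(eot_vaf):
            continue  # lost alterations and VAF-less classes have no ratio
        ratio = float(eot_vaf) / max_vaf
        rows.append({
            "patient_id": rec["patient_id"],
            "gene": rec["gene"],
            "variant_class": rec["variant_class"],
            "status": rec["status"],
            "eot_vaf": float(eot_vaf),
            "max_vaf": max_vaf,
            "ratio": ratio,
            "subclonal": ratio <= threshold,
        })
    return pd.DataFrame(rows, columns=["patient_id", "gene", "variant_class",
                                       "status", "eot_vaf", "max_vaf",
                                       "ratio", "subclonal"])


def compute_clonality_cohort(status_records: pd.DataFrame,
                             variants: pd.DataFrame,
                             threshold: float = SUBCLONAL_THRESHOLD) -> pd.DataFrame:
    """Clonality records for every patient with a detectable EoT sample."""
    eot = variants[variants["timepoint"] == "EoT"]
    parts = []
    for pid, recs in status_records.groupby("patient_id", sort=True):
        calls = eot[eot["patient_id"] == pid]
        if compute_max_vaf(calls) is None:
            continue
        parts.append(compute_clonality(recs, calls, threshold=threshold))
    if not parts:
        return pd.DataFrame(columns=["patient_id", "gene", "variant_class",
                                     "status", "eot_vaf", "max_vaf",
                                     "ratio", "subclonal"])
    return pd.concat(parts, ignore_index=True)


def compare_clonality(acquired, maintained, exact_max_n: int = 20) -> dict:
    """Two-sided Wilcoxon rank-sum comparison of clonality ratios.

    Uses exact enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie correction.
    """
    acquired = [float(x) for x in acquired]
    maintained = [float(x) for x in maintained]
    if not acquired or not maintained:
        raise ValidationError("both groups must be nonempty")
    combined = acquired + maintained
    no_ties = len(set(combined)) == len(combined)
    if len(combined) <= exact_max_n and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(acquired, maintained, alternative="two-sided",
                             method=method)
    return {
        "n_acquired": len(acquired),
        "n_maintained": len(maintained),
        "statistic_u": float(res.statistic),
        "p_value": float(res.pvalue),
        "method": method,
        "median_acquired": float(pd.Series(acquired).median()),
        "median_maintained": float(pd.Series(maintained).median()),
    }
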