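import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from ctdynamics.dynamics import (aggregate_gene_class_status_cohort,
                                 aggregate_gene_status, association_2x2,
                                 classify_alteration_status, classify_cohort,
                                 count_multi_acquired, detection_concordance,
                                 round_percent, summarize_acquisition_frequency)
from ctdynamics.io import ValidationError
from conftest import variant_frame


def _random_paired_tables(rng, n_keys=10):
    """Random paired call sets over a small key universe; returns the frames
    plus the membership sets that define the expected partition."""
    universe = [("G%d" % i, "SNV", "c1", 10 + i, "C", "T") for i in range(n_keys)]
    base_keys = {k for k in universe if rng.random() < 0.5}
    eot_keys = {k for k in universe if rng.random() < 0.5}

    def rows(keys, timepoint):
        return [dict(patient_id="P1", timepoint=timepoint, gene=g,
                     variant_class=vc, chrom=ch, pos=pos, ref=r, alt=a,
                     vaf=round(rng.uniform(0.001, 0.5), 6))
                for (g, vc, ch, pos, r, a) in sorted(keys)]

    c1d1 = variant_frame(rows(base_keys, "C1D1"))
    eot = variant_frame(rows(eot_keys, "EoT"))
    return c1d1, eot, base_keys, eot_keys


class TestClassification:
    def test_eot_only_is_acquired_and_both_is_maintained(self):
        c1d1 = variant_frame([dict(gene="BRAF", pos=5, vaf=0.20)])
        eot = variant_frame([
            dict(gene="BRAF", pos=5, vaf=0.01, timepoint="EoT"),
            dict(gene="KRAS", pos=9, vaf=0.02, timepoint="EoT"),
        ])
        out = classify_alteration_status(c1d1, eot).set_index("gene")
        # presence-based: a large VAF drop does not demote 'maintained'
        assert out.loc["BRAF", "status"] == "maintained"
        assert out.loc["KRAS", "status"] == "acquired"

    def test_c1d1_only_is_lost(self):
        c1d1 = variant_frame([dict(gene="APC", pos=3, vaf=0.1)])
        out = classify_alteration_status(c1d1, variant_frame([]))
        assert list(out["status"]) == ["lost"]

    def test_mixed_patients_rejected(self):
        c1d1 = variant_frame([dict(patient_id="P1")])
        eot = variant_frame([dict(patient_id="P2", timepoint="EoT")])
        with pytest.raises(ValidationError, match="mixed patients"):
            classify_alteration_status(c1d1, eot)

    def test_duplicate_key_within_timepoint_rejected(self):
        c1d1 = variant_frame([dict(vaf=0.1), dict(vaf=0.2)])
        with pytest.raises(ValidationError, match="duplicate"):
            classify_alteration_status(c1d1, variant_frame([]))

    def test_matches_set_algebra_oracle_on_random_pairs(self):
        """Statuses equal plain set operations: acquired = EoT \\ C1D1,
        maintained = intersection, lost = C1D1 \\ EoT; statuses partition
        the key union."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            c1d1, eot, base_keys, eot_keys = _random_paired_tables(rng)
            out = classify_alteration_status(c1d1, eot)
            got = {(r.gene, r.variant_class, r.chrom, r.pos, r.ref, r.alt):
                   r.status for r in out.itertuples()}
            expected = {}
            for k in base_keys | eot_keys:
                if k in base_keys and k in eot_keys:
                    expected[k] = "maintained"
                elif k in eot_keys:
                    expected[k] = "acquired"
                else:
                    expected[k] = "lost"
            assert got == expected
            counts = out["status"].value_counts()
            assert counts.sum() == len(base_keys | eot_keys)


class TestGenePrecedence:
    @pytest.mark.parametrize("statuses,expected", [
        (["maintained"], "maintained"),
        (["acquired"], "acquired"),
        (["lost"], "lost"),
        (["maintained", "acquired"], "maintained"),
        (["maintained", "lost"], "maintained"),
        (["acquired", "lost"], "acquired"),
        (["maintained", "acquired", "lost"], "maintained"),
    ])
    def test_all_nonempty_status_combinations(self, statuses, expected):
        records = pd.DataFrame([
            dict(patient_id="P1", gene="KRAS", variant_class="SNV",
                 chrom="c1", pos=i, ref="C", alt="T", status=s,
                 c1d1_vaf=0.1, eot_vaf=0.1)
            for i, s in enumerate(statuses)])
        out = aggregate_gene_status(records)
        assert out.loc[0, "gene_status"] == expected

    def test_invariant_to_record_order(self):
        records = pd.DataFrame([
            dict(patient_id="P1", gene="KRAS", variant_class="SNV",
                 chrom="c1", pos=i, ref="C", alt="T", status=s,
                 c1d1_vaf=0.1, eot_vaf=0.1)
            for i, s in enumerate(["lost", "acquired", "maintained"])])
        fwd = aggregate_gene_status(records)
        rev = aggregate_gene_status(records.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(fwd, rev)


    def test_class_level_rollup_keeps_fusion_distinct(self):
        """A maintained SNV must not swallow an acquired fusion in the
        same gene at (gene, class) resolution."""
        records = pd.DataFrame([
            dict(patient_id="P1", gene="BRAF", variant_class="SNV",
                 chrom="c1", pos=1, ref="C", alt="T", status="maintained",
                 c1d1_vaf=0.2, eot_vaf=0.2),
            dict(patient_id="P1", gene="BRAF", variant_class="fusion",
                 chrom=None, pos=None, ref=None, alt=None,
                 status="acquired", c1d1_vaf=None, eot_vaf=None),
        ])
        gene_level = aggregate_gene_status(records)
        assert list(gene_level["gene_status"]) == ["maintained"]
        class_level = aggregate_gene_class_status_cohort(records)
        by = class_level.set_index("variant_class")["gene_status"]
        assert by["SNV"] == "maintained"
        assert by["fusion"] == "acquired"


class TestFrequencies:
    @pytest.mark.parametrize("count,denom,expected", [
        (22, 112, 19.6),
        (0, 112, 0.0),
        (13, 318, 4.1),
        (476, 503, 94.6),
        (368, 404, 91.1),
    ])
    def test_round_percent_reproduces_printed_values(self, count, denom, expected):
        assert round_percent(count, denom) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValidationError):
            round_percent(1, 0)

    def test_summary_from_gene_records(self):
        gene_records = pd.DataFrame(
            [dict(patient_id=f"P{i}", gene="MET", gene_status="acquired",
                  n_maintained=0, n_acquired=1, n_lost=0) for i in range(22)])
        out = summarize_acquisition_frequency(gene_records, ["MET"],
                                              denominator=112)
        assert out.loc[0, "count"] == 22
        assert out.loc[0, "percent"] == 19.6

    def test_baseline_carriers_removed_from_denominator(self):
        recs = pd.DataFrame([
            dict(patient_id="P1", gene="MET", gene_status="maintained",
                 n_maintained=1, n_acquired=0, n_lost=0),
            dict(patient_id="P2", gene="MET", gene_status="acquired",
                 n_maintained=0, n_acquired=1, n_lost=0),
            dict(patient_id="P3", gene="TP53", gene_status="lost",
                 n_maintained=0, n_acquired=0, n_lost=1),
        ])
        out = summarize_acquisition_frequency(
            recs, ["MET"], denominator=3, exclude_baseline_carriers=True)
        assert out.loc[0, "denominator"] == 2
        assert out.loc[0, "percent"] == 50.0


class TestMultiAcquired:
    def test_counting_rule(self):
        gene_records = pd.DataFrame([
            dict(patient_id="P1", gene="KRAS", gene_status="acquired"),
            dict(patient_id="P1", gene="MET", gene_status="acquired"),
            dict(patient_id="P2", gene="KRAS", gene_status="acquired"),
        ])
        patients = pd.DataFrame([
            dict(patient_id="P1", arm="triplet"),
            dict(patient_id="P2", arm="triplet"),
            dict(patient_id="P3", arm="triplet"),
        ])
        out = count_multi_acquired(gene_records, patients)
        assert out.loc[0, "count"] == 1          # only P1 has >= 2
        assert out.loc[0, "denominator"] == 3    # P3 counts in denominator

    def test_matches_poisson_tail_closed_form(self):
        """With per-patient acquired gene counts ~ Poisson(lam), the
        fraction with >= 2 is 1 - e^-lam (1 + lam) within 3 SE."""
        rng = np.random.default_rng(1)
        lam, n = 1.3, 4000
        counts = rng.poisson(lam, size=n)
        rows, pats = [], []
        for i, k in enumerate(counts):
            pid = f"P{i}"
            pats.append(dict(patient_id=pid, arm="triplet"))
            rows += [dict(patient_id=pid, gene=f"G{j}", gene_status="acquired")
                     for j in range(k)]
        out = count_multi_acquired(pd.DataFrame(rows), pd.DataFrame(pats))
        expected = 1 - math.exp(-lam) * (1 + lam)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(out.loc[0, "fraction"] - expected) <= 3 * se


class TestConcordance:
    def test_printed_value(self):
        a = {f"P{i}": i < 380 for i in range(404)}
        b = {f"P{i}": i < 368 for i in range(404)}
        out = detection_concordance(a, b)
        assert out["detected_both"] == 368
        assert out["percent_both"] == 91.1

    def test_identity_mappings(self):
        a = {f"P{i}": i % 3 != 0 for i in range(30)}
        out = detection_concordance(a, dict(a))
        assert out["percent_both"] == out["percent_a"] == out["percent_b"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValidationError):
            detection_concordance({"P1": True}, {"P2": True})


def _fisher_oracle(a, b, c, d):
    """Two-sided Fisher exact p by exact rational hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return float(total)


class TestAssociation2x2:
    def _mappings(self, a, b, c, d):
        exposure, outcome = {}, {}
        i = 0
        for (e, o), count in zip([(1, 1), (1, 0), (0, 1), (0, 0)],
                                 [a, b, c, d]):
            for _ in range(count):
                exposure[f"P{i}"], outcome[f"P{i}"] = e, o
                i += 1
        return exposure, outcome

    def test_closed_form_cross_ratio(self):
        out = association_2x2(*self._mappings(10, 90, 2, 198))
        assert out["odds_ratio"] == pytest.approx(11.0)
        assert not out["haldane_corrected"]

    def test_symmetric_table(self):
        out = association_2x2(*self._mappings(5, 5, 5, 5))
        assert out["odds_ratio"] == pytest.approx(1.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_zero_cell_haldane_correction(self):
        out = association_2x2(*self._mappings(0, 10, 5, 5))
        assert out["haldane_corrected"]
        assert out["odds_ratio"] == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_degenerate_margin_gives_nan_or(self):
        out = association_2x2(*self._mappings(0, 0, 5, 5))
        assert math.isnan(out["odds_ratio"])

    def test_fisher_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            total = int(rng.integers(4, 31))
            cuts = sorted(rng.integers(0, total + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = total - a - b - c
            out = association_2x2(*self._mappings(a, b, c, d))
            assert out["p_value"] == pytest.approx(
                _fisher_oracle(a, b, c, d), abs=1e-12)


def test_cohort_classification_partition_property(small_cohort):
    """Every distinct key per patient gets exactly one status."""
    status = classify_cohort(small_cohort.variants)
    keys = status[["patient_id", "gene", "variant_class",
                   "chrom", "pos", "ref", "alt"]]
    assert not keys.duplicated().any()
    assert set(status["status"]) <= {"acquired", "maintained", "lost"}
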