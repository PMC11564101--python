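import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ctdynamics.enrichment import bh_adjust, preranked_gsea, rank_genes_by_model
from ctdynamics.io import ValidationError


def _dense_es_oracle(stats_sorted, hit_mask, weight_p):
    """Straightforward dense running-sum ES, computed position by position."""
    n = len(stats_sorted)
    n_miss = n - hit_mask.sum()
    w = np.abs(stats_sorted) ** weight_p
    denom = (w * hit_mask).sum()
    running, best = 0.0, 0.0
    for i in range(n):
        if hit_mask[i]:
            running += w[i] / denom
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestEnrichmentScore:
    def _ranks(self):
        genes = [f"G{i}" for i in range(8)]
        return pd.Series([4.0, 3.0, 2.0, 1.0, -1.0, -2.0, -3.0, -4.0],
                         index=genes)

    def test_toy_es_equals_dense_oracle(self):
        ranks = self._ranks()
        out = preranked_gsea(ranks, {"S": ["G1", "G2"]}, n_perm=100,
                             seed=0, min_size=2)
        hit = np.isin(ranks.index.to_numpy(), ["G1", "G2"])
        expected = _dense_es_oracle(ranks.to_numpy(), hit, 1.0)
        assert out.loc[0, "es"] == pytest.approx(expected, abs=1e-12)

    def test_unweighted_singleton_ranked_first_gives_es_one(self):
        ranks = self._ranks()
        out = preranked_gsea(ranks, {"S": ["G0"]}, n_perm=100, seed=0,
                             weight_p=0.0, min_size=1)
        assert out.loc[0, "es"] == pytest.approx(1.0)

    def test_es_sign_flips_under_negated_ranking(self):
        ranks = self._ranks()
        sets = {"S": ["G0", "G1", "G2"]}
        out_pos = preranked_gsea(ranks, sets, n_perm=100, seed=0, min_size=2)
        out_neg = preranked_gsea(-ranks, sets, n_perm=100, seed=0, min_size=2)
        assert out_pos.loc[0, "es"] == pytest.approx(-out_neg.loc[0, "es"],
                                                     abs=1e-12)

    def test_random_oracle_agreement(self, rng):
        """Sparse ES computation equals the dense oracle on random sets."""
        genes = [f"G{i}" for i in range(60)]
        vals = rng.normal(size=60)
        ranks = pd.Series(vals, index=genes)
        ordered = ranks.sort_index().sort_values(ascending=False,
                                                 kind="stable")
        for _ in range(25):
            members = list(rng.choice(genes, size=8, replace=False))
            out = preranked_gsea(ranks, {"S": members}, n_perm=50, seed=1,
                                 min_size=2)
            hit = np.isin(ordered.index.to_numpy(), members)
            expected = _dense_es_oracle(ordered.to_numpy(), hit, 1.0)
            assert out.loc[0, "es"] == pytest.approx(expected, abs=1e-12)

    def test_leading_edge_subset_of_geneset(self, rng):
        genes = [f"G{i}" for i in range(50)]
        ranks = pd.Series(rng.normal(size=50), index=genes)
        members = list(rng.choice(genes, size=10, replace=False))
        out = preranked_gsea(ranks, {"S": members}, n_perm=200, seed=0)
        assert set(out.loc[0, "leading_edge"]) <= set(members)
        assert len(out.loc[0, "leading_edge"]) >= 1

    def test_null_pvalues_approximately_uniform(self, rng):
        """Random genesets against a random ranking give ~uniform p."""
        genes = [f"G{i}" for i in range(150)]
        ranks = pd.Series(rng.normal(size=150), index=genes)
        pvals = []
        for k in range(200):
            members = list(rng.choice(genes, size=10, replace=False))
            out = preranked_gsea(ranks, {"S": members}, n_perm=400,
                                 seed=k)
            pvals.append(out.loc[0, "p_value"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_es_matches_gseapy_cross_check(self, rng):
        """Independent cross-check of the enrichment score against
        gseapy's preranked implementation."""
        import gseapy
        genes = [f"G{i}" for i in range(40)]
        ranks = pd.Series(np.sort(rng.normal(size=40))[::-1], index=genes)
        sets = {f"S{k}": list(rng.choice(genes, size=6, replace=False))
                for k in range(3)}
        ours = preranked_gsea(ranks, sets, n_perm=50, seed=0, min_size=2)
        rnk_df = ranks.reset_index()
        rnk_df.columns = ["gene", "stat"]
        theirs = gseapy.prerank(rnk=rnk_df, gene_sets=sets,
                                permutation_num=10, min_size=2, max_size=50,
                                seed=0, outdir=None, no_plot=True,
                                weight=1.0).res2d.set_index("Term")
        for name in sets:
            mine = float(ours.set_index("geneset").loc[name, "es"])
            assert mine == pytest.approx(float(theirs.loc[name, "ES"]),
                                         abs=1e-6)

    def test_duplicate_genes_rejected(self):
        ranks = pd.Series([1.0, 2.0], index=["A", "A"])
        with pytest.raises(ValidationError):
            preranked_gsea(ranks, {"S": ["A"]})


def _bh_oracle(p):
    """Textbook step-up: p_(i) * m / i with right-to-left monotonicity."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestBhAdjust:
    def test_equally_spaced_collapse(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert out == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_textbook_oracle_on_random_vectors(self, rng):
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(_bh_oracle(p), abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_bounded_and_order_consistent(self, rng):
        p = rng.uniform(size=30)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0 + 1e-12).all()


class TestGeneRanking:
    def _cohort(self, rng, n=120, n_noise=8):
        hazard_cov = rng.normal(size=n)
        t = rng.exponential(1.0 / (0.08 * np.exp(0.9 * hazard_cov)))
        c = rng.exponential(60.0, size=n)
        patients = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(n)],
            "arm": "triplet",
            "time_on_treatment_months": 4.0,
            "os_months": np.minimum(t, c),
            "os_event": (t <= c).astype(int),
            "pfs_months": np.minimum(t, c),
            "pfs_event": (t <= c).astype(int),
        })
        genes = {"HAZARD": hazard_cov}
        for j in range(n_noise):
            genes[f"NOISE{j}"] = rng.normal(size=n)
        matrix = pd.DataFrame(genes).T
        matrix.columns = patients["patient_id"]
        return matrix, patients

    def test_planted_signal_gene_has_largest_z(self, rng):
        matrix, patients = self._cohort(rng)
        z = rank_genes_by_model(matrix, patients)
        assert z.abs().idxmax() == "HAZARD"
        assert z["HAZARD"] > 0

    def test_duplicated_gene_row_gets_identical_z(self, rng):
        matrix, patients = self._cohort(rng, n=80, n_noise=2)
        matrix.loc["HAZARD_COPY"] = matrix.loc["HAZARD"]
        z = rank_genes_by_model(matrix, patients)
        assert z["HAZARD"] == pytest.approx(z["HAZARD_COPY"], rel=1e-9)

    def test_misaligned_sample_ids_rejected(self, rng):
        matrix, patients = self._cohort(rng, n=30, n_noise=1)
        matrix = matrix.rename(columns={"P0": "UNKNOWN"})
        with pytest.raises(ValidationError, match="without metadata"):
            rank_genes_by_model(matrix, patients)

    def test_interaction_mode_flags_differential_gene(self, rng):
        n = 150
        trt = np.repeat([0, 1], n)
        gene = rng.normal(size=2 * n)
        lin = 0.9 * trt * gene
        t = rng.exponential(1.0 / (0.08 * np.exp(lin)))
        patients = pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(2 * n)],
            "arm": np.where(trt == 1, "triplet", "control"),
            "time_on_treatment_months": 4.0,
            "os_months": t, "os_event": 1,
            "pfs_months": t, "pfs_event": 1,
        })
        matrix = pd.DataFrame({"DIFF": gene,
                               "NOISE": rng.normal(size=2 * n)}).T
        matrix.columns = patients["patient_id"]
        z = rank_genes_by_model(matrix, patients, mode="interaction",
                                arms=["control", "triplet"])
        assert abs(z["DIFF"]) > abs(z["NOISE"])
        assert z["DIFF"] > 2.0
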