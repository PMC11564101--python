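"""Gene ranking by survival association and preranked GSEA.

Genes (pre-filtered to the top variance quartile and z-scaled) are ranked
by the signed Wald z of a per-gene Cox model — either a univariable fit
within one arm, or a gene x arm interaction fit across two arms.  The
ranked list feeds a preranked gene-set enrichment analysis: a weighted
Kolmogorov–Smirnov-style running sum whose null is generated by permuting
gene labels, with Benjamini–Hochberg control across genesets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .survival import cox_fit, interaction_test

__all__ = [
    "rank_genes_by_model",
    "preranked_gsea",
    "bh_adjust",
]

logger = logging.getLogger(__name__)


def rank_genes_by_model(matrix: pd.DataFrame,
                        patients: pd.DataFrame,
                        mode: str = "univariable",
                        arms: list[str] | None = None,
                        time_col: str = "os_months",
                        event_col: str = "os_event") -> pd.Series:
    """Signed Cox Wald z per gene, for GSEA ranking.

    Parameters
    ----------
    matrix
        Gene x sample matrix, samples = patient ids, typically z-scaled.
    patients
        Patient table with ``patient_id``, ``arm`` and survival columns.
    mode
        ``univariable`` — per-gene Cox fit within ``arms[0]`` (or all
        patients when ``arms`` is None); ``interaction`` — per-gene
        gene x arm interaction z between exactly two arms,
        ``arms = [reference, comparator]``.

    Genes whose model fails to converge are dropped with a log entry.
    """
    patients = patients.set_index("patient_id", drop=False)
    samples = [s for s in matrix.columns if s in patients.index]
    if not samples:
        raise ValidationError("no overlap between matrix samples and patients")
    if len(samples) < len(matrix.columns):
        missing = set(matrix.columns) - set(samples)
        raise ValidationError(f"samples without metadata: {sorted(missing)[:5]}")
    meta = patients.loc[samples]

    if mode == "univariable":
        if arms:
            mask = meta["arm"].isin(arms).to_numpy()
        else:
            mask = np.ones(len(samples), dtype=bool)
        sub = meta.loc[mask]
        times = sub[time_col].to_numpy(float)
        events = sub[event_col].to_numpy(int)
        if events.sum() < 10:
            logger.warning("fewer than 10 events (%d); z-scores unstable",
                           events.sum())
        cols = sub["patient_id"].tolist()
        zs = {}
        for gene in matrix.index:
            x = matrix.loc[gene, cols].to_numpy(float)
            try:
                res = cox_fit(times, events, pd.DataFrame({"expr": x}))
                zs[gene] = res.z("expr")
            except (ValidationError, Exception):
                logger.info("gene %s dropped (non-convergent fit)", gene)
        return pd.Series(zs, name="z").dropna()

    if mode == "interaction":
        if not arms or len(arms) != 2:
            raise ValidationError("interaction mode needs exactly two arms")
        sub = meta[meta["arm"].isin(arms)]
        times = sub[time_col].to_numpy(float)
        events = sub[event_col].to_numpy(int)
        treatment = (sub["arm"] == arms[1]).to_numpy(float)
        cols = sub["patient_id"].tolist()
        zs = {}
        for gene in matrix.index:
            x = matrix.loc[gene, cols].to_numpy(float)
            try:
                res = interaction_test(times, events, treatment, x)
                zs[gene] = res["z"]
            except (ValidationError, Exception):
                logger.info("gene %s dropped (non-convergent fit)", gene)
        return pd.Series(zs, name="z").dropna()

    raise ValidationError(f"unknown mode {mode!r}")


def _running_es(order_stats: np.ndarray, hit_idx: np.ndarray, n: int,
                weight_p: float) -> tuple[float, int, bool]:
    """Max-deviation ES for hits at sorted positions ``hit_idx``.

    Works sparsely: between hits the running sum decreases linearly, so
    its extrema occur immediately after a hit (candidate maxima) or
    immediately before one (candidate minima).  Returns the signed ES,
    the index *within hit_idx* of the peak hit, and whether the ES is
    positive (leading edge = hits up to the peak) or negative (leading
    edge = hits from the peak on).
    """
    size = hit_idx.size
    n_miss = max(n - size, 1)
    w = np.abs(order_stats[hit_idx]) ** weight_p
    denom = w.sum()
    if denom == 0:  # all-zero stats inside the set: fall back to unweighted
        w = np.ones(size)
        denom = float(size)
    cumw = np.cumsum(w) / denom
    k = np.arange(size)
    miss_before = (hit_idx - k) / n_miss       # misses strictly before hit k
    after = cumw - miss_before                 # running sum just after hit k
    before = np.concatenate(([0.0], cumw[:-1])) - miss_before  # just before
    i_max = int(np.argmax(after))
    i_min = int(np.argmin(before))
    if after[i_max] >= -before[i_min]:
        return float(after[i_max]), i_max, True
    return float(before[i_min]), i_min, False


def preranked_gsea(ranks: pd.Series,
                   genesets: dict[str, list[str]],
                   n_perm: int = 10_000,
                   weight_p: float = 1.0,
                   seed: int | None = 0,
                   min_size: int = 5) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    ``ranks`` maps gene -> signed statistic.  For each geneset the
    enrichment score is the maximum deviation of the running sum over the
    statistic-sorted gene list (hits weighted by |stat|^p, misses by a
    constant); significance comes from ``n_perm`` permutations of gene
    labels, with the +1-smoothed same-sign tail fraction as p and
    NES = ES / mean(|permuted ES| of the same sign).  BH adjustment is
    applied across the tested genesets.
    """
    if ranks.index.duplicated().any():
        raise ValidationError("duplicate genes in ranking")
    if not np.isfinite(ranks.to_numpy(float)).all():
        raise ValidationError("non-finite ranking statistic")
    if n_perm < 100:
        logger.warning("n_perm=%d is small; p-values will be coarse", n_perm)
    # sort descending by statistic, gene symbol as deterministic tiebreak
    ordered = ranks.sort_index().sort_values(ascending=False, kind="stable")
    stats = ordered.to_numpy(float)
    genes = ordered.index.to_numpy()
    gene_pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    for name, members in genesets.items():
        hit_idx = np.array(sorted(gene_pos[g] for g in set(members)
                                  if g in gene_pos), dtype=int)
        size = hit_idx.size
        if size < min_size:
            logger.info("geneset %s skipped (overlap %d < %d)",
                        name, size, min_size)
            continue
        es, peak, positive = _running_es(stats, hit_idx, n, weight_p)

        perm_es = np.empty(n_perm)
        for b in range(n_perm):
            ph = np.sort(rng.choice(n, size=size, replace=False))
            perm_es[b], _, _ = _running_es(stats, ph, weight_p=weight_p, n=n)
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        n_same = int(same_sign.sum())
        more_extreme = int((np.abs(perm_es[same_sign]) >= abs(es)).sum())
        p = (1 + more_extreme) / (1 + n_same) if n_same else 1.0
        mean_same = np.abs(perm_es[same_sign]).mean() if n_same else np.nan
        nes = es / mean_same if mean_same and np.isfinite(mean_same) else np.nan

        if positive:
            leading = [genes[i] for i in hit_idx[:peak + 1]]
        else:
            leading = [genes[i] for i in hit_idx[peak:]]
        rows.append({"geneset": name, "size": size, "es": es, "nes": nes,
                     "p_value": p, "leading_edge": leading})

    df = pd.DataFrame(rows)
    if not df.empty:
        df["p_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return df


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals.copy()
    if ((pvals < 0) | (pvals > 1)).any() or not np.isfinite(pvals).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]
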