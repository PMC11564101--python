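"""Transcriptomic scoring: variance filtering, z-scaling, gene-signature
scores, BM subtyping, single-sample GSEA and median splits.

All inputs are gene x sample matrices of log2(TPM+1).  Geometric-mean
signature scores (cytolytic = GZMA/PRF1; ICR = a 20-gene immune program;
CD8 = CD8A/CD8B) are plain means in log2 space, i.e. geometric means of
TPM+1, reported in log2(TPM) units.  The BM subtype is a weighted sum of
per-gene z-scores over 44 subtyping genes with a fixed 1.5 cutoff: score
> 1.5 -> BM1 (immune/EMT-high), score <= 1.5 -> BM2 (cell-cycle
dysregulated).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "filter_top_iqr",
    "zscore_genes",
    "geometric_signature_score",
    "bm_subtype",
    "ssgsea_score",
    "median_split",
    "BM_THRESHOLD",
]

BM_THRESHOLD = 1.5


def filter_top_iqr(matrix: pd.DataFrame,
                   quartile_fraction: float = 0.25) -> pd.DataFrame:
    """Retain the ceil(fraction * n_genes) genes with largest expression IQR.

    Ties in IQR break by gene-symbol lexicographic order so the retained
    set is deterministic.
    """
    if matrix.shape[0] == 0:
        raise ValidationError("empty expression matrix")
    if not 0 < quartile_fraction <= 1:
        raise ValidationError("quartile_fraction must be in (0, 1]")
    values = matrix.to_numpy(dtype=float)
    q75, q25 = np.percentile(values, [75, 25], axis=1)
    iqr = pd.Series(q75 - q25, index=matrix.index)
    n_keep = math.ceil(quartile_fraction * matrix.shape[0])
    order = sorted(matrix.index, key=lambda g: (-iqr[g], g))
    pos = {g: i for i, g in enumerate(matrix.index)}
    keep = sorted(order[:n_keep], key=pos.__getitem__)
    return matrix.loc[keep]


def zscore_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores (sample sd, ddof=1); zero-sd genes set to 0 with a warning."""
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0) | ~np.isfinite(sd)
    if flat.any():
        genes = list(matrix.index[flat.ravel()])
        warnings.warn(f"constant-expression genes z-scored to 0: {genes[:5]}"
                      + ("..." if len(genes) > 5 else ""), stacklevel=2)
    safe_sd = np.where(flat, 1.0, sd)
    z = (values - mean) / safe_sd
    z[np.broadcast_to(flat, z.shape)] = 0.0
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def geometric_signature_score(matrix: pd.DataFrame,
                              genes: list[str]) -> pd.Series:
    """Per-sample mean log2(TPM+1) over signature genes.

    Equals the log2 geometric mean of (TPM+1); with all genes at equal TPM
    x it returns log2(x+1).  Raises listing any missing genes.
    """
    missing = [g for g in genes if g not in matrix.index]
    if missing:
        raise ValidationError(f"signature genes missing from matrix: {missing}")
    return matrix.loc[list(genes)].mean(axis=0)


def bm_subtype(matrix: pd.DataFrame,
               weights: dict[str, float] | pd.Series,
               threshold: float = BM_THRESHOLD) -> pd.DataFrame:
    """Weighted z-score subtype call per sample.

    ``score = sum_g w_g z_g``; samples with score > threshold are BM1,
    otherwise BM2 (the boundary goes to BM2).  Subtyping genes absent from
    the matrix are imputed as z = 0 with a warning.
    """
    weights = pd.Series(weights, dtype=float)
    if weights.empty:
        raise ValidationError("empty BM weight vector")
    present = [g for g in weights.index if g in matrix.index]
    absent = [g for g in weights.index if g not in matrix.index]
    if absent:
        warnings.warn(f"BM subtyping genes imputed as z=0: {absent}",
                      stacklevel=2)
    if not present:
        raise ValidationError("no BM subtyping genes present in matrix")
    z = zscore_genes(matrix.loc[present])
    score = z.mul(weights[present], axis=0).sum(axis=0)
    return pd.DataFrame({
        "score": score,
        "subtype": np.where(score > threshold, "BM1", "BM2"),
    })


def ssgsea_score(matrix: pd.DataFrame,
                 geneset: list[str],
                 exponent: float = 0.25) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    For each sample, genes are ordered by decreasing expression (ties by
    average rank; equal-ranked genes ordered by symbol for determinism).
    The score is the sum over the ordered list of the difference between
    the rank-weighted in-set ECDF (weights = rank^exponent, ranks from
    ascending expression) and the unweighted out-of-set ECDF.  Being
    purely rank-based, the score is invariant under strictly monotone
    transforms of a sample's expression values.
    """
    members = set(geneset) & set(matrix.index)
    if not members:
        raise ValidationError("geneset has no overlap with expression matrix")
    n = matrix.shape[0]
    n_out = n - len(members)
    in_mask = matrix.index.isin(members)
    scores = {}
    for sample in matrix.columns:
        expr = matrix[sample]
        ranks = expr.rank(method="average", ascending=True).to_numpy()
        # descending expression order, gene symbol as deterministic tiebreak
        order = np.lexsort((matrix.index.to_numpy(), -ranks))
        w = ranks[order] ** exponent
        hit = in_mask[order]
        w_hit = np.where(hit, w, 0.0)
        cum_in = np.cumsum(w_hit) / w_hit.sum()
        if n_out > 0:
            cum_out = np.cumsum(~hit) / n_out
        else:
            cum_out = np.zeros(n)
        scores[sample] = float(np.sum(cum_in - cum_out))
    return pd.Series(scores, name="ssgsea")


def median_split(scores: pd.Series) -> pd.Series:
    """Binary high/low labels at the median; ties at the median go low.

    The median is the midpoint of the order statistics for even n.  If all
    values are identical every sample is labelled low (with a warning).
    """
    scores = pd.Series(scores, dtype=float)
    if len(scores) < 2:
        raise ValidationError("need at least 2 scores for a median split")
    med = float(np.median(scores.to_numpy()))
    if scores.nunique() == 1:
        warnings.warn("all scores identical; every sample labelled low",
                      stacklevel=2)
    return pd.Series(np.where(scores <= med, "low", "high"),
                     index=scores.index, name="group")
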