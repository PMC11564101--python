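"""Paired-timepoint alteration dynamics.

Somatic alterations observed in paired baseline (C1D1) and end-of-treatment
(EoT) liquid-biopsy samples are classified per alteration key as

* ``acquired``   — detected at EoT only,
* ``maintained`` — detected at both timepoints,
* ``lost``       — detected at baseline only.

Detection means presence in the reported call set regardless of VAF (ctDNA
panels report calls down to 0.01% VAF); an optional minimum-VAF presence
threshold is exposed but defaults to 0.  SNVs/indels are identified by exact
(chrom, pos, ref, alt); amplifications and fusions by (gene, class) alone.

Gene-level rollup applies the precedence maintained > acquired > lost, so a
gene carrying both a maintained and an acquired alteration is reported as
maintained.  Downstream summaries reproduce printed count/denominator/percent
triples with 1-decimal half-away-from-zero rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError, validate_variant_table

__all__ = [
    "alteration_key",
    "classify_alteration_status",
    "classify_cohort",
    "aggregate_gene_status",
    "aggregate_gene_status_cohort",
    "round_percent",
    "summarize_acquisition_frequency",
    "count_multi_acquired",
    "detection_concordance",
    "association_2x2",
]

STATUS_ORDER = ("maintained", "acquired", "lost")  # gene-level precedence

STATUS_COLUMNS = [
    "patient_id", "gene", "variant_class", "chrom", "pos", "ref", "alt",
    "status", "c1d1_vaf", "eot_vaf",
]


def alteration_key(row) -> tuple:
    """Identity of an alteration: coordinates for SNV/indel, gene+class else."""
    vclass = row["variant_class"]
    if vclass in ("SNV", "indel"):
        return (row["gene"], vclass, row["chrom"], int(row["pos"]),
                row["ref"], row["alt"])
    return (row["gene"], vclass)


def _calls_by_key(calls: pd.DataFrame, timepoint: str,
                  min_vaf: float) -> dict[tuple, float | None]:
    out: dict[tuple, float | None] = {}
    cols = calls[["gene", "variant_class", "chrom", "pos", "ref", "alt",
                  "vaf", "patient_id"]].itertuples(index=False)
    for gene, vclass, chrom, pos, ref, alt, vaf, pid in cols:
        no_vaf = pd.isna(vaf)
        if not no_vaf and vaf < min_vaf:
            continue
        if vclass in ("SNV", "indel"):
            key = (gene, vclass, chrom, int(pos), ref, alt)
        else:
            key = (gene, vclass)
        if key in out:
            raise ValidationError(
                f"duplicate alteration key {key} at {timepoint} "
                f"for patient {pid}")
        out[key] = None if no_vaf else float(vaf)
    return out


def _classify_validated(c1d1_calls: pd.DataFrame,
                        eot_calls: pd.DataFrame,
                        min_vaf: float) -> pd.DataFrame:
    base = _calls_by_key(c1d1_calls, "C1D1", min_vaf)
    eot = _calls_by_key(eot_calls, "EoT", min_vaf)
    pid = None
    for df in (c1d1_calls, eot_calls):
        if len(df):
            pid = df["patient_id"].iloc[0]
            break
    records = []
    for key in sorted(set(base) | set(eot), key=repr):
        in_b, in_e = key in base, key in eot
        status = "maintained" if (in_b and in_e) else ("acquired" if in_e else "lost")
        records.append({
            "patient_id": pid,
            "gene": key[0],
            "variant_class": key[1],
            "chrom": key[2] if len(key) == 6 else None,
            "pos": key[3] if len(key) == 6 else None,
            "ref": key[4] if len(key) == 6 else None,
            "alt": key[5] if len(key) == 6 else None,
            "status": status,
            "c1d1_vaf": base[key] if in_b else None,
            "eot_vaf": eot[key] if in_e else None,
        })
    df = pd.DataFrame(records, columns=STATUS_COLUMNS)
    df["pos"] = df["pos"].astype("Int64")
    return df


def classify_alteration_status(c1d1_calls: pd.DataFrame,
                               eot_calls: pd.DataFrame,
                               min_vaf: float = 0.0) -> pd.DataFrame:
    """Classify every alteration key seen at either timepoint for one patient.

    Parameters
    ----------
    c1d1_calls, eot_calls
        Variant tables restricted to one patient; timepoint columns must be
        C1D1 and EoT respectively.
    min_vaf
        Optional presence threshold; calls with a VAF below it are treated
        as undetected.  Defaults to 0 (presence = detection).

    Returns
    -------
    DataFrame with one row per alteration key and columns
    ``patient_id, gene, variant_class, chrom, pos, ref, alt, status,
    c1d1_vaf, eot_vaf``.  The statuses partition the key union.
    """
    c1d1_calls = validate_variant_table(c1d1_calls)
    eot_calls = validate_variant_table(eot_calls)
    patients = set(c1d1_calls["patient_id"]) | set(eot_calls["patient_id"])
    if len(patients) > 1:
        raise ValidationError(f"calls from mixed patients: {sorted(patients)}")
    if (c1d1_calls["timepoint"] != "C1D1").any():
        raise ValidationError("c1d1_calls contains non-C1D1 rows")
    if (eot_calls["timepoint"] != "EoT").any():
        raise ValidationError("eot_calls contains non-EoT rows")
    return _classify_validated(c1d1_calls, eot_calls, min_vaf)


def classify_cohort(variants: pd.DataFrame, min_vaf: float = 0.0) -> pd.DataFrame:
    """Classify every patient in a cohort variant table.

    A patient with calls at only one timepoint yields all-lost or
    all-acquired records; pairing decisions (which patients count as
    evaluable) belong to the summary layer.
    """
    variants = validate_variant_table(variants)
    parts = []
    for _pid, sub in variants.groupby("patient_id", sort=True):
        tp = sub["timepoint"].to_numpy()
        parts.append(_classify_validated(
            sub[tp == "C1D1"], sub[tp == "EoT"], min_vaf))
    if not parts:
        return pd.DataFrame(columns=STATUS_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def aggregate_gene_status(records: pd.DataFrame) -> pd.DataFrame:
    """Roll alteration-level statuses up to gene level for one patient.

    Precedence: maintained > acquired > lost.  Returns one row per gene with
    ``gene_status`` and per-status supporting alteration counts.
    """
    patients = set(records["patient_id"])
    if len(patients) > 1:
        raise ValidationError(f"records from mixed patients: {sorted(patients)}")
    rows = []
    for gene, sub in records.groupby("gene", sort=True):
        counts = sub["status"].value_counts()
        for status in STATUS_ORDER:
            if counts.get(status, 0) > 0:
                gene_status = status
                break
        rows.append({
            "patient_id": sub["patient_id"].iloc[0],
            "gene": gene,
            "gene_status": gene_status,
            "n_maintained": int(counts.get("maintained", 0)),
            "n_acquired": int(counts.get("acquired", 0)),
            "n_lost": int(counts.get("lost", 0)),
        })
    return pd.DataFrame(rows, columns=["patient_id", "gene", "gene_status",
                                       "n_maintained", "n_acquired", "n_lost"])


def aggregate_gene_status_cohort(records: pd.DataFrame) -> pd.DataFrame:
    parts = [aggregate_gene_status(sub)
             for _pid, sub in records.groupby("patient_id", sort=True)]
    if not parts:
        return pd.DataFrame(columns=["patient_id", "gene", "gene_status",
                                     "n_maintained", "n_acquired", "n_lost"])
    return pd.concat(parts, ignore_index=True)


def aggregate_gene_class_status_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Per-patient rollup at (gene, variant_class) level.

    Same precedence as the gene-level rollup, but amplifications and
    fusions are not swallowed by a maintained SNV in the same gene —
    needed for class-qualified summaries such as acquired-fusion
    frequencies.
    """
    rows = []
    grouped = records.groupby(["patient_id", "gene", "variant_class"],
                              sort=True)
    for (pid, gene, vclass), sub in grouped:
        counts = sub["status"].value_counts()
        for status in STATUS_ORDER:
            if counts.get(status, 0) > 0:
                rows.append({"patient_id": pid, "gene": gene,
                             "variant_class": vclass, "gene_status": status})
                break
    return pd.DataFrame(rows, columns=["patient_id", "gene",
                                       "variant_class", "gene_status"])


def round_percent(count: int, denominator: int, decimals: int = 1) -> float:
    """100*count/denominator, rounded half away from zero."""
    if denominator < 1:
        raise ValidationError("denominator must be >= 1")
    pct = Decimal(100 * count) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def summarize_acquisition_frequency(
    gene_records: pd.DataFrame,
    gene_set: list[tuple[str, str]] | list[str],
    denominator: int | None = None,
    exclude_baseline_carriers: bool = False,
) -> pd.DataFrame:
    """Per-gene acquisition frequencies over an evaluable denominator.

    Parameters
    ----------
    gene_records
        Cohort gene-status records (output of :func:`aggregate_gene_status_cohort`),
        optionally merged with status-level class info via the ``gene`` column.
    gene_set
        Genes of interest: plain symbols, or (gene, variant_class) pairs
        when ``gene_records`` carries a ``variant_class`` column (output of
        :func:`aggregate_gene_class_status_cohort`).
    denominator
        Evaluable patient count.  If None it defaults to the number of
        distinct patients in ``gene_records``.
    exclude_baseline_carriers
        When True, each gene's denominator excludes patients whose gene
        status is maintained or lost (i.e. who carried the alteration at
        baseline); matching the convention of restricting to patients
        without the baseline alteration.

    Returns
    -------
    DataFrame with columns ``gene, count, denominator, percent``.
    """
    all_patients = gene_records["patient_id"].unique()
    base_denom = denominator if denominator is not None else len(all_patients)
    if base_denom < 1:
        raise ValidationError("denominator must be >= 1")
    rows = []
    for entry in gene_set:
        if isinstance(entry, tuple):
            gene, vclass = entry
            if "variant_class" not in gene_records.columns:
                raise ValidationError(
                    "class-qualified gene_set needs class-level records")
            sub = gene_records[(gene_records["gene"] == gene)
                               & (gene_records["variant_class"] == vclass)]
            label = f"{gene}:{vclass}"
        else:
            gene, label = entry, entry
            sub = gene_records[gene_records["gene"] == gene]
        denom = base_denom
        if exclude_baseline_carriers:
            carriers = sub.loc[sub["gene_status"].isin(["maintained", "lost"]),
                               "patient_id"].nunique()
            denom = base_denom - carriers
        count = int((sub["gene_status"] == "acquired").sum())
        rows.append({"gene": label, "count": count, "denominator": denom,
                     "percent": round_percent(count, denom)})
    return pd.DataFrame(rows)


def count_multi_acquired(gene_records: pd.DataFrame,
                         patients: pd.DataFrame,
                         gene_set: list[str] | None = None,
                         min_acquired: int = 2) -> pd.DataFrame:
    """Per-arm fraction of paired patients with >= ``min_acquired`` acquired genes.

    ``patients`` supplies the arm assignment and defines the per-arm
    denominators (all paired-ctDNA patients, including those with zero
    acquired alterations).
    """
    sub = gene_records[gene_records["gene_status"] == "acquired"]
    if gene_set is not None:
        sub = sub[sub["gene"].isin(gene_set)]
    n_acq = sub.groupby("patient_id").size()
    rows = []
    for arm, parm in patients.groupby("arm", sort=True):
        ids = parm["patient_id"]
        denom = len(ids)
        count = int(sum(n_acq.get(pid, 0) >= min_acquired for pid in ids))
        rows.append({"arm": arm, "count": count, "denominator": denom,
                     "percent": round_percent(count, denom) if denom else np.nan,
                     "fraction": count / denom if denom else np.nan})
    return pd.DataFrame(rows)


def detection_concordance(set_a: dict[str, bool],
                          set_b: dict[str, bool]) -> dict:
    """Detection concordance between two assays over their shared patients.

    Returns counts and 1-decimal percents for detection in assay a, in
    assay b, and in both, each over the shared-population denominator.
    """
    shared = sorted(set(set_a) & set(set_b))
    n = len(shared)
    if n == 0:
        raise ValidationError("no shared patients between assays")
    in_a = sum(bool(set_a[p]) for p in shared)
    in_b = sum(bool(set_b[p]) for p in shared)
    in_both = sum(bool(set_a[p]) and bool(set_b[p]) for p in shared)
    return {
        "n": n,
        "detected_a": in_a, "percent_a": round_percent(in_a, n),
        "detected_b": in_b, "percent_b": round_percent(in_b, n),
        "detected_both": in_both, "percent_both": round_percent(in_both, n),
    }


def association_2x2(exposure: dict[str, int], outcome: dict[str, int]) -> dict:
    """Odds ratio and two-sided Fisher exact p for a 2x2 exposure/outcome table.

    The OR is the sample cross-ratio ad/bc; with exactly one zero cell the
    Haldane–Anscombe 0.5 continuity correction is applied to every cell and
    flagged.  A degenerate margin (an all-zero row or column) yields an
    undefined OR (NaN) with p = 1.
    """
    shared = sorted(set(exposure) & set(outcome))
    a = sum(exposure[p] and outcome[p] for p in shared)          # exp+, out+
    b = sum(exposure[p] and not outcome[p] for p in shared)      # exp+, out-
    c = sum((not exposure[p]) and outcome[p] for p in shared)    # exp-, out+
    d = sum((not exposure[p]) and (not outcome[p]) for p in shared)
    table = np.array([[a, b], [c, d]])
    corrected = False
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        odds = float("nan")
    else:
        n_zero = int((table == 0).sum())
        if n_zero > 0:
            corrected = True
            a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
            odds = (a2 * d2) / (b2 * c2)
        else:
            odds = (a * d) / (b * c)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return {"a": a, "b": b, "c": c, "d": d,
            "odds_ratio": odds, "p_value": float(p),
            "haldane_corrected": corrected}
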