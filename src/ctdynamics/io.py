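"""Readers, writers and validated in-memory containers.

Tabular data (somatic variant calls, patient metadata, expression) travel as
:class:`pandas.DataFrame` objects with enforced schemas; structured reference
data (96-channel substitution signatures, genesets, FASTA contigs) get thin
dedicated containers.  Every reader validates on entry and raises
:class:`ValidationError` naming the offending row/column rather than coercing
silently; every writer/reader pair is an inverse on valid data.

Conventions
-----------
* Variant coordinates are 1-based inclusive (VCF convention).
* VAFs are fractions in [0, 1] internally; percent only at presentation.
* Copy-number amplifications and gene fusions carry no substitution
  coordinates and are keyed by (gene, variant_class) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TIMEPOINTS",
    "VARIANT_CLASSES",
    "ARMS",
    "VARIANT_COLUMNS",
    "PATIENT_COLUMNS",
    "SBS96_CHANNELS",
    "SignatureReference",
    "validate_variant_table",
    "read_variant_table",
    "write_variant_table",
    "validate_patient_table",
    "read_patient_table",
    "write_patient_table",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_signature_reference",
    "write_signature_reference",
    "read_fasta",
    "write_fasta",
]


class ValidationError(ValueError):
    """A file or table violated its schema; message names the location."""


TIMEPOINTS = ("C1D1", "EoT")
VARIANT_CLASSES = ("SNV", "indel", "amplification", "fusion")
ARMS = ("triplet", "doublet", "control")

#: columns of a variant-call table, in canonical order
VARIANT_COLUMNS = [
    "patient_id",
    "timepoint",
    "gene",
    "variant_class",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vaf",
    "protein_change",
]

#: required columns of a patient-metadata table (extra columns = covariates)
PATIENT_COLUMNS = [
    "patient_id",
    "arm",
    "time_on_treatment_months",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
]

_BASES = ("A", "C", "G", "T")
_SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the canonical pyrimidine-centric 96 trinucleotide-substitution channels,
#: ordered substitution-major (C>A ... T>G), then 5' flank, then 3' flank
SBS96_CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in _SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# variant tables
# ---------------------------------------------------------------------------

def validate_variant_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a variant-call table.

    Returns a copy with canonical column order and dtypes (``pos`` as
    nullable Int64, ``vaf`` as float with NaN where absent).
    """
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    out = df.loc[:, VARIANT_COLUMNS].copy()
    out["pos"] = out["pos"].astype("Int64")
    out["vaf"] = pd.to_numeric(out["vaf"], errors="coerce")

    def _fail(mask: pd.Series, message: str):
        if mask.any():
            idx = mask.idxmax()
            pid = out.at[idx, "patient_id"]
            raise ValidationError(f"row {idx} (patient {pid}): {message}")

    _fail(~out["timepoint"].isin(TIMEPOINTS), "unknown timepoint")
    _fail(~out["variant_class"].isin(VARIANT_CLASSES), "unknown variant_class")
    has_vaf = out["vaf"].notna()
    _fail(has_vaf & ~out["vaf"].between(0.0, 1.0), "vaf outside [0, 1]")

    coord = out["variant_class"].isin(("SNV", "indel"))
    _fail(coord & (out["pos"].isna() | (out["pos"] < 1)),
          "SNV/indel requires pos >= 1")
    _fail(coord & (out["chrom"].isna() | (out["chrom"].astype(str) == "")),
          "SNV/indel requires chrom")
    _fail(coord & ~has_vaf, "SNV/indel requires a VAF")
    snv = out["variant_class"] == "SNV"
    if snv.any():
        ref = out.loc[snv, "ref"].astype(str)
        alt = out.loc[snv, "alt"].astype(str)
        bad = ~(ref.isin(_BASES) & alt.isin(_BASES))
        _fail(bad.reindex(out.index, fill_value=False),
              "SNV ref/alt must be single bases")
        _fail((ref == alt).reindex(out.index, fill_value=False),
              "SNV ref == alt")
    return out


def read_variant_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "chrom": str,
                                            "ref": str, "alt": str,
                                            "protein_change": str, "gene": str})
    return validate_variant_table(df)


def write_variant_table(df: pd.DataFrame, path) -> None:
    validate_variant_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# patient metadata
# ---------------------------------------------------------------------------

def validate_patient_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"patient table missing columns: {missing}")
    out = df.copy()
    if out["patient_id"].duplicated().any():
        dup = out.loc[out["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ValidationError(f"duplicate patient_id {dup!r}")
    for idx, row in out.iterrows():
        where = f"row {idx} (patient {row['patient_id']})"
        if row["arm"] not in ARMS:
            raise ValidationError(f"{where}: unknown arm {row['arm']!r}")
        if not row["time_on_treatment_months"] > 0:
            raise ValidationError(f"{where}: time_on_treatment_months must be > 0")
        for col in ("os_months", "pfs_months"):
            if row[col] < 0:
                raise ValidationError(f"{where}: {col} negative")
        for col in ("os_event", "pfs_event"):
            if int(row[col]) not in (0, 1):
                raise ValidationError(f"{where}: {col} not binary")
    return out


def read_patient_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return validate_patient_table(df)


def write_patient_table(df: pd.DataFrame, path) -> None:
    validate_patient_table(df).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def validate_expression_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Genes (rows) x samples (columns), log2(TPM+1), finite, unique genes."""
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValidationError(f"duplicate gene symbol {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    values = df.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        gene = df.index[np.where(~np.isfinite(values))[0][0]]
        raise ValidationError(f"non-finite expression value in gene {gene!r}")
    out = df.astype(float)
    out.index.name, out.columns.name = "gene", None
    return out


def read_expression_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    return validate_expression_matrix(df)


def write_expression_matrix(df: pd.DataFrame, path) -> None:
    validate_expression_matrix(df).to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# genesets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Parse GMT: one geneset per line, ``name<TAB>description<TAB>gene...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, _desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate geneset {name!r}")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"{path}:{lineno}: duplicate gene in {name!r}")
            sets[name] = genes
    return sets


def write_gmt(genesets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in genesets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# signature references
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureReference:
    """96-channel x K column-stochastic matrix of SBS signature probabilities."""

    probs: pd.DataFrame  # index = SBS96_CHANNELS, columns = signature ids

    def __post_init__(self):
        probs = self.probs
        if list(probs.index) != list(SBS96_CHANNELS):
            raise ValidationError(
                "signature reference rows must be the canonical 96 channels "
                "in canonical order")
        if probs.columns.duplicated().any():
            raise ValidationError("duplicate signature id")
        arr = probs.to_numpy(dtype=float)
        if (arr < 0).any():
            raise ValidationError("negative signature probability")
        sums = arr.sum(axis=0)
        for sig, s in zip(probs.columns, sums):
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ValidationError(
                    f"signature column {sig!r} sums to {s:.6f}, not 1")
        probs = probs.astype(float)
        probs.index.name, probs.columns.name = "channel", None
        object.__setattr__(self, "probs", probs)

    @property
    def signatures(self) -> list[str]:
        return list(self.probs.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.probs.to_numpy(dtype=float)


def read_signature_reference(path) -> SignatureReference:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SignatureReference(df)


def write_signature_reference(ref: SignatureReference, path) -> None:
    ref.probs.to_csv(path, sep="\t", index_label="channel")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Contig name -> upper-case sequence (via pyfaidx)."""
    from pyfaidx import Fasta

    with Fasta(str(path), rebuild=True, build_index=True) as fa:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}


def write_fasta(contigs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
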