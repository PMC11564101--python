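"""96-channel substitution spectra and signature exposure refitting.

Single-base substitutions are assigned to the canonical pyrimidine-centric
96 trinucleotide channels: a substitution whose reference base is a purine
is reverse-complemented (triplet and alternate base) before labelling, so a
substitution and its reverse complement always share a channel.

Variants from paired samples are pooled group-wise (arm x origin):

* baseline pool — C1D1 VAF > 1%;
* acquired pool — absent at C1D1 (VAF 0 / undetected) and present at EoT
  with VAF > 0.

The pools are mutually exclusive by construction.  Exposures of a pooled
spectrum to a reference signature set are refit by nonnegative least
squares, ``argmin ||counts - P e||_2  s.t.  e >= 0``, reported with the
relative L2 reconstruction error and cosine similarity; proportions below a
sparsity floor (default 1% of the total) are zeroed in the reported mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import COMPLEMENT, SBS96_CHANNELS, SignatureReference, ValidationError

__all__ = [
    "SBS96_CHANNELS",
    "trinucleotide_channel",
    "pool_variants",
    "spectrum_from_variants",
    "ExposureVector",
    "refit_exposures",
    "make_synthetic_reference",
]

_CHANNEL_INDEX = {label: i for i, label in enumerate(SBS96_CHANNELS)}

BASELINE_VAF_THRESHOLD = 0.01  # baseline pool requires C1D1 VAF > 1%


def _revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def trinucleotide_channel(chrom: str, pos: int, ref: str, alt: str,
                          reference: dict[str, str]) -> str | None:
    """Channel label for an SNV given its flanking context.

    ``pos`` is 1-based; the reference base there must equal ``ref``.
    Purine-reference substitutions are strand-normalised by reverse
    complement.  Returns None (skip signal) at a contig edge.
    """
    if chrom not in reference:
        raise ValidationError(f"unknown contig {chrom!r}")
    seq = reference[chrom]
    if not (1 <= pos <= len(seq)):
        raise ValidationError(f"{chrom}:{pos} outside contig (len {len(seq)})")
    if seq[pos - 1] != ref:
        raise ValidationError(
            f"{chrom}:{pos} reference mismatch: FASTA has {seq[pos - 1]!r}, "
            f"call has {ref!r}")
    if pos == 1 or pos == len(seq):
        return None  # no flanking base on one side
    triplet = seq[pos - 2:pos + 1]
    if ref in ("A", "G"):
        triplet = _revcomp(triplet)
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{triplet[0]}[{ref}>{alt}]{triplet[2]}"


def pool_variants(status_records: pd.DataFrame,
                  patients: pd.DataFrame,
                  baseline_vaf_threshold: float = BASELINE_VAF_THRESHOLD,
                  ) -> dict[tuple[str, str], pd.DataFrame]:
    """Group-wise variant pools keyed by (arm, origin).

    origin ``baseline``: C1D1 VAF > threshold (default 1%); origin
    ``acquired``: no C1D1 detection and EoT VAF > 0.  Only SNVs are
    retained (spectra are substitution-defined).  The two pools partition:
    a baseline-pool member has a C1D1 VAF and an acquired-pool member has
    none, so no alteration can be in both.
    """
    arm_of = dict(zip(patients["patient_id"], patients["arm"]))
    snvs = status_records[status_records["variant_class"] == "SNV"]
    pools: dict[tuple[str, str], list] = {}
    for _, rec in snvs.iterrows():
        arm = arm_of.get(rec["patient_id"])
        if arm is None:
            continue
        c1d1 = rec["c1d1_vaf"]
        eot = rec["eot_vaf"]
        c1d1_detected = not pd.isna(c1d1) and c1d1 > 0
        if c1d1_detected and c1d1 > baseline_vaf_threshold:
            origin = "baseline"
        elif (not c1d1_detected) and not pd.isna(eot) and eot > 0:
            origin = "acquired"
        else:
            continue
        pools.setdefault((arm, origin), []).append(rec)
    return {key: pd.DataFrame(rows).reset_index(drop=True)
            for key, rows in pools.items()}


def spectrum_from_variants(variants: pd.DataFrame,
                           reference: dict[str, str]) -> np.ndarray:
    """96-channel count vector from SNV records; edge-of-contig SNVs skipped."""
    counts = np.zeros(96, dtype=int)
    for _, rec in variants.iterrows():
        label = trinucleotide_channel(rec["chrom"], int(rec["pos"]),
                                      rec["ref"], rec["alt"], reference)
        if label is not None:
            counts[_CHANNEL_INDEX[label]] += 1
    return counts


@dataclass
class ExposureVector:
    """NNLS refit of a pooled spectrum against a signature reference."""

    signatures: list[str]
    exposures: np.ndarray           # raw NNLS solution, >= 0
    proportions: np.ndarray         # sparsified, sums to 1 (or 0 if empty)
    reconstruction_error: float     # relative L2
    cosine_similarity: float

    def as_dict(self) -> dict:
        return {
            "signatures": list(self.signatures),
            "exposures": [float(x) for x in self.exposures],
            "proportions": [float(x) for x in self.proportions],
            "reconstruction_error": self.reconstruction_error,
            "cosine_similarity": self.cosine_similarity,
        }


def refit_exposures(counts: np.ndarray,
                    reference: SignatureReference,
                    sparsity_floor: float = 0.01) -> ExposureVector:
    """Nonnegative least-squares exposure refit of a 96-channel spectrum.

    ``proportions`` renormalises the solution to sum to 1 and zeroes
    entries below ``sparsity_floor`` of the total (then renormalises),
    mimicking attribution parsimony; the raw solution is kept alongside.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (96,):
        raise ValidationError(f"spectrum must have 96 channels, got {counts.shape}")
    if (counts < 0).any():
        raise ValidationError("negative channel count")
    total = counts.sum()
    if total == 0:
        raise ValidationError("zero spectrum")
    P = reference.matrix
    exposures, _ = nnls(P, counts)
    recon = P @ exposures
    err = float(np.linalg.norm(counts - recon) / np.linalg.norm(counts))
    denom = np.linalg.norm(counts) * np.linalg.norm(recon)
    cos = float(counts @ recon / denom) if denom > 0 else 0.0

    esum = exposures.sum()
    if esum > 0:
        props = exposures / esum
        props = np.where(props < sparsity_floor, 0.0, props)
        if props.sum() > 0:
            props = props / props.sum()
    else:
        props = np.zeros_like(exposures)
    return ExposureVector(signatures=reference.signatures,
                          exposures=exposures, proportions=props,
                          reconstruction_error=err, cosine_similarity=cos)


def make_synthetic_reference(signature_ids: list[str],
                             seed: int = 0,
                             concentration: float = 0.15) -> SignatureReference:
    """Synthetic, clearly-labelled stand-in signature set for tests/simulation.

    Each signature is a Dirichlet draw sharpened on a few characteristic
    channels so that signatures are mutually distinguishable; ids named
    after known substitution preferences (e.g. ``SBS17b`` -> T>G channels)
    concentrate their mass accordingly.  This emulates the *shape* of a
    predefined reference set without reproducing any published matrix.
    """
    rng = np.random.default_rng(seed)
    substitution_bias = {
        "SBS1": "C>T", "SBS5": None, "SBS15": "C>T",
        "SBS17a": "T>C", "SBS17b": "T>G",
    }
    cols = {}
    for sig in signature_ids:
        alpha = np.full(96, concentration)
        bias = substitution_bias.get(sig)
        if bias is not None:
            mask = np.array([f"[{bias}]" in ch for ch in SBS96_CHANNELS])
            alpha[mask] *= 40.0
        col = rng.dirichlet(alpha)
        cols[sig] = col / col.sum()
    probs = pd.DataFrame(cols, index=list(SBS96_CHANNELS))
    return SignatureReference(probs)
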