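"""Synthetic paired-ctDNA cohort generator.

Generates cohorts with the statistical structure the downstream analysis
assumes, so every stage is testable without access-restricted trial data:

* three treatment arms (``triplet``, ``doublet``, ``control``) with
  arm-specific mutation-acquisition rates — acquired alteration counts are
  Poisson(rate x months on treatment) with per-patient rate heterogeneity
  from a low/medium/high mixture;
* heavy-tailed baseline VAFs (truncated log-normal), one truncal driver SNV
  per patient defining the sample maxVAF, maintained/lost dynamics at EoT,
  and acquired alterations whose EoT VAF sits at a subclonal fraction of
  the sample maxVAF;
* SNV coordinates drawn on a synthetic reference contig so that the pooled
  96-channel spectra follow configurable per-(arm, origin) signature
  mixtures;
* a gene x sample expression matrix (log2(TPM+1)) carrying immune,
  cell-cycle and BM-subtype programs tied to per-patient latents — the
  cell-cycle latent is correlated with the acquisition rate, and the
  immune latent drives the cytolytic-score genes;
* survival times from a proportional-hazards model with arm effects, an
  immune x arm interaction, and simple baseline covariates (ECOG PS, CRP,
  organ count, prior irinotecan).

Everything derives from a single integer seed; identical configs produce
byte-identical outputs.  The ``truth`` block records every generative
parameter for recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (ARMS, COMPLEMENT, SBS96_CHANNELS, SignatureReference,
                 ValidationError, validate_expression_matrix,
                 validate_patient_table, validate_variant_table)
from .signatures import make_synthetic_reference

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "simulate_worked_counts",
    "synthetic_genome",
    "IMMUNE_GENES",
    "CELL_CYCLE_GENES",
    "BM_GENES",
    "default_bm_weights",
]

# --- gene panels -----------------------------------------------------------

#: cytolytic / CD8 / broader immune-program genes (synthetic stand-in for a
#: 20-gene immune signature plus the cytolytic and CD8 pairs)
IMMUNE_GENES = [
    "GZMA", "PRF1", "CD8A", "CD8B", "GZMB", "GZMH", "GNLY", "IFNG",
    "STAT1", "TBX21", "CXCL9", "CXCL10", "CXCL11", "CCL5", "IRF1",
    "IL2RB", "CD2", "CD3E", "NKG7", "KLRD1",
]

#: hallmark-style cell-cycle program genes
CELL_CYCLE_GENES = [
    "CCNB1", "CDK1", "MKI67", "BUB1", "PLK1", "CCNA2", "CDC20",
    "TOP2A", "AURKA", "AURKB",
]

#: synthetic stand-ins for the 44 BM-subtyping genes (names are synthetic;
#: real weights come from the cited subtyping publication as a config asset)
BM_GENES = [f"BMS{i:02d}" for i in range(1, 45)]

#: genes drawn on for baseline truncal alterations
BASELINE_GENES = ["BRAF", "TP53", "APC", "SMAD4", "FAT1", "RNF43", "LRP1B",
                  "PIK3CA", "KMT2D", "ARID1A"]

#: acquired-resistance gene pools by variant class
ACQUIRED_SNV_GENES = ["KRAS", "NRAS", "MAP2K1", "EGFR", "TP53", "APC",
                      "SMAD4", "FBXW7", "GNAS", "ERBB2"]
ACQUIRED_AMP_GENES = ["MET", "KRAS", "BRAF", "IGF1R"]
ACQUIRED_FUSION_GENES = ["MET", "BRAF", "ALK", "RET", "NTRK1"]

DEFAULT_SIGNATURES = ["SBS1", "SBS5", "SBS15", "SBS17a", "SBS17b"]


def _default_signature_mix() -> dict:
    base = {"SBS1": 0.45, "SBS5": 0.45, "SBS15": 0.10}
    return {
        ("triplet", "baseline"): dict(base),
        ("doublet", "baseline"): dict(base),
        ("control", "baseline"): dict(base),
        ("triplet", "acquired"): {"SBS1": 0.3, "SBS5": 0.3, "SBS17b": 0.4},
        ("doublet", "acquired"): {"SBS1": 0.25, "SBS5": 0.25,
                                  "SBS17a": 0.2, "SBS17b": 0.3},
        ("control", "acquired"): {"SBS1": 0.5, "SBS5": 0.5},
    }


@dataclass
class SimulationConfig:
    """Generative parameters of a synthetic paired-ctDNA cohort.

    Defaults emulate the study conditions the analysis assumes: ~106
    paired patients per arm, targeted-arm acquisition rates 1.7x and 1.5x
    the control rate, subclonal acquired VAFs (median EoT VAF/maxVAF well
    below 0.3), SBS17-shaped acquired spectra in the targeted arms, and an
    immune x arm survival interaction.
    """

    n_patients_per_arm: int = 106
    arms: tuple = ARMS
    baseline_mutation_rate: float = 25.0     # expected truncal alterations
    acquisition_rate_per_month: dict = field(default_factory=lambda: {
        "triplet": 3.4, "doublet": 3.0, "control": 2.0})
    rate_mixture: dict = field(default_factory=lambda: {
        "weights": (0.55, 0.35, 0.10),       # low / medium / high subgroups
        "multipliers": (0.3, 1.0, 6.0)})     # relative to the arm rate
    subclonal_vaf_scale: float = 0.12        # mean acquired VAF / maxVAF
    maintained_fraction: float = 0.85        # baseline calls kept at EoT
    signature_mix: dict = field(default_factory=_default_signature_mix)
    expression_programs: dict = field(default_factory=lambda: {
        "immune": 1.2, "cell_cycle": 1.2, "bm": 1.0})  # log2-unit effects
    survival_params: dict = field(default_factory=lambda: {
        "baseline_hazard": 0.05,             # events per month (control)
        "log_hr": {
            "arm_triplet": -0.45,
            "arm_doublet": -0.40,
            "immune": 0.30,                  # immune-high worse on doublet
            "immune_x_triplet": -0.80,       # ... but better on triplet
            "cell_cycle": 0.15,
            "ecog": 0.40,
            "log_crp": 0.20,
            "n_organs": 0.10,
            "prior_irinotecan": 0.10,
        },
        "pfs_hazard_multiplier": 1.8})
    censoring_rate: float = 0.25
    time_on_treatment: dict = field(default_factory=lambda: {
        "dist": "lognormal", "median_months": 4.5, "sigma": 0.6})
    genome_length: int = 30_000
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_patients_per_arm < 1:
            raise ValidationError("n_patients_per_arm must be positive")
        for arm in self.arms:
            if arm not in ARMS:
                raise ValidationError(f"unknown arm label {arm!r}")
            if arm not in self.acquisition_rate_per_month:
                raise ValidationError(f"no acquisition rate for arm {arm!r}")
            if self.acquisition_rate_per_month[arm] < 0:
                raise ValidationError("acquisition rates must be >= 0")
        if self.baseline_mutation_rate <= 0:
            raise ValidationError("baseline_mutation_rate must be > 0")
        if not 0 < self.subclonal_vaf_scale <= 1:
            raise ValidationError("subclonal_vaf_scale must be in (0, 1]")
        w = np.asarray(self.rate_mixture["weights"], dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("rate_mixture weights must sum to 1")
        if (np.asarray(self.rate_mixture["multipliers"]) <= 0).any():
            raise ValidationError("rate_mixture multipliers must be > 0")
        for key, mix in self.signature_mix.items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValidationError(
                    f"signature mix for {key} sums to {total}, not 1")
        if self.survival_params["baseline_hazard"] <= 0:
            raise ValidationError("baseline hazard must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        return self


@dataclass
class SyntheticCohort:
    """A simulated cohort plus the generative truth for recovery tests."""

    patients: pd.DataFrame
    variants: pd.DataFrame
    expression: pd.DataFrame
    reference: dict[str, str]                 # synthetic FASTA contigs
    signature_reference: SignatureReference
    truth: dict

    def __post_init__(self):
        validate_patient_table(self.patients)
        validate_variant_table(self.variants)
        known = set(self.patients["patient_id"])
        orphan = set(self.variants["patient_id"]) - known
        if orphan:
            raise ValidationError(f"variants for unknown patients: {orphan}")


# --- genome and context index ---------------------------------------------

def synthetic_genome(length: int = 30_000, seed: int = 0,
                     contig: str = "synth1") -> dict[str, str]:
    """A single random synthetic contig (clearly labelled as synthetic)."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=length))
    return {contig: seq}


def _context_index(reference: dict[str, str]) -> dict[tuple, list]:
    """Pyrimidine-centric context -> [(contig, pos, strand)], 1-based pos.

    strand +1 means the forward base is the pyrimidine; -1 means the
    context matches on the reverse complement.
    """
    index: dict[tuple, list] = {}
    for contig, seq in reference.items():
        for pos in range(2, len(seq)):        # 1-based, both flanks present
            trip = seq[pos - 2:pos + 1]
            mid = trip[1]
            if mid in ("C", "T"):
                key = (trip[0], mid, trip[2])
                strand = 1
            else:
                rc = "".join(COMPLEMENT[b] for b in reversed(trip))
                key = (rc[0], rc[1], rc[2])
                strand = -1
            index.setdefault(key, []).append((contig, pos, strand))
    return index


def _parse_channel(channel: str) -> tuple[str, str, str, str]:
    # "A[C>T]G" -> ("A", "C", "T", "G")
    return channel[0], channel[2], channel[4], channel[6]


# --- cohort simulation -----------------------------------------------------

def _draw_snv(rng, channel_probs, channels, ctx_index, used, reference):
    """Place an SNV realising a channel drawn from the mixture."""
    for _ in range(50):
        channel = channels[rng.choice(len(channels), p=channel_probs)]
        five, ref_pyr, alt_pyr, three = _parse_channel(channel)
        sites = ctx_index.get((five, ref_pyr, three))
        if not sites:
            continue
        contig, pos, strand = sites[rng.integers(len(sites))]
        if (contig, pos) in used:
            continue
        used.add((contig, pos))
        if strand == 1:
            ref, alt = ref_pyr, alt_pyr
        else:
            ref, alt = COMPLEMENT[ref_pyr], COMPLEMENT[alt_pyr]
        assert reference[contig][pos - 1] == ref
        return contig, pos, ref, alt
    raise ValidationError("could not place SNV; genome too small")


def _truncated_lognormal(rng, median, sigma, low, high):
    for _ in range(1000):
        x = rng.lognormal(math.log(median), sigma)
        if low < x < high:
            return x
    return min(max(low * 1.01, median), high * 0.99)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Simulate a full paired-ctDNA + expression + survival cohort."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    (s_genome, s_variants, s_expr, s_surv, s_sig) = root.spawn(5)
    rng_v = np.random.default_rng(s_variants)
    rng_e = np.random.default_rng(s_expr)
    rng_s = np.random.default_rng(s_surv)

    reference = synthetic_genome(config.genome_length,
                                 seed=s_genome.generate_state(1)[0] % (2**31))
    ctx_index = _context_index(reference)
    sig_ref = make_synthetic_reference(
        DEFAULT_SIGNATURES, seed=int(s_sig.generate_state(1)[0] % (2**31)))
    sig_probs = {sig: sig_ref.probs[sig].to_numpy() for sig in DEFAULT_SIGNATURES}
    channels = list(SBS96_CHANNELS)

    def channel_probs_for(arm: str, origin: str) -> np.ndarray:
        mix = config.signature_mix[(arm, origin)]
        p = np.zeros(96)
        for sig, wgt in mix.items():
            p += wgt * sig_probs[sig]
        return p / p.sum()

    mix_w = np.asarray(config.rate_mixture["weights"], dtype=float)
    mix_m = np.asarray(config.rate_mixture["multipliers"], dtype=float)

    patient_rows, variant_rows = [], []
    latents = {"immune": {}, "cell_cycle": {}, "bm": {}}
    truth_patients = {}

    pid_counter = 0
    for arm in config.arms:
        arm_rate = config.acquisition_rate_per_month[arm]
        base_probs = channel_probs_for(arm, "baseline")
        acq_probs = channel_probs_for(arm, "acquired")
        for _ in range(config.n_patients_per_arm):
            pid_counter += 1
            pid = f"P{pid_counter:04d}"
            used: set = set()

            # exposure ------------------------------------------------------
            tot_cfg = config.time_on_treatment
            months = rng_v.lognormal(math.log(tot_cfg["median_months"]),
                                     tot_cfg["sigma"])
            months = max(months, 0.25)

            # acquisition rate ---------------------------------------------
            comp = int(rng_v.choice(len(mix_w), p=mix_w))
            lam = arm_rate * mix_m[comp]

            # baseline (C1D1) calls ----------------------------------------
            max_vaf = _truncated_lognormal(rng_v, 0.10, 1.2, 1e-4, 1.0)
            n_base = max(1, rng_v.poisson(config.baseline_mutation_rate))
            base_alts = []
            # truncal driver defines maxVAF and is always maintained
            contig, pos, ref, alt = _draw_snv(rng_v, base_probs, channels,
                                              ctx_index, used, reference)
            base_alts.append(dict(gene="BRAF", variant_class="SNV",
                                  chrom=contig, pos=pos, ref=ref, alt=alt,
                                  c1d1_vaf=max_vaf, maintained=True,
                                  protein_change="V600E"))
            for _ in range(n_base - 1):
                vaf = max_vaf * _truncated_lognormal(rng_v, 0.4, 0.9,
                                                     1e-4 / max_vaf, 1.0)
                contig, pos, ref, alt = _draw_snv(rng_v, base_probs, channels,
                                                  ctx_index, used, reference)
                gene = BASELINE_GENES[rng_v.integers(1, len(BASELINE_GENES))]
                base_alts.append(dict(
                    gene=gene, variant_class="SNV", chrom=contig, pos=pos,
                    ref=ref, alt=alt, c1d1_vaf=min(vaf, max_vaf),
                    maintained=bool(rng_v.random() < config.maintained_fraction),
                    protein_change=None))

            for rec in base_alts:
                variant_rows.append(dict(
                    patient_id=pid, timepoint="C1D1", gene=rec["gene"],
                    variant_class=rec["variant_class"], chrom=rec["chrom"],
                    pos=rec["pos"], ref=rec["ref"], alt=rec["alt"],
                    vaf=rec["c1d1_vaf"], protein_change=rec["protein_change"]))

            # EoT: maintained calls ----------------------------------------
            eot_vafs = []
            for rec in base_alts:
                if not rec["maintained"]:
                    continue
                eot_vaf = min(rec["c1d1_vaf"]
                              * rng_v.lognormal(0.0, 0.3), 1.0)
                eot_vafs.append(eot_vaf)
                variant_rows.append(dict(
                    patient_id=pid, timepoint="EoT", gene=rec["gene"],
                    variant_class=rec["variant_class"], chrom=rec["chrom"],
                    pos=rec["pos"], ref=rec["ref"], alt=rec["alt"],
                    vaf=eot_vaf, protein_change=rec["protein_change"]))
            eot_max = max(eot_vafs)

            # EoT: acquired calls ------------------------------------------
            n_acq = rng_v.poisson(lam * months)
            ampfus_seen: set = set()
            for _ in range(n_acq):
                u = rng_v.random()
                if u < 0.85:
                    vclass = "SNV"
                elif u < 0.90:
                    vclass = "indel"
                elif u < 0.97:
                    vclass = "amplification"
                else:
                    vclass = "fusion"
                if vclass in ("amplification", "fusion"):
                    pool = (ACQUIRED_AMP_GENES if vclass == "amplification"
                            else ACQUIRED_FUSION_GENES)
                    gene = pool[rng_v.integers(len(pool))]
                    if (gene, vclass) in ampfus_seen:
                        vclass = "SNV"  # keys unique per class: re-emit as SNV
                    else:
                        ampfus_seen.add((gene, vclass))
                if vclass in ("SNV", "indel"):
                    vaf = eot_max * config.subclonal_vaf_scale \
                        * rng_v.lognormal(0.0, 0.5)
                    vaf = float(np.clip(vaf, 1e-4, eot_max))
                if vclass == "SNV":
                    contig, pos, ref, alt = _draw_snv(
                        rng_v, acq_probs, channels, ctx_index, used, reference)
                    gene = ACQUIRED_SNV_GENES[
                        rng_v.integers(len(ACQUIRED_SNV_GENES))]
                    variant_rows.append(dict(
                        patient_id=pid, timepoint="EoT", gene=gene,
                        variant_class="SNV", chrom=contig, pos=pos,
                        ref=ref, alt=alt, vaf=vaf, protein_change=None))
                elif vclass == "indel":
                    contig = next(iter(reference))
                    for _ in range(50):
                        pos = int(rng_v.integers(2, len(reference[contig])))
                        if (contig, pos) not in used:
                            break
                    used.add((contig, pos))
                    ref = reference[contig][pos - 1]
                    variant_rows.append(dict(
                        patient_id=pid, timepoint="EoT",
                        gene=ACQUIRED_SNV_GENES[
                            rng_v.integers(len(ACQUIRED_SNV_GENES))],
                        variant_class="indel", chrom=contig, pos=pos,
                        ref=ref, alt=ref + "A", vaf=vaf, protein_change=None))
                else:
                    variant_rows.append(dict(
                        patient_id=pid, timepoint="EoT", gene=gene,
                        variant_class=vclass, chrom=None, pos=None,
                        ref=None, alt=None, vaf=np.nan, protein_change=None))

            # latents -------------------------------------------------------
            immune = rng_e.normal()
            lam_z = math.log(max(lam, 1e-3))
            cell_cycle = 0.7 * (lam_z - math.log(max(arm_rate, 1e-3))) \
                / max(math.log(mix_m[-1]), 1e-6) + rng_e.normal(0, 0.7)
            bm = 0.6 * immune + 0.8 * rng_e.normal()
            latents["immune"][pid] = immune
            latents["cell_cycle"][pid] = cell_cycle
            latents["bm"][pid] = bm

            # covariates ----------------------------------------------------
            ecog = int(rng_s.random() < 0.4)
            crp = float(rng_s.lognormal(1.0, 0.8))
            n_organs = int(1 + rng_s.poisson(1.3))
            prior_iri = int(rng_s.random() < 0.5)

            # survival ------------------------------------------------------
            sp = config.survival_params
            lhr = sp["log_hr"]
            xb = (lhr["arm_triplet"] * (arm == "triplet")
                  + lhr["arm_doublet"] * (arm == "doublet")
                  + lhr["immune"] * immune
                  + lhr["immune_x_triplet"] * immune * (arm == "triplet")
                  + lhr["cell_cycle"] * cell_cycle
                  + lhr["ecog"] * ecog
                  + lhr["log_crp"] * math.log(crp)
                  + lhr["n_organs"] * (n_organs - 1)
                  + lhr["prior_irinotecan"] * prior_iri)
            haz = sp["baseline_hazard"] * math.exp(xb)
            os_raw = rng_s.exponential(1.0 / haz)
            pfs_raw = rng_s.exponential(
                1.0 / (haz * sp["pfs_hazard_multiplier"]))
            cens_rate = config.censoring_rate
            if cens_rate > 0:
                c_haz = sp["baseline_hazard"] * cens_rate / (1 - cens_rate)
                cens = rng_s.exponential(1.0 / c_haz)
            else:
                cens = math.inf
            os_months = min(os_raw, cens)
            os_event = int(os_raw <= cens)
            pfs_months = min(pfs_raw, os_months)
            pfs_event = int(pfs_raw <= min(cens, os_raw))

            patient_rows.append(dict(
                patient_id=pid, arm=arm,
                time_on_treatment_months=months,
                os_months=os_months, os_event=os_event,
                pfs_months=pfs_months, pfs_event=pfs_event,
                ecog=ecog, crp=crp, n_organs=n_organs,
                prior_irinotecan=prior_iri))
            truth_patients[pid] = dict(
                arm=arm, lam=lam, component=comp, months=months,
                expected_acquired=lam * months, n_acquired=int(n_acq),
                immune=immune, cell_cycle=cell_cycle, bm=bm,
                hazard=haz)

    patients = pd.DataFrame(patient_rows)
    variants = validate_variant_table(pd.DataFrame(variant_rows))

    # expression matrix -----------------------------------------------------
    eff = config.expression_programs
    bm_weights = default_bm_weights(
        seed=int(root.spawn(1)[0].generate_state(1)[0] % (2**31)))
    n_background = 400
    background = [f"GENE{i:04d}" for i in range(1, n_background + 1)]
    genes = IMMUNE_GENES + CELL_CYCLE_GENES + BM_GENES + background
    ids = patients["patient_id"].tolist()
    expr = pd.DataFrame(
        rng_e.normal(3.0, 1.0, size=(len(genes), len(ids))),
        index=genes, columns=ids)
    imm = np.array([latents["immune"][p] for p in ids])
    ccl = np.array([latents["cell_cycle"][p] for p in ids])
    bml = np.array([latents["bm"][p] for p in ids])
    expr.loc[IMMUNE_GENES] += eff["immune"] * imm
    expr.loc[CELL_CYCLE_GENES] += eff["cell_cycle"] * ccl
    for gene in BM_GENES:
        expr.loc[gene] += eff["bm"] * np.sign(bm_weights[gene]) * bml
    expr = validate_expression_matrix(expr.clip(lower=0.0))

    truth = {
        "config": config,
        "patients": truth_patients,
        "rate_mixture": dict(config.rate_mixture),
        "acquisition_rate_per_month": dict(config.acquisition_rate_per_month),
        "signature_mix": dict(config.signature_mix),
        "bm_weights": bm_weights,
        "latents": latents,
        "log_hr": dict(config.survival_params["log_hr"]),
    }
    return SyntheticCohort(patients=patients, variants=variants,
                           expression=expr, reference=reference,
                           signature_reference=sig_ref, truth=truth)


def default_bm_weights(seed: int = 12345) -> pd.Series:
    """Synthetic 44-gene subtyping weight vector (stand-in config asset).

    Roughly half the genes weight positive (immune/EMT-like, pushing
    toward BM1) and half negative (cell-cycle-like, pushing toward BM2);
    magnitudes are moderate so that weighted z-sums land on both sides of
    the 1.5 cutoff.
    """
    rng = np.random.default_rng(seed)
    signs = np.where(np.arange(len(BM_GENES)) % 2 == 0, 1.0, -1.0)
    mags = rng.uniform(0.05, 0.35, size=len(BM_GENES))
    return pd.Series(signs * mags, index=BM_GENES)


def simulate_worked_counts(numerator: int, denominator: int,
                           gene: str = "MET",
                           variant_class: str = "amplification",
                           arm: str = "triplet"
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Minimal paired cohort realising a given count/denominator summary.

    Exactly ``denominator`` paired patients, each carrying a maintained
    truncal BRAF SNV; exactly ``numerator`` of them additionally carry an
    EoT-only alteration of the labelled gene and class.  Feeding the
    result through status classification and the frequency summarizer
    reproduces the implied percentage.
    """
    if not 0 <= numerator <= denominator:
        raise ValidationError("need 0 <= numerator <= denominator")
    if arm not in ARMS:
        raise ValidationError(f"unknown arm {arm!r}")
    variant_rows, patient_rows = [], []
    for i in range(1, denominator + 1):
        pid = f"W{i:04d}"
        for tp, vaf in (("C1D1", 0.20), ("EoT", 0.18)):
            variant_rows.append(dict(
                patient_id=pid, timepoint=tp, gene="BRAF",
                variant_class="SNV", chrom="synth1", pos=100 + i,
                ref="C", alt="T", vaf=vaf, protein_change="V600E"))
        if i <= numerator:
            if variant_class in ("SNV", "indel"):
                variant_rows.append(dict(
                    patient_id=pid, timepoint="EoT", gene=gene,
                    variant_class=variant_class, chrom="synth1",
                    pos=5000 + i, ref="C",
                    alt="T" if variant_class == "SNV" else "CA",
                    vaf=0.02, protein_change=None))
            else:
                variant_rows.append(dict(
                    patient_id=pid, timepoint="EoT", gene=gene,
                    variant_class=variant_class, chrom=None, pos=None,
                    ref=None, alt=None, vaf=np.nan, protein_change=None))
        patient_rows.append(dict(
            patient_id=pid, arm=arm, time_on_treatment_months=4.0,
            os_months=10.0, os_event=0, pfs_months=6.0, pfs_event=0))
    variants = validate_variant_table(pd.DataFrame(variant_rows))
    patients = validate_patient_table(pd.DataFrame(patient_rows))
    return variants, patients
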