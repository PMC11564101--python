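"""End-to-end pipeline: io -> dynamics -> clonality -> rates -> signatures
-> expression scores -> enrichment -> survival.

Stages that need inputs the config does not provide (e.g. expression
scoring without an expression matrix) are skipped with a log entry; every
produced file is listed in a machine-readable summary JSON with a content
hash, alongside the seed and a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import clonality as clonality_mod
from . import dynamics, enrichment, expression, rates, signatures
from . import survival as survival_mod
from .io import (ValidationError, read_expression_matrix, read_fasta,
                 read_gmt, read_patient_table, read_signature_reference,
                 read_variant_table)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

#: default top acquired putative resistance alterations
TOP_ACQUIRED_GENES = ["KRAS", "NRAS", "MAP2K1", "MET"]


@dataclass
class PipelineConfig:
    """Inputs, thresholds and knobs for a full run."""

    variants_path: str | None = None
    patients_path: str | None = None
    expression_path: str | None = None
    genesets_path: str | None = None          # GMT
    bm_weights_path: str | None = None        # TSV: gene <TAB> weight
    signature_reference_path: str | None = None
    fasta_path: str | None = None
    output_dir: str = "ctdynamics_out"
    top_genes: list[str] = field(default_factory=lambda: list(TOP_ACQUIRED_GENES))
    subclonal_threshold: float = 0.3
    baseline_vaf_threshold: float = 0.01
    bm_threshold: float = 1.5
    mixture_k: int = 3
    n_restarts: int = 20
    n_perm: int = 1000
    reference_arm: str = "control"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for name in ("subclonal_threshold", "baseline_vaf_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.mixture_k < 1:
            raise ValidationError("mixture_k must be >= 1")
        return self


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True,
                         default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages whose inputs are available; returns the summary."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed,
                     "config_hash": _config_hash(config),
                     "stages": {}, "outputs": {}}

    def emit(name: str, path: Path):
        summary["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    variants = patients = status = gene_status = None

    if config.variants_path and config.patients_path:
        variants = read_variant_table(config.variants_path)
        patients = read_patient_table(config.patients_path)

        # --- dynamics -----------------------------------------------------
        status = dynamics.classify_cohort(variants)
        status_path = outdir / "alteration_status.tsv"
        status.to_csv(status_path, sep="\t", index=False)
        emit("alteration_status", status_path)

        gene_status = dynamics.aggregate_gene_status_cohort(status)
        gs_path = outdir / "gene_status.tsv"
        gene_status.to_csv(gs_path, sep="\t", index=False)
        emit("gene_status", gs_path)

        freq = dynamics.summarize_acquisition_frequency(
            gene_status, config.top_genes,
            denominator=patients["patient_id"].nunique())
        freq_path = outdir / "acquisition_frequency.tsv"
        freq.to_csv(freq_path, sep="\t", index=False)
        emit("acquisition_frequency", freq_path)

        multi = dynamics.count_multi_acquired(gene_status, patients)
        multi_path = outdir / "multi_acquired.tsv"
        multi.to_csv(multi_path, sep="\t", index=False)
        emit("multi_acquired", multi_path)
        summary["stages"]["dynamics"] = "ok"

        # --- clonality ----------------------------------------------------
        clon = clonality_mod.compute_clonality_cohort(
            status, variants, threshold=config.subclonal_threshold)
        clon_path = outdir / "clonality.tsv"
        clon.to_csv(clon_path, sep="\t", index=False)
        emit("clonality", clon_path)
        acq = clon.loc[clon["status"] == "acquired", "ratio"]
        mnt = clon.loc[clon["status"] == "maintained", "ratio"]
        if len(acq) and len(mnt):
            summary["stages"]["clonality"] = clonality_mod.compare_clonality(
                acq, mnt)
        else:
            summary["stages"]["clonality"] = "skipped (a status group empty)"

        # --- rates --------------------------------------------------------
        obs = rates.compute_rates(status, patients)
        obs_path = outdir / "acquisition_rates.tsv"
        obs.to_csv(obs_path, sep="\t", index=False)
        emit("acquisition_rates", obs_path)
        fit = rates.fit_poisson_mixture(obs, K=config.mixture_k,
                                        n_restarts=config.n_restarts,
                                        seed=config.seed)
        bic = rates.poisson_mixture_bic_table(obs, seed=config.seed,
                                              n_restarts=max(
                                                  5, config.n_restarts // 4))
        mixture_json = {
            "K": fit.K,
            "weights": fit.weights.tolist(),
            "rates_per_month": fit.rates.tolist(),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "bic_table": bic.to_dict(orient="records"),
        }
        mix_path = outdir / "rate_mixture.json"
        mix_path.write_text(json.dumps(mixture_json, indent=2))
        emit("rate_mixture", mix_path)
        try:
            nb = rates.compare_rates_nb(obs, reference_arm=config.reference_arm)
        except ValidationError as exc:
            nb = {"error": str(exc)}
        nb_path = outdir / "rate_comparison.json"
        nb_path.write_text(json.dumps(nb, indent=2))
        emit("rate_comparison", nb_path)
        summary["stages"]["rates"] = "ok"

        # --- signatures -----------------------------------------------------
        if config.fasta_path and config.signature_reference_path:
            reference = read_fasta(config.fasta_path)
            sig_ref = read_signature_reference(config.signature_reference_path)
            pools = signatures.pool_variants(
                status, patients,
                baseline_vaf_threshold=config.baseline_vaf_threshold)
            spectra, exposures = {}, {}
            for (arm, origin), pool in sorted(pools.items()):
                counts = signatures.spectrum_from_variants(pool, reference)
                spectra[f"{arm}:{origin}"] = counts.tolist()
                if counts.sum() > 0:
                    exposures[f"{arm}:{origin}"] = signatures.refit_exposures(
                        counts, sig_ref).as_dict()
            spec_df = pd.DataFrame(spectra, index=list(signatures.SBS96_CHANNELS))
            spec_path = outdir / "spectra.tsv"
            spec_df.to_csv(spec_path, sep="\t", index_label="channel")
            emit("spectra", spec_path)
            exp_path = outdir / "signature_exposures.json"
            exp_path.write_text(json.dumps(exposures, indent=2))
            emit("signature_exposures", exp_path)
            summary["stages"]["signatures"] = "ok"
        else:
            logger.info("signature stage skipped (no FASTA/reference)")
            summary["stages"]["signatures"] = "skipped"
    else:
        logger.info("ctDNA stages skipped (no variant/patient tables)")
        for st in ("dynamics", "clonality", "rates", "signatures"):
            summary["stages"][st] = "skipped"

    # --- expression scores --------------------------------------------------
    if config.expression_path and config.patients_path:
        expr = read_expression_matrix(config.expression_path)
        if patients is None:
            patients = read_patient_table(config.patients_path)
        scores = pd.DataFrame(index=expr.columns)
        have = set(expr.index)
        if {"GZMA", "PRF1"} <= have:
            scores["cytolytic"] = expression.geometric_signature_score(
                expr, ["GZMA", "PRF1"])
            scores["cytolytic_group"] = expression.median_split(
                scores["cytolytic"])
        if {"CD8A", "CD8B"} <= have:
            scores["cd8"] = expression.geometric_signature_score(
                expr, ["CD8A", "CD8B"])
        if config.bm_weights_path:
            w = pd.read_csv(config.bm_weights_path, sep="\t", index_col=0)
            bm = expression.bm_subtype(expr, w.iloc[:, 0],
                                       threshold=config.bm_threshold)
            scores["bm_score"] = bm["score"]
            scores["bm_subtype"] = bm["subtype"]
        scores_path = outdir / "expression_scores.tsv"
        scores.to_csv(scores_path, sep="\t", index_label="sample")
        emit("expression_scores", scores_path)
        summary["stages"]["scores"] = "ok"

        # --- enrichment -----------------------------------------------------
        if config.genesets_path:
            genesets = read_gmt(config.genesets_path)
            filtered = expression.filter_top_iqr(expr)
            zs = expression.zscore_genes(filtered)
            ranked = enrichment.rank_genes_by_model(zs, patients)
            gsea = enrichment.preranked_gsea(ranked, genesets,
                                             n_perm=config.n_perm,
                                             seed=config.seed)
            gsea_path = outdir / "gsea.tsv"
            out = gsea.copy()
            if not out.empty:
                out["leading_edge"] = out["leading_edge"].map(",".join)
            out.to_csv(gsea_path, sep="\t", index=False)
            emit("gsea", gsea_path)
            summary["stages"]["enrichment"] = "ok"
        else:
            summary["stages"]["enrichment"] = "skipped"

        # --- survival -------------------------------------------------------
        if "cytolytic_group" in scores.columns:
            meta = patients.set_index("patient_id")
            shared = [s for s in scores.index if s in meta.index]
            sub = meta.loc[shared]
            surv_out = {}
            km = survival_mod.km_fit(sub["os_months"], sub["os_event"],
                                     scores.loc[shared, "cytolytic_group"])
            surv_out["km_by_cytolytic"] = {
                g: {"n": f.n, "events": f.events, "median": f.median}
                for g, f in km.items()}
            arms_present = sorted(sub["arm"].unique())
            if {"triplet", "control"} <= set(arms_present):
                two = sub[sub["arm"].isin(["control", "triplet"])]
                cyto = scores.loc[two.index, "cytolytic"].to_numpy(float)
                res = survival_mod.interaction_test(
                    two["os_months"], two["os_event"],
                    (two["arm"] == "triplet").to_numpy(float), cyto)
                surv_out["cytolytic_x_triplet_interaction"] = res
            surv_path = outdir / "survival.json"
            surv_path.write_text(json.dumps(surv_out, indent=2))
            emit("survival", surv_path)
            summary["stages"]["survival"] = "ok"
        else:
            summary["stages"]["survival"] = "skipped"
    else:
        logger.info("expression stages skipped (no expression matrix)")
        for st in ("scores", "enrichment", "survival"):
            summary["stages"][st] = "skipped"

    summary_path = outdir / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, default=str))
    return summary
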