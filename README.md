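# ctdynamics

Analysis toolkit for **paired-timepoint circulating tumor DNA (ctDNA)
resistance dynamics** in treated metastatic colorectal cancer, integrated
with bulk transcriptomic scoring and survival association. It is aimed at
translational genomics analysts working with liquid-biopsy panels sampled
at baseline (cycle 1 day 1, C1D1) and end of treatment (EoT), alongside a
tumor expression matrix and clinical outcomes.

## What it computes

**Alteration dynamics.** Each somatic alteration observed in a patient's
paired samples is classified as *acquired* (EoT only), *maintained* (both
timepoints) or *lost* (C1D1 only); SNVs/indels are keyed by exact
(chrom, pos, ref, alt), amplifications and fusions by (gene, class).
Gene-level rollups apply the precedence maintained > acquired > lost.
Frequencies are reported as count / denominator pairs with 1-decimal
half-away-from-zero percentages, plus detection-concordance summaries and
Fisher exact 2×2 association tests (odds ratio = *ad/bc*).

**Clonality.** For each VAF-bearing alteration at EoT, the clonality ratio
is VAF / maxVAF, where maxVAF is the highest VAF among all somatic
alterations in the sample (a tumor-fraction proxy). Ratios ≤ 0.3 are
called subclonal; acquired vs maintained ratios are compared with a
Wilcoxon rank-sum test (exact for small samples).

**Acquisition rates.** Each paired patient contributes an acquired-count
and an exposure (months on treatment). A K-component Poisson mixture with
exposure offsets, *count*ᵢ ~ Poisson(λₖ·tᵢ), fitted by EM (restarted,
seeded, monotone log-likelihood), partitions patients into low/medium/high
rate subgroups; a negative-binomial regression with log-exposure offsets
estimates per-arm rate ratios.

**Mutational signatures.** SNVs are mapped to the canonical 96
pyrimidine-centric trinucleotide channels, pooled per (arm, origin) —
baseline = C1D1 VAF > 1 %, acquired = no C1D1 detection and EoT VAF > 0 —
and refit against a reference signature matrix by nonnegative least
squares, `argmin ‖counts − P·e‖₂ s.t. e ≥ 0`.

**Expression scores.** Cytolytic (geometric mean of GZMA and PRF1 in
TPM+1, i.e. mean log2(TPM+1)), CD8 and ICR-style geometric scores; BM
subtype as a weighted 44-gene z-score sum with the fixed 1.5 cutoff
(score > 1.5 → BM1, else BM2); single-sample GSEA; top-IQR variance
filtering; median splits (ties low).

**Enrichment and survival.** Per-gene Cox Wald z ranking (univariable or
gene×arm interaction), preranked GSEA with a gene-permutation null and
Benjamini–Hochberg control; Kaplan–Meier estimates, Cox proportional
hazards (Efron ties) with optional covariate adjustment, and
treatment×biomarker interaction Wald tests.

**Synthetic cohorts.** `ctdynamics.synthetic` generates full cohorts —
variants with signature-shaped spectra on a synthetic reference contig,
subclonal acquired VAFs, arm-specific acquisition rates with mixture
heterogeneity, expression programs tied to patient latents, and
proportional-hazards survival — with a `truth` block for recovery testing.

## Worked example

```python
from ctdynamics import (SimulationConfig, simulate_cohort, classify_cohort,
                        compute_rates, compare_rates_nb, fit_poisson_mixture)

cohort = simulate_cohort(SimulationConfig(seed=1))   # 106 patients/arm
status = classify_cohort(cohort.variants)
obs = compute_rates(status, cohort.patients)

nb = compare_rates_nb(obs, reference_arm="control")
print({arm: round(r["rate_ratio"], 2) for arm, r in nb["arms"].items()})

fit = fit_poisson_mixture(obs, K=3, seed=1)
print([round(float(r), 2) for r in fit.rates])
```

prints

```
{'doublet': 1.65, 'triplet': 1.59}
[0.87, 2.96, 16.2]
```

— the targeted arms acquire alterations roughly 1.6× faster than the
control arm (generative truths 1.5× and 1.7×; per-patient rate
heterogeneity makes single-cohort estimates noisy), and the
three-component mixture separates patients into subgroups acquiring
about 0.9, 3.0 and 16 mutations per month.

A shell interface mirrors the stages
(`ctdynamics simulate|classify|clonality|rates|signatures|scores|gsea|survival|run`);
`ctdynamics run config.yaml` executes the full pipeline and writes
per-stage TSV/JSON outputs plus a summary with content hashes.

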