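# Methods

This note documents the statistical models, conventions and design
choices behind `ctdynamics`, and what the synthetic-data generator does
and does not emulate.

## Alteration status and identity

Paired-sample status is presence-based: an alteration is *acquired* if
detected at EoT only, *maintained* if detected at both timepoints, *lost*
if detected at C1D1 only. Detection means membership in the reported call
set regardless of VAF, because liquid-biopsy panels report calls down to
0.01 % VAF and the status definition is about detection, not abundance. An
optional `min_vaf` presence threshold exists but defaults to 0. SNV/indel
identity requires an exact (chrom, pos, ref, alt) match (1-based, VCF
convention); amplifications and fusions carry no substitution coordinates
and are keyed by (gene, class). Statuses partition the key union — this is
property-tested against brute-force set algebra.

Gene-level rollups use the precedence maintained > acquired > lost. A
second rollup at (gene, class) resolution exists because class-qualified
summaries (e.g. acquired-fusion frequencies) must not be swallowed by a
maintained SNV in the same gene.

Percentages are reported at 1 decimal, rounded half away from zero, which
reproduces printed count/denominator summaries exactly. The evaluable
denominator for acquisition frequencies is configurable: either all paired
patients, or patients without the baseline alteration
(`exclude_baseline_carriers=True`) — both conventions appear in practice
and the choice is the caller's.

For 2×2 associations the odds ratio is the sample cross-ratio *ad/bc*;
with exactly one zero cell the Haldane–Anscombe 0.5 correction is applied
and flagged in the output (a conventional, explicit choice — the source
analyses do not specify one). The p-value is the two-sided Fisher exact
test (hypergeometric enumeration, via scipy), verified against an exact
rational-arithmetic oracle.

## Clonality

maxVAF is the maximum VAF over all VAF-bearing somatic alterations in a
sample, computed inclusively: the alteration being normalised
participates, so exactly one alteration per sample attains ratio 1 unless
tied. (Whether the focal alteration should be excluded is ambiguous; the
inclusive sample-level convention is adopted and documented here.)
Amplifications and fusions have no VAF and are excluded; a sample with no
VAF-bearing calls is *undetected* (distinct from maxVAF = 0) and dropped
from clonality analyses. Ratios ≤ 0.3 are subclonal, boundary inclusive.

The acquired-vs-maintained comparison is a two-sided Wilcoxon rank-sum
test: exact enumeration when the combined sample size is ≤ 20 with no
ties, otherwise the normal approximation with tie correction. The exact
branch is verified against an exhaustive rank-permutation oracle.

## Acquisition-rate models

Per-patient rate = acquired count / months on treatment, assuming a
constant acquisition rate over the treatment interval. Zero rates are
mapped to half the smallest nonzero rate *only* in the display transform
(`zero_rate_display`), never in modelling.

**Poisson mixture.** `count_i ~ Σₖ πₖ Poisson(λₖ·tᵢ)` fitted by EM on
counts with exposure offsets (statistically preferable to mixing
pre-computed rates, which would ignore heteroscedastic exposure). K
defaults to 3 (low/medium/high subgroups), with a BIC table over
K ∈ {1..5} as a diagnostic since no selection rule is prescribed.
Initialisation places rates at quantiles of the observed per-patient
rates with multiplicative log-normal jitter across restarts (default 20,
seeded). The log-likelihood is asserted nondecreasing at every EM
iteration; convergence is a relative change < 1e-8; components are
reported in ascending rate order, making the fit invariant to patient
order and label permutation. K = 1 reduces exactly to the pooled MLE
Σcounts/Σexposures. An all-zero count vector with K > 1 is degenerate and
flagged with a warning.

**Arm comparison.** Negative-binomial regression of counts on arm
indicators with log-exposure offsets (dispersion estimated by maximum
likelihood); exponentiated coefficients are rate ratios vs the reference
arm with Wald 95 % CIs. If the NB fit fails (e.g. no overdispersion to
estimate, separation), the model falls back to a Poisson GLM and flags it.

## Mutational signatures

Channels are the canonical pyrimidine-centric 96 set, ordered
substitution-major (C>A … T>G) then by 5′ and 3′ flank. Purine-reference
substitutions are reverse-complemented (triplet and alternate base), so a
substitution and its reverse complement always share a channel
(property-tested). Contig-edge SNVs lack a flank and are skipped; a
FASTA/call reference-base mismatch is an error naming the position.

Pools per (arm, origin): baseline = C1D1 VAF > 1 %; acquired = no C1D1
detection (VAF 0 or undetected — indistinguishable in panel output,
treated as 0) and EoT VAF > 0. The pools are disjoint by construction.
Only SNVs enter spectra. Protein-altering filtering is not performed (the
pipeline carries no consequence annotator); this is a documented deviation
from pipelines that restrict to protein-altering calls.

Exposure refitting is nonnegative least squares against a user-supplied
reference matrix (never downloaded; tests and the generator use synthetic
signatures built by `make_synthetic_reference`, clearly labelled
stand-ins whose ids indicate their dominant substitution class).
Reported proportions zero out exposures below 1 % of the total and
renormalise — a parsimony heuristic, not a reimplementation of any
published attribution tool; the raw solution is also emitted, with the
relative L2 reconstruction error and cosine similarity.

## Expression scoring

All scores operate on log2(TPM+1); the +1 pseudocount is applied
uniformly, including inside geometric scores (the convention is ambiguous
in common usage; uniformity prevents mixed scales). Geometric signature
scores are plain means in log2 space. Gene z-scores use the sample
standard deviation (ddof = 1); constant genes are set to z = 0 with a
warning. The top-IQR filter keeps ceil(fraction·n) genes, ties broken by
gene symbol for determinism.

BM subtyping sums weighted z-scores over the subtyping gene panel;
score > 1.5 → BM1, ≤ 1.5 → BM2 (boundary to BM2). The weight vector is a
configuration asset read from TSV because the real weights originate in a
cited publication; the bundled generator weights are synthetic stand-ins.
Missing panel genes are imputed as z = 0 with a warning.

ssGSEA uses a Barbie-style statistic: genes ordered by decreasing
expression (average-rank ties, symbol tiebreak), score = Σ(weighted
in-set ECDF − out-set ECDF) with weights rank^0.25. Weights are functions
of ranks, not raw values, so scores are invariant under strictly monotone
transforms of a sample's expression.

Median splits label values ≤ median as low (ties low), median = midpoint
of order statistics for even n.

## Enrichment and survival

Gene ranking uses the signed Wald z from per-gene Cox fits — univariable
within an arm, or the product-term z from a gene×arm interaction model
between two arms; non-convergent genes are dropped with a log entry.
Preranked GSEA computes the max-deviation running-sum ES with |stat|^p hit
weights (p = 1 default), a gene-label permutation null (default 10,000,
seeded), p = (1 + #{same-sign permuted ES ≥ |ES|}) / (1 + #same-sign),
NES = ES / mean(|same-sign permuted ES|), and BH adjustment across
genesets. The sparse hit-position formulation is verified against a dense
position-by-position oracle.

Cox models use lifelines with Efron's tie approximation and two-sided
Wald tests; no proportional-hazards gating is applied. The interaction
test fits treatment + biomarker + product and reports the product term;
continuous biomarkers enter untransformed. KM medians are the earliest
time with Ŝ ≤ 0.5, reported as not-reached when the curve stays above 0.5.

## Synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes,
not any real cohort: three arms (~106 paired patients each by default,
matching a ~318-patient paired set); targeted-arm acquisition rates 1.7×
and 1.5× a control rate of 2 per month; per-patient rate heterogeneity
from a low/medium/high multiplier mixture (0.3/1.0/6.0 at weights
0.55/0.35/0.10), giving a rate continuum with a small tail above 20
mutations per month; truncated log-normal baseline VAFs (median 10 %,
σ = 1.2 on the log scale) with one truncal driver SNV defining maxVAF;
acquired VAFs at a mean 0.12 fraction of the EoT maxVAF (log-normal
spread), so the median clonality ratio sits well below the 0.3 subclonal
cutoff; per-(arm, origin) signature mixtures with SBS17a/b present only
in targeted-arm acquired spectra; immune, cell-cycle and BM expression
programs tied to per-patient latents (the cell-cycle latent correlates
with the acquisition rate; the immune latent drives the cytolytic genes);
and exponential proportional-hazards survival with arm effects, an
immune×triplet interaction (log-HR −0.8), simple covariates (ECOG,
log-CRP, organ count, prior irinotecan) and exponential censoring (~25 %).
Time on treatment is log-normal (median 4.5 months, σ = 0.6) — the
distribution is exposed in the config because no canonical choice exists.

SNV coordinates are placed on a 30 kb synthetic contig generated from the
seed, via a context index that realises any requested trinucleotide
channel on either strand; positions are unique within a patient so
alteration keys never collide. All randomness flows from one integer seed
through `numpy.random.SeedSequence` spawning, so a fixed config is
byte-identical across runs.

**What it does not emulate:** read-level sequencing noise, CHIP
artifacts, tumor phylogenies or copy-number structure, panel footprints,
batch effects, correlated gene–gene expression beyond the block programs,
and informative censoring. Passing recovery tests therefore demonstrates
the *estimators'* correctness and calibration under the assumed model,
not robustness to real-data pathologies.

## Problem sizes and numerical choices

Monte-Carlo calibration suites use: 100 two-arm cohorts of 200
patients/arm (pared generator config: baseline rate 2, single-component
mixture) for NB rate-ratio coverage; 500 count-level replicates for the
NB null rejection rate (the null concerns the estimator, so counts are
simulated directly); 100 generator-default cohorts of 6 patients/arm
(≥ 50 clonality ratios per status group) for the subclonality comparison;
100 replicates of 300/group exponential survival for Cox CI coverage; and
200 seeds for interaction-null uniformity. EM convergence tolerance is
1e-8 relative; NNLS is scipy's active-set solver; BH is the standard
step-up with monotonicity enforcement.

## Known limitations

Per-gene Cox ranking fits one model per gene in Python and is intended
for variance-filtered panels (hundreds of genes), not whole
transcriptomes. The NB fallback to Poisson widens no CI retroactively —
callers should check the `fallback` flag. The sparsity floor on signature
proportions is a reporting convention; exposures near the floor are
unstable by nature. Gene-permutation GSEA nulls ignore inter-gene
correlation, as all preranked approaches do.
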