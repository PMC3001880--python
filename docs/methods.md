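# Methods

This note documents the statistical procedures, the generative model behind
the synthetic cohorts, the defaults and why they were chosen, and the known
limitations of what the tests demonstrate.

## Analysis pipeline

**Scales and ordering.** All analysis runs on linear-scale intensities: the
expression cut-off (100) and the class means are linear-scale quantities,
and duplicate probes of a gene are averaged arithmetically on the linear
scale. The differential-expression caller alone works on `log2(x + 1)`
internally. The processing order is: inter-array normalization → collapse
of duplicate probes to gene symbols → per-species averaging across
individuals → expression filter → class statistics. Averaging precedes
filtering, so the filter consumes mean profiles, never raw matrices.

**Inter-array normalization.** The surrogate for full robust multichip
averaging is its between-array step, quantile normalization: every column
is mapped onto the mean of the sorted columns, ties receiving the midrank
average of the reference values they span. Normalization is applied
*within* each dataset (within a species' arrays; jointly across the
reference stage replicates) so that cross-species level differences — a
quantity the analysis reports — are not normalized away. A single-column
matrix is passed through unchanged with a warning. Note that with ties the
midrank convention makes column distributions identical only up to the
collapsed tied values.

**Expression filter.** A probe (gene) is excluded when its mean intensity
is below the cut-off in *both* species; a mean exactly at the cut-off
counts as expressed. The cut-off separates expression from leaky
background; the `--no-cutoff` mode reproduces the unfiltered variant of
the class-mean analysis. Fetal subtraction removes, by case-insensitive
gene symbol (the fetal dataset may come from a different platform), all
genes expressed above the cut-off in the fetal-testis profile; probes
without a symbol cannot be matched and are retained.

**Class statistics.** The class mean (AEL for all autosomes 1–22, XEL for
the X, kEL for a single autosome) is the arithmetic mean over the class's
per-probe means, with SEM computed across probes (matching the per-probe
averaging design; a single-probe class reports SEM 0 with a warning).
Y-linked and unplaced probes belong to neither AEL nor XEL. Contrasts use
the two-sided Wilcoxon rank-sum test: for ≤ 20 pooled values the exact
null distribution is enumerated (dynamic programming over doubled midranks
— equivalent to enumerating all `C(n, n_a)` assignments), counting
assignments whose rank sum deviates from the null mean at least as much as
observed; beyond that, the normal approximation with tie correction and a
0.5 continuity correction. No multiple-testing correction is applied
across the handful of class contrasts; raw p-values are reported at
α = 0.05 two-sided. The 22X:A ratio `22·n_x/n_a` is reported rounded
half-up to one decimal; raw values are retained for computation.

**Differential expression (stages and species).** Two-group comparisons
use a simplified moderated *t*: per gene, a pooled variance `s_g²` with
`d = n₁+n₂−2` degrees of freedom; a scaled-F prior `(d₀, s₀²)` fitted by
method of moments to the distribution of `log s_g²` (via the digamma /
trigamma identities of the log-chi-square; `d₀ = ∞` when the observed
spread of `log s_g²` does not exceed chi-square sampling noise); the
shrunk variance `(d₀s₀² + d s_g²)/(d₀+d)` — always between `s_g²` and
`s₀²` — and a *t*-statistic with `d₀+d` degrees of freedom.
Benjamini–Hochberg adjustment runs across genes, and a gene is called iff
`q ≤ 0.05` and `|log2 fold change| ≥ 1`; failing either threshold means
"unchanged". These thresholds are configuration, recorded in the
provenance output. With shrinkage disabled an ordinary Welch *t* is used;
when every gene has zero replicate variance (noise-free synthetic data)
shrinkage is impossible and calls are decided by the mean difference alone
(p ∈ {0, 1}) with a warning. Stage calls (BS→PS, PS→RS) are matched into a
target species by upper-cased gene symbol — the only orthology mechanism;
unmatched symbols are counted and logged, not resolved. Symbols whose
probes disagree on the chromosome take the majority label, ties going to
"other".

## Synthetic cohort model

The generator emulates the two-species whole-testis design: per-gene
baselines `b_g` drawn once from a log-normal (location 6.0, scale 1.0 on
the natural-log scale; median ≈ 400, so a realistic minority of genes falls
below the cut-off) and shared between species; four cell-type profiles per
species; whole-tissue individuals formed as
`(Σ_c w_c · profile_c[g]) · exp(ε)`, with `ε ~ N(0, noise_sd²)` independent
per gene × individual (`noise_sd` 0.2). The multiplicative log-normal noise
reflects positive, heteroscedastic microarray intensities. Defaults: 5
chimpanzee and 6 human individuals; composition 13% spermatogonia, 14%
spermatocytes, 48% spermatids, 25% somatic — the spermatocyte and spermatid
shares follow stereological counts of the spermatogenic epithelium, and the
remainder is split between spermatogonia and somatic cells, exposed as
configuration because the chimpanzee composition is not established.

The X chromosome model: somatically expressed X genes carry a two-fold
somatic upregulation; in spermatocytes X genes are reduced to the
*meiotic residual* of baseline (default 0.15 chimpanzee, 0.45 human) and in
spermatids to the *postmeiotic residual* (same defaults). The residuals
were chosen so the planted species difference is detectable by rank-sum
contrasts at the default cohort sizes across ~500 X genes; they are
configuration, not constants. Gene content is 500 genes per chromosome
label 1–22 and X, giving the X its genomic share (~1/23) — small enough
for seconds-scale tests, with real-scale counts available by configuration.

Stage programs plant 4-fold changes (1000 genes per program by default)
between BS→PS and PS→RS. "Up" program genes are stage-specific: they sit
at a background intensity (50, below the cut-off) outside their active
stages, and X-linked genes upregulated PS→RS *escape* postmeiotic
repression — the residual is not applied to them in spermatids, modelling
escapees rather than genes silenced and simultaneously upregulated. A
configurable fraction (default 0.5) of unprogrammed genes is
adult-germline-specific: expressed from spermatogonia onward but at
background in somatic cells and in the fetal mixture. The fetal-testis
profile mixes only the somatic and spermatogonial components (renormalized
weights), with germline-specific genes at background — so fetal
subtraction removes housekeeping/somatic genes and retains the
germ-cell-specific ones, as in the real design.

The reference stage dataset (BS/PS/RS, 4 replicates each) uses the same
gene universe with Titlecase symbols (mouse nomenclature, exercising the
case-insensitive matching) and its own residuals (default 0.1/0.1). The
planted truth returned with every simulation derives the expected up/down
sets from the *noiseless* stage means at the caller's fold-change
threshold: X genes silenced by the reference residual are genuinely
differential between stages, so the expectation is the planted programs
plus silencing-induced changes (and, e.g., MSCI overriding X "up" programs
in BS→PS).

All randomness flows from one integer seed through fixed, independent
sub-streams (gene table, probe table, per-species cohorts, stage
replicates, fetal replicates); identical configuration and seed reproduce
identical bytes, and the noise stream is consumed even at `noise_sd = 0`.
Mixtures accumulate cell types in sorted order, making the noise-free
mixture bit-for-bit equal to the correspondingly ordered weighted sum.

## Numerical choices and degenerate inputs

* Ratio and percentage rounding is half-up (`floor(10x + 0.5)/10`,
  `floor(x + 0.5)`), matching how the reported values are printed.
* Exact rank-sum p-values are computed on doubled midranks (integers), with
  a `1e-9` slack when counting equally extreme assignments; reported
  p-values are clipped into `(0, 1]`.
* Two identical groups give p = 1 and direction "none"; empty classes,
  disjoint probe universes, < 2 replicates per group, and invalid
  configurations raise typed errors naming the offending field.
* The trigamma inverse uses Newton iteration from the asymptotic start
  `x ≈ 0.5 + 1/y`; the prior fit falls back to `d₀ = ∞` (complete
  shrinkage) for homogeneous variances.
* Pipeline outputs are written only after all stages succeed; a failure
  aborts with the stage name and leaves no partial output. Tables are
  written with fixed float formats so seeded runs are byte-reproducible.

## What the tests do and do not show

Recovery tests demonstrate that the pipeline detects the planted silencing
structure under the model's assumptions: shared per-gene baselines between
species, purely multiplicative log-normal noise, identical cell-type
composition in both species, exhaustive annotation, and symbol-level
orthology with no gene gain/loss. Real cross-species microarray data
violate several of these (probe-affinity differences between species,
composition differences, annotation errors, platform effects between the
adult and fetal datasets), so passing tests validate the statistical
machinery, not the biological conclusion on any particular dataset.
Headline real-data magnitudes (absolute AEL/XEL levels, the published
differential-expression percentages and matched-probe counts) depend on
the original accessions and are outside what the synthetic cohorts are
meant to reproduce; the published stage-table ratios are reproduced from
their printed counts. The moderated-*t* caller handles two-group designs
only — no design-matrix or contrast machinery — and probe-sequence or
hybridization effects are not modelled.
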