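# Methods

This note documents the models and procedures the package implements, the
parameters that matter, the synthetic-data generators used to validate
them, and the numerical choices made where the design was open.

## Pan-PCD catalog and panel derivation

A *pan-PCD catalog* merges gene sets for individual programmed-cell-death
pathways (apoptosis, necroptosis, pyroptosis, ferroptosis, autophagy,
lysosome-dependent death, entotic death, NETotic death, parthanatos,
immunogenic death, anoikis, oxeiptosis, alkaliptosis) into a mapping from
gene symbol to its set of pathway memberships. Genes commonly belong to
several pathways (caspase-8 sits in apoptosis, necroptosis, and
pyroptosis), so the catalog stores full membership sets rather than a
primary pathway. Symbols are case-normalized to mouse title-case because
source collections mix human and mouse styles; GMT is the interchange
format because it is what the source databases export.

Panel derivation assumes log2-scale, already-normalized bulk expression
(FPKM-like or processed microarray values); the package deliberately does
no within-package normalization. The pipeline is:

1. **Moderated t-test** per acute time point (injured vs sham). Per-gene
   pooled variances s²_g (d = n_A + n_B − 2 residual df) are shrunk toward
   a prior (d₀, s₀²) estimated from the marginal distribution of log s²_g
   by moment matching: the excess variance of the log-variances over the
   trigamma(d/2) sampling term determines d₀ via a Newton-iterated
   trigamma inverse, and the mean determines s₀². The posterior variance
   is s̃²_g = (d₀s₀² + d·s²_g)/(d₀ + d) and the statistic has d₀ + d df.
   `prior_df=0` reduces exactly to the ordinary pooled t (verified to
   1e-10 in tests); `prior_df=inf` shares one variance across genes. The
   estimator agrees with the Bioconductor limma implementation to machine
   precision on heteroscedastic test matrices (cross-checked via Rscript
   in the suite). A gene with zero variance in both groups and zero logFC
   is reported with p = 1 by convention.
2. **DEG calling** at |log₂FC| > 1.5 and p < 0.05, both strict
   inequalities, unadjusted. Loosening either threshold can only add
   genes (a tested monotonicity property).
3. **Injury-responsive set**: the union of DEG calls over the acute time
   points (1/3/7 dpi), intersected with the catalog. Union rather than
   per-time-point intersection was chosen because the biological question
   is involvement at *any* acute phase; an `combine="intersection"` flag
   exposes the alternative.
4. **Cross-model rank-sum filter**: per candidate gene, a two-sided
   Wilcoxon rank-sum test of injured (all post-injury time points pooled;
   configurable) vs sham in each additional model, retaining p < 0.05
   (unadjusted — this step is a robustness filter, not an inference).
   Exact p-values when both groups have ≤ 10 samples without ties (the
   microarray regime), normal approximation with tie correction
   otherwise. Genes absent from a model's platform are dropped as
   untestable and reported, rather than silently retained.
5. **Cross-model intersection**, ordered alphabetically; an empty
   intersection is an error that reports the per-model set sizes.

## Single-cell scoring and stratification

**Recovery-curve AUC.** Genes are ranked within each cell (rank 1 =
highest). Sparse count data has a large block of tied zeros; ties are
broken by a *seeded random shuffle* because any deterministic tie order
(e.g. alphabetical) would bias panel genes systematically. The score is
the area under the early part of the recovery curve, normalized by its
maximum: score = Σ_{j≤k} R(j) / Σ_{j≤k} min(j, m) with k = ⌈f·n⌉. The top
fraction f defaults to 0.05, the documented default of the reference
rank-AUC tool; it is exposed as a parameter. The score depends on
expression only through ranks, hence is invariant under strictly monotone
per-cell transforms (tested), and lies in [0, 1] by construction.

**Module score.** Mean expression of panel genes minus the mean of
control genes drawn (seeded, with replacement, 100 per panel gene) from
the same equal-frequency average-expression bin (24 bins) — an
expression-matched null, so a panel indistinguishable from background
scores ≈ 0 and per-cell constant shifts cancel.

**Automatic threshold.** Scores of mixed populations are typically
bimodal (low-activity bulk plus a high-activity mode). A Gaussian KDE
(Silverman bandwidth, 512-point grid over the observed range) is scanned
for local maxima with density ≥ 5% of the global maximum; with ≥ 2 such
modes the threshold is the density minimum strictly between the two
highest modes, otherwise mean + 2·sd clipped to the range. This is a
concrete, auditable stand-in for the multi-heuristic "automatic"
threshold of the reference tool — the method used is always recorded in
the result. At least 50 cells are required for a stable density. *High*
means score strictly greater than the threshold.

**Slope statistic.** Per cell type, OLS of score on a 0/1
baseline/contrast indicator. With a binary covariate the OLS slope equals
the difference of group means exactly (asserted to 1e-12 against
statsmodels); p and the 95% CI use the t distribution with n − 2 df. All
post-injury groups are pooled into the contrast by default. Slope ratios
between arms use a percentile bootstrap (cell-level resampling within
each of the four groups, default 1000 replicates) rather than the delta
method, because score distributions are bimodal and non-Gaussian; a
denominator slope whose CI spans zero flags the ratio as unstable.

## Enrichment and connectivity screening

**Preranked enrichment.** Genes sorted by statistic descending (seeded
random tie-break); P_hit accumulates |statistic|^weight over panel genes
(weight 1 default, weight 0 = classic KS), P_miss accumulates misses
uniformly; ES is the signed maximum deviation. The null permutes gene
labels; NES divides ES by the mean |ES| of same-sign permutations, and
the p-value uses the add-one estimator (1 + #{same-sign |ES_π| ≥ |ES|}) /
(1 + #same-sign) to avoid p = 0 artifacts.

**KS connectivity.** For a tag set with ascending profile ranks V(1..t)
among n genes, a = max_j [j/t − V(j)/n] and b = max_j [V(j)/n − (j−1)/t];
ks = a if a > b else −b. The compound score is s = (ks_up − ks_down)/2
when the arms deviate in opposite directions and 0 otherwise (the classic
convention behind published ±100 connectivity scores); division by two
keeps raw s in [−1, 1]. Raw scores are library-scaled per sign so the
extremes map to ±100; scaling never changes a sign. Extremal tag
placements give |s| = 1 − O(t/n), approaching 1 for large libraries.

**Permutation p-values** draw random up/down tag sets of the observed
sizes (the null depends only on universe and arm sizes, so one null is
shared across a library run). Note a structural property: because the
same-sign rule sends about half of random tag-set pairs to s = 0 exactly,
the null has an atom at zero and the permutation p-value has an atom at
p = 1. KS-mode p-values are therefore *valid and conservative*
(P(p ≤ α) ≤ α, asserted over an α grid in the suite) but not uniform in
the strict distributional sense; the continuous Spearman
correlation-mode p-values are uniform under the null (asserted with a
Kolmogorov–Smirnov test on 200 simulated inert compounds). Both scoring
modes feed the same consensus rule.

**Consensus screen.** A compound passes when its scaled score is negative
with p < α (default 0.05) in *every* dataset (≥ 2 required; compounds
missing from a dataset are flagged and never pass); survivors are ranked
by ascending mean scaled score.

## Synthetic-data generators

The generators emulate the study conditions each stage is meant to
handle, with planted truth for calibration:

* **Bulk time course** — per-gene baselines Uniform(2, 10) log2 units,
  Gaussian noise sd 0.2 (a tight but realistic replicate noise for pooled
  RNA-seq/microarray log expression), injury effect +2.0 log2 units on
  responders, 3 replicates per arm, three models sharing a 30-gene core
  plus 10 model-specific responders each and 60 non-catalog background
  responders. Age-dependent attenuation is a per-time-point multiplier on
  the effect (persistent (1, 1, 1) vs attenuating (1, 0.4, 0.1) at 1/3/7
  dpi), mirroring the qualitative neonatal decay of the injury response.
* **Single-cell counts** — library sizes LogNormal(8.7, 0.35) (~6k UMIs),
  a fixed gamma-draw (dirichlet-like) abundance baseline over 2000 genes,
  negative-binomial counts (gamma-Poisson, dispersion 0.3). High-activity
  cells carry a 3-fold elevation of panel genes, with a quarter of the
  panel suppressed instead of elevated so group contrasts yield a
  two-armed up/down signature, as real adult-vs-neonatal panel contrasts
  do. High-cell prevalence defaults to 0.2 (sham) and 0.6 (injured),
  echoing the sham-to-injured rise the stratification is meant to
  resolve. The 2000-gene universe is a scaled-down transcriptome with
  proportionally realistic depth; it keeps the default suite fast while
  preserving the rank/tie structure the scorer must handle.
* **Score tables** — Normal per-cell scores (sd 0.03 around baseline
  0.12) with planted injured-minus-sham shifts per arm; the defaults
  (0.16 vs 0.02) plant an 8:1 slope contrast for ratio calibration.
  Shifts are planted directly on the score scale here because slope
  coverage is a property of the score distribution, not of counts.
* **Perturbation libraries** — reverser profiles −γ·query + noise, mimics
  +γ·query + noise, inert pure noise (γ = 1, noise sd 0.5), embedded among
  910 noise-only background genes; 5/2/43 compounds per library.

What the generators do **not** model: batch effects, ambient RNA,
doublets, gene–gene correlation beyond the planted signal, platform
differences between models, or compositional biases of real perturbation
assays. Passing recovery tests therefore demonstrates correctness of the
statistics and the pipeline plumbing under the stated generative
assumptions, not performance on real data.

## Numerical and design notes

* All stochastic routines take explicit seeds; generators are pure
  functions of their configs, and the end-to-end benchmark is
  byte-reproducible given the seed.
* The trigamma inverse uses Newton iteration from the 0.5 + 1/y starting
  point with asymptotic branches for extreme arguments; non-positive
  excess variance yields d₀ = ∞ (complete shrinkage), in which case the
  moderated statistic is referred to a normal distribution.
* Degenerate inputs have defined behaviour throughout: all-zero cells are
  an error naming the offending cells; identical scores degenerate the
  threshold to the common value (everything stratifies low); zero
  residual variance gives p = 1 for a zero slope and p = 0 otherwise; an
  all-zero score library scales to all zeros.
* The packaged catalog/panel fixtures are synthetic stand-ins at the
  literature cardinalities (963 genes / 13 pathways; 68 genes / 7
  pathways), seeded with real PCD genes and padded with `Pcds####`
  symbols; they validate I/O and counting contracts only.
* Benchmark problem sizes (2000 genes, 2000 cells per arm, 1000
  permutations/bootstrap replicates) were chosen so the full benchmark
  completes in well under a minute on one CPU while keeping Monte Carlo
  error far below the decision margins of the recovery checks.

## Known limitations

* The automatic threshold is one concretization of "automatic" bimodal
  thresholding; on strongly skewed unimodal score distributions the
  mean + 2·sd fallback is arbitrary and should be inspected via the
  recorded diagnostics.
* UCell-, singscore-, and ssGSEA-style scorers are not implemented; the
  two scorers provided (rank-AUC, module score) are the ones the headline
  analyses rely on.
* Correlation- and KS-mode connectivity scores are not numerically
  comparable across modes; consensus decisions should use one mode per
  screen.
* The moderated t assumes approximately normal log-scale expression
  within groups; raw counts should go through an upstream normalization
  first.
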