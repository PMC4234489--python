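# Methods

This note records the statistical model behind `cohub`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer would want to know.

## Pipeline model

The analysis assumes log-scale expression for `G` genes over `N` samples
drawn from several platforms, a binary case/control status, and three
partially observed binary tumor traits (grade low/high, type I/II, stage
early/late; controls always carry unknown traits, and grade G2 is
excluded from the binary grade contrast).

**Cross-platform normalization.** Platforms are merged on the
intersection of gene identifiers and every gene is z-scored within
platform using the population SD. This is a deliberate, simple stand-in
for model-based cross-platform normalization: it removes *gene-wise
affine* platform distortions exactly (shift plus scale per gene per
platform) and nothing more. Genuine platform-specific biology, probe
effects that are not affine on the log scale, and batch structure within
a platform are all outside its reach.

**Differential expression.** Welch's two-sample t statistic per gene
(pooled-variance mode available) with two-sided p-values and
Benjamini–Hochberg adjustment (via `statsmodels`). Two FDR thresholds
appear with different roles: 1% for reporting the DE gene count, 5%
(with fold change > 1.5) for admitting genes to the network. Because the
pipeline standardizes expression first, the fold-change cut is applied
to mean differences on that standardized log scale against
`log2(1.5) ≈ 0.58`; the dialect is configurable since fold-change
conventions differ between studies. Genes missing from the DE set are
admitted by descending variance until the target count (4,500 at study
scale; 450 in the down-scaled synthetic setting) is reached.

**Network construction.** Unsigned adjacency `a_ij = |r_ij|^β` from the
Pearson correlation matrix (signed variant available). The topological
overlap

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_u a_iu a_uj,   k_i = Σ_{u≠i} a_iu

is clustered by average linkage on `1 − TOM` (scipy), and modules are
the connected components of merges at height ≤ 0.95 with at least 100
members (a static cut; undersized clusters are "unassigned"). Modules
are named M1, M2, … by decreasing size, with the conventional color
aliases in the same order. Each module's eigengene is the first right
singular vector of its standardized member submatrix, sign-oriented to
correlate non-negatively with the members' mean profile. Eigengene–trait
association is Pearson's r over known-trait samples with the t-transform
p-value and Bonferroni correction across modules × traits. Per-gene
scores are the scaled intramodular connectivity `K = k_i / max k`
(computed within the gene's module, matching the hub notion of
intramodular centrality; whole-network scaling is an option) and gene
significance `GS(trait) = |cor(x_i, trait)|`.

**Choice of the soft power β.** The scale-free-topology criterion picks
the smallest β whose binned log–log connectivity fit reaches R² = 0.8.
Two robustness guards temper it, because the binned R² is a noisy
statistic and grows spuriously as the network empties at large β:
candidates whose mean connectivity falls below 5 are excluded (no module
of meaningful size can survive in a network whose average degree is a
handful), and a threshold crossing is trusted only when sustained over
two consecutive candidates (or at the final candidate). When no
candidate qualifies — networks dominated by a few planted modules are
genuinely not scale-free — the conventional sample-size default applies
(β = 6 for unsigned networks with more than 40 samples, larger for
smaller studies, doubled for signed networks) with a warning, rather
than chasing the best-fitting bin regression into a regime where the
static cut returns nothing. Every report records the β actually used.

**Hub triage.** For each trait, modules whose Bonferroni-adjusted
eigengene–trait p is below 0.05 are screened. The module's members form
the design matrix of an elastic-net logistic regression of the trait
(known-trait samples only), minimizing

    (1/n) Σ log-loss + λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²)

with α = 0.5 by default. Samples are resampled with replacement B = 1000
times (stratified by class so every replicate is fittable; plain
resampling with redraw-on-degenerate is available); on each resample λ
is chosen by 5-fold internal cross-validated deviance (a fixed-λ mode
exists for speed), and `f` counts the resamples where a gene's
coefficient is nonzero. The triage rule is the strict intersection
`f > 750` (upper quartile of B), `K > 0.25`, `GS > 0.2`. Where published
sources disagree on whether the GS cut is 0.2 or 0.25 (and K the other
way around), the (GS > 0.2, K > 0.25) version is used: it is the only
one consistent with the published table's own rows (entries with
GS = 0.21 and 0.22, and K = 0.26–0.27). All cuts are plain
configuration.

**Classification.** The distinct hub genes per trait form the signature.
Stratified 10-fold cross-validation produces one out-of-fold probability
per sample from elastic-net fits on each fold complement; AUC is the
Mann–Whitney concordance (ties counted ½, sklearn's implementation,
cross-checked in the tests against an all-pairs oracle), and
significance is a label-permutation p-value with add-one smoothing,
`p = (1 + #{AUC_perm ≥ AUC}) / (1 + n_perm)`. A validation-set mode fits
once on training data and scores an untouched study. The permutation
count defaults to 999 (199 inside the pipeline's manifest run).

**Enrichment.** Module over-representation against user-supplied GMT
gene sets by the upper hypergeometric tail, Bonferroni across all
module × set tests and BH within module. The universe defaults to all
network genes and must cover every module gene.

## Elastic-net solver

The penalized logistic model is fitted by IRLS (quadratic approximation
with probabilities clipped at 1e−5) with cyclic coordinate descent on
each weighted least-squares subproblem, glmnet-style: unpenalized
intercept, internal predictor standardization with coefficients mapped
back to the original scale, warm-started λ paths (20 log-spaced points
from λ_max down to λ_max/100), and active-set iteration between full
sweeps. The inner loops are numba-compiled. `λ_max = max_j |x̃_j^T (y −
ȳ)| / (n α)` reproduces the exactly-all-zero solution at and above the
boundary; a relative guard of 1e−12 at the soft-threshold keeps that
exactness under summation-order rounding. Solutions satisfy the
elastic-net KKT conditions to ~1e−10 at the default tolerance (1e−7 on
the maximum coefficient change) and match an independent solver
(sklearn saga) to ~1e−9. Inside the bootstrap, where only the active
set matters, the tolerance is relaxed to 1e−4; on the problems measured
this reproduces the identical chosen λ and active set at a quarter of
the cost.

## Synthetic studies

Each module m has one latent factor per sample,
`u_m ~ N(status_shift · case, 1)`; member genes are
`x = λ u_m + √(1−λ²) · noise_sd · ε` with λ = 0.7 for ordinary members
and 0.9 for the designated hubs (5 per module by default); background
genes are pure noise. Three modules of 150 genes plus 150 background
genes, 300 samples over two platforms, and a case fraction of 0.5 form
the default study. Each trait is drawn for cases only from a logistic
model on its driving module's factor (log-odds slope 2, centered within
cases), with 20% of case traits masked to unknown. Per-platform
distortions are gene-wise affine: shift `~ N(0, 0.5)` and scale
`exp(N(0, 0.2))`.

`status_shift = 1.5` (in factor-SD units) makes module genes
differentially expressed between cases and controls by about 0.9
standardized log-units — comfortably above the fold-change admission
cut, as expected of disease-associated modules, while leaving the
within-module correlation structure close to the loading products.
Identical seeds give byte-identical studies.

What the generator does **not** emulate: probe-level artifacts, scanner
noise, gene-length or GC effects, correlated background genes,
overlapping modules, heavy-tailed intramodular connectivity (all members
share one loading, so real networks' connectivity spread is flattened),
and traits with direct per-gene effects outside the factor structure.
Recovery results on these studies therefore demonstrate the machinery's
correctness under its own assumptions, not performance on real
microarray collections.

## Measured behaviour on the default studies

All numbers below are produced by the test-suite and
`scripts/acceptance.py`, not asserted from memory.

* Module recovery: adjusted Rand index between recovered and planted
  partitions ≥ 0.8 on 20/20 seeds (median ≈ 0.99); eigengenes correlate
  with their planted factors at |r| ≥ 0.98; the sample-size fallback
  β = 6 is selected on every default-study seed.
* Planted hubs have mean intramodular K ≈ 0.96 versus ≈ 0.33 for
  ordinary members, so the K cut separates them cleanly.
* The hub-signature classifier reaches cross-validated AUC ≈ 0.85–0.92
  with permuted-label AUC within 0.1 of 0.5.

## Known limitations

* **Selection frequency under collinearity.** The bootstrap elastic-net
  frequency f is a *conditional* selection measure. Within a module all
  members are proxies of one factor; once a few genes are in the model,
  the genes most correlated with the module consensus — precisely the
  high-loading hubs — add the least and are pruned first by the L1 part.
  Measured across the full (α, λ) plane on default studies (and verified
  against an independent solver), active sets contain only 1–3 of 5
  planted hubs even when two-thirds of the module is active, and hub f
  stays far below the upper-quartile cut while a few quasi-arbitrary
  members exceed it. Consequently the f cut identifies *trait-predictive
  module genes*, not necessarily the topologically central ones; it is
  the K cut that carries the hub-ness of the triage. This is the known
  instability of L1-type selection among exchangeable correlated
  features, and it is documented here rather than papered over.
* **Active-set monotonicity.** The number of nonzero coefficients along
  a decreasing-λ path is *not* guaranteed monotone (variables can leave
  the active set); a reproducible counterexample is exercised in the
  acceptance tests.
* The static cut has no dynamic-tree-cut refinement and no module
  merging by eigengene similarity; nested or adjacent modules will be
  merged or lost near the 0.95 height.
* The per-platform standardization removes affine distortions only; it
  is not a substitute for model-based cross-platform normalization on
  real data.
* Scaled-down problem sizes are used throughout the synthetic analyses
  (450 network genes, B = 100 bootstrap resamples with cuts scaled
  proportionally, 199–999 permutations); these were chosen so the full
  recovery analysis runs in about a minute while leaving every rate
  estimable.
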