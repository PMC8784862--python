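# Methods

## The testing problem

The sampling unit is the individual. For each gene we ask whether the
distribution of that gene's expression across an individual's cells differs
between groups of individuals (or along a continuous phenotype), adjusting
for cell-level covariates when estimating the distributions and for
individual-level covariates in the test. The procedure is distribution
estimation → pairwise distances → covariate-adjusted pseudo-F with a
permutation null. Because the test is rank-based over permutations, any
monotone rescaling of the distances (e.g. the JSD log base) leaves p-values
unchanged.

## Distribution estimation

**Parametric (default).** Counts of one individual's cells are modeled as
NB (or ZINB) with a log-linear mean in the cell covariates; the zero
inflation, when used, gets a logit link on the same covariates (an
intercept-only zero model is available via `zinb_infl="intercept"`). The
reported law is the conditional distribution at a reference covariate
vector, by default the per-covariate **median over all cells of all
individuals** — using one shared reference point is what makes distributions
comparable across individuals. UMI counts rarely need zero inflation, so the
fits use a fallback ladder

    ZINB → NB → Poisson → failed

with demotions triggered by non-convergence or boundary estimates: π̂ < 1e-4
collapses ZINB to NB, θ̂ > 1e4 (i.e. estimated NB variance within 0.01% of
Poisson) collapses NB to Poisson. All-zero or zero-variance count vectors,
and individuals with fewer than `min_cells` (default 10) cells, fail
outright. A gene is testable only if **every** individual has a non-failed
distribution; dropping individuals per gene would change n across genes and
make the permutation nulls incomparable, so such genes are reported with
status `fit_failed` instead.

**Discretization.** Parametric fits are compared after evaluation on a
common integer support 0..K, where K is the smallest integer leaving less
than 1e-6 upper-tail mass for every individual's fit, capped at
10·(max observed count + 1); the remaining tail mass folds into the top bin
so densities stay exactly normalized.

**Non-parametric.** log1p counts are regressed on the covariates by OLS and
each cell's adjusted value is the fitted value at the reference covariates
plus its residual (the pseudocount is +1; the choice only shifts the log
scale). Wasserstein distances use the adjusted values directly through the
one-dimensional quantile form; JSD uses a Gaussian KDE with Silverman's
rule-of-thumb bandwidth on a shared 512-point grid spanning both samples
± 3 bandwidths. Sparse low counts make this path unreliable (most mass sits
on a handful of log1p atoms), which is why the NB path is the default.

**Denoiser aggregation.** When an external denoiser provides per-gene
per-cell ZINB (or Poisson) parameters, an individual's distribution is the
equal-weight mixture of its cells' densities on 0..K. The sampling variant
(draw m counts per cell, default m = 5, and refit the NB regression) exists
for the case where cell covariates must still be adjusted; the direct
mixture is cheaper and is what the aggregation API computes.

## Distances

JSD uses the natural log (values in [0, ln 2]); Wasserstein-1 is the exact
sum of absolute CDF differences with unit bins on integer supports. Two
parametric fits are discretized on the larger of their two supports.
Distances below 1e-14 clamp to zero to absorb round-off. The n×n matrix is
filled on the upper triangle and mirrored.

## Test statistic and permutation scheme

Gower centering G = C(−½D∘D)C is followed by eigendecomposition and
truncation of negative eigenvalues at zero (distances from JSD are not
generally Euclidean-embeddable); after reconstruction the kernel is
re-centered exactly. The statistic

    F = tr(H_Z G H_Z) / tr[(I − H_Z) G (I − H_Z)]

projects on the **full** design (intercept, covariates, X), so covariates
with strong expression association are absorbed into the numerator rather
than inflating the residual — this is the difference from classical
PERMANOVA partitioning. The implementation computes F as t/(tr G − t) with
t = tr(Q′GQ) for an orthonormal basis Q of the design, which is what makes
reusing one G across hundreds of permutations cheap. A denominator below
1e-12 marks the gene `degenerate` (saturated design).

Permutation applies to the X column only; the kernel-reuse identity
(permuting X with G fixed equals relabeling G and the covariates by the
inverse permutation with X fixed) is asserted to 1e-12 in the tests. The
p-value is the add-one estimator (1 + #{F_b ≥ F_obs})/(1 + B), with ties
counted as exceedances (conservative; other implementations may break ties
differently). Numerical tie detection uses a 1e-9 relative slack. Defaults:
B = 999 (use 9999 for final analyses); when binary X admits at most B
distinct case/control assignments the engine enumerates them exhaustively
and the p-value is the exact proportion, observed assignment included.
Adaptive early stopping (on by default, `adaptive=False` to disable) halts a
gene after 100 permutations once the running p-value exceeds 0.5 — such a
gene can never approach conventional significance, and rejection decisions
at usual α are unchanged. Each gene's permutation stream is seeded from
(global seed, gene index), so results are bit-identical across reruns and
worker counts. `mode="resample"` redraws X given the covariates (logistic
fit + Bernoulli draws for binary X, fitted values + permuted residuals for
continuous X), which preserves X–covariate association but is unstable at
small n; plain permutation is the default. Binary designs with a group
smaller than 3 warn that few distinct permutations exist. An asymptotic
kernel-regression p-value path for large n is deliberately not implemented;
the config rejects `mode="asymptotic"`.

## Simulation framework

Each gene has a 4-dimensional multivariate-normal model of its latent
per-individual parameters (log mean, log overdispersion, logit zero
proportion, log of the sd of log cell mean). One draw per individual is
back-transformed; each cell's mean is log-normal around the individual's
mean with a −s²/2 correction so the average cell mean equals μ_i exactly;
counts are ZINB given the cell mean. Signal goes into the case group only:

* **meanDE** multiplies case μ_i by the fold (default 1.2), direction up or
  down per gene by a seeded fair coin;
* **varDE** re-solves the sd-of-log-mean channel so each case individual's
  per-cell expression **variance is multiplied exactly by the fold**
  (default 1.5) while the per-cell mean is unchanged — closed-form from the
  ZINB-log-normal moments, and verified against simulated moments in the
  tests. This channel is the one a pseudo-bulk mean cannot see, which is
  the point of the varDE condition. Which moment the variance fold should
  target was genuinely open; scaling total per-cell variance through the
  latent mean spread is the interpretation adopted here and is the single
  largest interpretive choice in the package.

Gene layout is meanDE first, then varDE, then EE. Read depth is the
realized column sum (no separate depth model), matching the fact that the
test conditions on observed depth. Zero-total cells are dropped exactly as
in a real analysis.

**Default model bank.** In place of parameters estimated from a real
cohort, `default_param_model` draws a bank of plausible gene models: latent
means uniform on log mean ∈ [−2, 2], log overdispersion ∈ [−1, 2], zero
logit ∈ [−3, 0], sd-of-log-mean ∈ [0.1, 0.6]; covariance is a random rank-2
factor plus diagonal (PSD by construction) with weak cross-correlations.
The across-individual latent SDs (0.05–0.15 on log mean, proportionally
smaller on the other channels) are calibrated so that individual-level mean
expression varies with roughly a 5–15% coefficient of variation within a
group — the modest residual inter-individual variability of depth-adjusted
pseudo-bulk expression in a homogeneous cell type, and the regime in which
the 20-sample pseudo-bulk NB Wald baseline is itself approximately
calibrated (its type-I error stays near nominal, as the study conditions
assume). Larger heterogeneity degrades everyone's power and makes the
ML-dispersion Wald baseline anti-conservative.

**What the simulator does not emulate:** multi-cell-type mixtures, doublets
and ambient RNA, batch effects beyond supplied covariates, gene–gene
correlation, and a separate read-depth model. Passing tests therefore show
correctness of the machinery and its operating characteristics under the
stated generative model, not performance on any real tissue.

## Baseline and summaries

The pseudo-bulk baseline sums each individual's counts and fits, per gene,
an NB regression with a log total-depth offset, reporting the Wald p-value
of the group coefficient (Poisson GLM fallback on non-convergence, NA if
that also fails). It is a deliberately plain mean-shift test — no dispersion
shrinkage or outlier moderation — because the comparisons here rely only on
its structural blind spot for variance-only signal, not on matching any
particular bulk tool's numerics.

Storey q-values fix λ = 0.5: π̂₀ = mean(p > 0.5)/0.5 clamped to (0, 1]
(floored at 1/m), step-down q_i = min_{p_j ≥ p_i} π̂₀·m·p_j/rank_j clamped
to [0, 1]; forcing π̂₀ = 1 reproduces Benjamini–Hochberg exactly (asserted
against statsmodels in the tests). The DE-proportion estimate is
1 − 2·mean(p > 0.5), clamped to [0, 1] since the raw formula can go
negative. The pseudo-dispersion θ̂ = μ̂²/(σ̂² − μ̂) inverts the NB
mean-variance relation; σ̂² ≤ μ̂ returns an infinite sentinel
(under/equi-dispersed). `scalar_permutation_test` runs the same
centered-kernel machinery on |v_i − v_j| of a per-individual scalar (mean or
pseudo-dispersion) — an exploratory, non-canonical reduction for asking
which moment carries a gene's signal.

## Input conventions and numerical choices

Counts are genes × rows in MatrixMarket MTX (with `genes.tsv` /
`barcodes.tsv` sidecars) or dense TSV; a cells × genes matrix must be
declared with the orientation flag, never auto-detected. Floats representing
integers (the MTX real dialect) are accepted to 1e-8; duplicated ids are an
error, not silently deduplicated. The gene filter keeps genes with nonzero
counts in ≥ 20% of cells (inclusive boundary). Log read depth is attached as
the `log_rd` cell covariate unless a column of that name exists; zero-total
cells are excluded with a warning before analysis since their log depth is
undefined.

## Problem sizes

The simulation studies in the test suite and acceptance script use 10 vs 10
individuals with 90 cells per individual for null calibration (300 EE
genes) and 360 cells for power (80–100 genes per condition), with 499
permutations — the sizes at which these operating characteristics are
stable desk-scale estimates. Larger designs (more individuals, 1080 cells,
9999 permutations) run through exactly the same code paths.

## Known limitations

* The non-parametric paths are unreliable for sparse low counts (by design
  they exist mainly for comparison).
* Binary X with severe group imbalance has few distinct permutations; the
  engine warns and enumerates, but resolution is limited.
* statsmodels' ZINB optimizer can be fragile on near-degenerate data; the
  fallback ladder makes this safe but means some truly zero-inflated genes
  are fitted as plain NB.
* Multi-level categorical phenotypes are only supported insofar as a single
  design column encodes them; no repeated-measures designs.
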