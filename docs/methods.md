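# Methods

## Problem and model

Omics association scans ask, for each of m features Y_j (taxa, metabolites,
genes), whether Y_j depends on a covariate of interest X (exposure, disease
status) after adjusting for confounders Z (age, sex, batch, BMI). The null
hypothesis per feature is conditional independence, H0,j : Y_j ⊥ X | Z; a
"signal" means conditional dependence. Features fall into four categories:
associated with both X and Z, with X only, with Z only, or with neither.
Features associated with Z only are the dangerous ones — they are marginally
correlated with X whenever X and Z are entangled, so confounder-blind
screening (e.g. BH on marginal p-values) rejects them wholesale. The package's
`bh_marginal` comparator exists to demonstrate exactly this failure.

The procedure implemented here uses *two* statistics per feature:

* T^M_j — a marginal independence statistic for Y_j vs X, ignoring Z;
* T^C_j — a conditional independence statistic for Y_j vs X given Z;

both oriented so large values are evidence against the respective null. The
rejection region is a rectangle: reject j iff T^M_j ≥ t1 and T^C_j ≥ t2. The
marginal axis screens out the large mass of features associated with neither
X nor Z, which concentrates the multiple-testing burden on fewer features and
lets the conditional cutoff drop. When the marginal statistic carries no
useful information the selected t1 falls to the sentinel (see below) and the
procedure reduces to ordinary one-dimensional FDR control on T^C — the data
decide whether the auxiliary axis helps.

## Null calibration by covariate resampling

The joint null law of (T^M_j, T^C_j) is intractable in general, but under
H0,j the conditional law of X given (Y_j, Z) equals its law given Z alone.
So, holding Y and Z fixed, replicates X̃_b ~ P̂(X|Z) (b = 1..B) regenerate
the statistic pair under the null. With (T^M_{j,0}, T^C_{j,0}) the observed
pair, the per-feature null exceedance probability is estimated by

    Fbar_{j,B}(t1,t2) = (1/(B+1)) Σ_{b=0..B} 1{T^M_{j,b} ≥ t1, T^C_{j,b} ≥ t2},

whose add-one self-inclusion makes the estimate conservative. The FDP
estimate at a cutoff pair is

    FDP~(t1,t2) = π̂0 · Σ_j Fbar_{j,B}(t1,t2) / max(1, #{j: T^M_j ≥ t1, T^C_j ≥ t2}),

with the Storey-type null-proportion estimate

    π̂0(λ) = min(1, #{j: T^C_j ≤ λ} / Σ_j F_{j,B}(λ)),  F_{j,B}(λ) = (1/(B+1)) Σ_b 1{T^C_{j,b} ≤ λ}.

The selected cutoffs maximize the rejection count over a grid subject to
FDP~ ≤ q; ties are broken deterministically (smaller FDP estimate, larger t2,
larger t1) so runs are seed-reproducible.

### Cutoff grid

The search grid uses ν evenly spaced order statistics per axis (ranks
⌈i·m/ν⌉, i = 1..ν, of the observed statistics). The marginal axis
additionally contains a sentinel at 0: statistics are non-negative, so t1 = 0
rejects nothing on the marginal axis and the sentinel column *is* the 1D
procedure. This makes the finite-sample dominance property structural — the
2D search space contains the 1D one, so the 2D procedure can never reject
fewer features at the same q, B, and seed. ν defaults to 100 (a 101 × 100
surface), a resolution at which the surface cost is negligible next to the
(B+1)·m statistic evaluations. The surface is computed exactly by a 2D
histogram of all (B+1)·m statistic pairs followed by suffix sums, not by
per-cell loops.

### Statistic engines

* **glm** — Wald |z|/|t| statistics for the X coefficient: T^C from the
  confounder-adjusted fit g(E[Y_j]) = α_j X + β_j'Z, T^M from the reduced fit
  without Z. Families: gaussian/identity, binomial/logit, poisson/log.
  Categorical X emits the square root of the block Wald chi-square so every
  engine returns one non-negative scalar per feature. Fitting is a batched
  IRLS Newton iteration carried over all features at once (the design matrix
  is shared; only the outcome column differs), validated against statsmodels
  GLM per-feature fits in the test suite. Features that fail to fit
  (separation, divergence, zero residual variance) get statistic 0 — never
  rejected — with a logged warning, so one pathological feature cannot abort
  a 1000-feature scan.
* **rv** — the RV matrix-correlation coefficient, which reduces to the
  squared Pearson correlation for univariate pairs. T^C is the RV of the
  residuals of X and Y_j from natural cubic spline regressions on Z
  (`spline_df` basis columns per continuous confounder, default 4; indicator
  contrasts for categorical confounders; `spline_df=1` is plain linear
  adjustment). In the linear-gaussian case the rv and glm conditional
  statistics are both monotone in the squared partial correlation, so their
  feature rankings coincide (asserted in tests with spline_df=1).
* **hsic** — biased empirical HSIC with Gaussian kernels, bandwidth set by
  the median heuristic on standardized variables (zero distances excluded
  from the median). The conditional version residualizes the centered X and
  Y kernels against the Z kernel through the Tikhonov-regularized operator
  R = G_Z (G_Z + nεI)^{-1}, P = I − R:  T^C_j = tr(P G_X P · P G_{Y_j} P)/n²,
  with ε = 0.001 by default. Both statistics are traces of products of PSD
  matrices, hence non-negative. This regularized-operator construction is
  this package's committed design for a conditional HSIC; other conditional
  HSIC variants exist.

### Conditional-law estimators

`fit_conditional` supports gaussian_linear and gaussian_spline regressions
for continuous X (normal draws around the fitted mean, residual SD estimated
with the fitted degrees of freedom; an optional residual bootstrap resamples
the centered empirical residuals instead), logistic / multinomial ML fits for
binary / categorical X (ridge-penalized fallback under separation), and plain
permutation (valid only when X ⊥ Z). Defaults by covariate kind: continuous →
gaussian_linear, binary → logistic, categorical → multinomial.

The estimate of P(X|Z) must be adequate for validity: in the nonlinear
benchmark (X ~ N(ρZ², 1)) the gaussian_linear sampler misses the quadratic
conditional mean and the empirical FDR inflates to ≈0.24 at ρ = 1.5, whereas
gaussian_spline restores control (≈0.01–0.03). The benchmark study therefore
pairs the nonlinear scenario with the spline sampler, mirroring the spline
residualization inside the RV statistic. Users facing possibly nonlinear
X–Z relationships should prefer gaussian_spline; it costs nothing when the
relationship happens to be linear.

All randomness lives in `sample_covariates`; statistic computation is
deterministic. The generator streams for data simulation and for covariate
resampling are salted differently, so passing the same integer seed to both
cannot alias them (an aliasing of this kind produces bootstrap noise exactly
equal to Z and silently corrupts the calibration).

### B, λ, and other defaults

* B defaults to 100 for interactive use; the replicated benchmark studies use
  B = 50 per run (resolution 1/(B+1) ≈ 0.02 of Fbar is sufficient at
  q = 0.05) and final single-dataset inference is better served by B = 500.
* λ (the Storey anchor) defaults to the median of the pooled resampled
  conditional statistics — a null-quantile anchor that adapts across engines
  whose statistics live on different scales (|t| vs RV in [0,1] vs HSIC).
  π̂0 is capped at 1 and returns 1 with a warning when the denominator is 0.
* `use_pi0` is on by default; switching it off gives the unweighted
  (more conservative) FDP estimate.
* Constant features are dropped before inference with a logged manifest;
  m = 0 returns an empty result.

## FWER variant

The family-wise variant replaces the FDP estimate by the any-hit fraction

    FWER^(t1,t2) = (1/(B+1)) Σ_{b=0..B} 1{∃ j: T^M_{j,b} ≥ t1, T^C_{j,b} ≥ t2}

and would select the max-rejections cell with FWER^ ≤ α. Simulation showed
the naive version of this rule badly inflated (empirical FWER 0.27 at
α = 0.05): the adaptive search over ~ν² cells carries multiplicity no
per-cell estimate can see, and a grid anchored on the observed order
statistics places the observed pairs exactly on cell corners — an advantage
the resampled rows do not have (the latter leak alone raised a provably
exact permutation null to 0.065). The implementation therefore (i) builds
the grid from pooled order statistics of all B+1 rows, and (ii) calibrates
the working level: for each row r let e_r be the smallest FWER^ over cells
at which row r's pairs would produce a rejection; the working level α' is
the largest value such that #{r: e_r ≤ α'} ≤ ⌊α(B+1)⌋. Both the grid and α'
are symmetric functions of the exchangeable rows, so P(e_0 ≤ α') ≤ α holds
exactly under the global null when the sampler is exact, and approximately
under the plug-in sampler. Measured: 0.05 under an exact permutation null
(theoretical bound 0.039 + Monte-Carlo noise), 0.04 with the fitted gaussian
sampler, both at α = 0.05.

## Synthetic-data generator

The generator reproduces the benchmark designs: coefficients α_j, β_j i.i.d.
from the spike-and-slab mixture (π/2)·U(−l−0.2, −l) + (π/2)·U(l, l+0.2) +
(1−π)·δ0, confounder Z ~ N(0,1), and

| model     | outcome                                  | covariate          |
|-----------|------------------------------------------|--------------------|
| linear    | Y_j = α_j X + β_j Z + ε, ε ~ N(0,1)      | X ~ N(ρZ, 1)       |
| nonlinear | Y_j = α_j X³ + β_j e^Z + ε               | X ~ N(ρZ², 1)      |
| logistic  | Y_j ~ Bern(expit(α_j X + β_j Z))         | X ~ N(ρZ, 1)       |
| poisson   | Y_j ~ Pois(exp(α_j X + β_j Z))           | X ~ N(ρZ, 1)       |
| example1  | as logistic, coefficient mixture 0.15/0.15/0.7 with U(±(0.5,0.7)) | X = (ρZ+ε)/√(ρ²+1) |

X is standardized to zero mean and unit variance after generation, so the
effect size l and the confounding strength ρ can be varied independently
(otherwise Var(X) grows with ρ and entangles the two factors). Standardizing
is an affine map and leaves cor(X, Z) = ρ/√(ρ²+1) in the example1 design
(0.10, 0.45, 0.71 at ρ = 0.1, 0.5, 1). Default sizes are n = 100 and
m = 1000 with the factor grid ρ ∈ {0.1, 1, 1.5}, π ∈ {0.05, 0.10, 0.20},
l ∈ {0.2, 0.3, 0.4}.

What the generator does *not* emulate: dependent errors across features,
compositionality and zero-inflation of real count tables, heavy-tailed or
heteroscedastic noise, multivariate X, or batch structure in Z. Passing the
simulated FDR/power checks therefore demonstrates correctness of the
procedure under independent-feature, correctly-specified-sampler conditions,
not robustness to every failure mode of real omics data. The bootstrap
calibration itself makes no independence assumption across features in its
FDP estimate, but the empirical checks here do not exercise strong
cross-feature dependence.

## Problem sizes in the shipped studies

The replicated studies run at n = 100, m = 200–500, B = 40–50, 15–100
replicates per cell with fixed seeds — sizes chosen so the full factorial
slice still estimates rates with usable Monte-Carlo error (binomial SE ≈
0.007–0.03 on FDR at 50 replicates). All rate assertions allow two
Monte-Carlo standard errors. The acceptance script reports empirical FDR
from 50 replicates per cell at m = 500, B = 50.

## Preprocessing helpers

For microbiome count tables: a prevalence filter that removes features
present in strictly less than a given fraction of samples (a feature at
exactly the threshold is kept), and a centered log-ratio transform
log(count + pseudocount) − sample mean log (pseudocount 0.5 by default),
after which each sample row sums to zero and outcomes are treated as
gaussian.

## Numerical choices and edge cases

* Exceedance counts use ≥ semantics throughout; tied features cross a
  threshold as a block.
* The 2D surface histogram uses `searchsorted(side="right") − 1`, which is
  exact for ≥ thresholds (no floating-point fudge factors).
* IRLS: max 40 iterations, step tolerance 1e-9, divergence declared when the
  linear predictor exceeds 30 in absolute value (separation); singular
  information → feature marked failed.
* Natural cubic spline basis: truncated-power construction with df+1 knots
  at evenly spaced quantiles; ties collapse knots, degrading gracefully to
  linear.
* Constant confounder columns are dropped from the encoded design with a
  warning (the no-confounder limit) rather than failing the rank check;
  genuinely collinear designs are a hard error naming the offending columns.
* Residualization designs are QR-pruned so projections span exactly the
  intended column space even when a basis column degenerates.

## Known limitations

* Validity under a *misspecified* conditional-law estimate is not guaranteed
  (demonstrated concretely by the linear-sampler/nonlinear-truth FDR
  inflation above); the package provides spline and residual-bootstrap
  escapes but no diagnostic test for sampler adequacy.
* The HSIC conditional statistic is one committed regularized-operator
  construction, not the only possible conditional HSIC.
* The FWER variant's exactness argument assumes the oracle sampler;
  plug-in estimation error is only checked empirically.
* Multivariate continuous X is supported by the engines but the gaussian
  samplers model columns independently given Z.
* p-values are never produced for the 2D procedure (it controls FDR through
  resampling, not through per-feature p-values); the BH comparator requires
  p-values supplied by the caller or the marginal-GLM helper.
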