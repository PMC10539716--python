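# tdfdr

Two-dimensional FDR control for confounder-adjusted omics association
testing.

## The problem

Given a feature-by-sample omics table Y (taxa, metabolites, gene
expression), a covariate of interest X (exposure, disease status) and
confounders Z (age, sex, batch), the task is to find the features that
depend on X *conditionally on* Z, with false discovery rate control. The
standard pipeline — fit a confounder-adjusted model per feature, correct the
p-values — adjusts every feature for Z even though confounders typically
touch only a subset, and pays for it in power, most severely when X and Z
are strongly entangled.

This package implements a two-dimensional procedure that uses the *marginal*
association statistic T^M_j (Y_j vs X, ignoring Z) as an auxiliary screen
and the *conditional* statistic T^C_j (Y_j vs X given Z) as the primary
evidence. A feature is rejected when T^M_j ≥ t1 and T^C_j ≥ t2. The cutoff
pair is chosen to maximize discoveries subject to an estimated false
discovery proportion staying at or below the target q:

    FDP~(t1,t2) = pi0_hat * sum_j Fbar_j(t1,t2) / max(1, R(t1,t2)),

where R counts rejections and Fbar_j is a bootstrap estimate of the
probability, under H0,j, that feature j's statistic pair lands in the
rejection rectangle. The bootstrap resamples the covariate from a fitted
conditional law P(X|Z) — under the null that is exactly the conditional
distribution of X given everything else — so no model for Y given (X, Z) is
ever needed. pi0_hat is a Storey-type estimate of the null proportion. The
one-dimensional procedure (cutoff on T^C only) is a member of the 2D search
space by construction, so the 2D procedure never rejects fewer features at
the same q, B, and seed.

Statistic engines: GLM Wald statistics (gaussian/binomial/poisson outcomes),
the RV coefficient on spline-residualized data (continuous outcomes), and
HSIC with Gaussian kernels (nonparametric). A family-wise error variant and
a Benjamini–Hochberg comparator are included, as are microbiome
preprocessing helpers (prevalence filter, CLR transform) and a synthetic
data module that reproduces the standard confounded benchmark designs.

See `docs/methods.md` for the full model description, estimator definitions,
defaults, and limitations.

## Worked example

Simulate the strongly confounded linear benchmark (X ~ N(1.5·Z, 1),
Y_j = α_j X + β_j Z + ε_j, 10% of features carrying true effects) and
compare the 2D procedure with its 1D counterpart over 10 replicates:

```
$ tdfdr simulate --model linear --rho 1.5 --pi 0.1 --l 0.4 \
      --n 100 --m 300 --reps 10 --b 50 --seed 7
2D (rv): FDR=0.0698±0.0268 power=0.5715±0.0484
1D (rv): FDR=0.0335±0.0181 power=0.2480±0.0502
```

Both procedures keep the empirical FDR within Monte-Carlo noise of the
nominal q = 0.05 (0.0698 is ~0.7 SE above it), while marginal screening
more than doubles power (0.57 vs 0.25): under strong confounding the
conditional statistic alone separates signal from noise poorly, and the
marginal axis removes enough irrelevant features that a lower conditional
cutoff reaches the same FDR.

Analyzing your own tables:

```
$ tdfdr run --features otu_counts.tsv --metadata samples.tsv \
      --covariate smoking --confounder sex \
      --prevalence 0.10 --clr --engine rv --q 0.05 --b 500 --seed 1 \
      --outdir results/
```

writes `results/results.tsv` (per-feature statistics and rejection flags for
the 2D and 1D procedures) and `results/run_metadata.json` (selected cutoffs,
pi0, and every parameter actually used). The same functionality is available
as a library: `tdfdr.run_2dfdr(Y, X, Z, engine="rv", q=0.05, B=500, seed=1)`.

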