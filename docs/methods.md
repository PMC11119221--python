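# Methods

## Model family and candidate space

All candidates are Gaussian linear mixed models for observations nested in
one grouping factor:

    y_ig = x_ig' β + z_ig' b_g + ε_ig,
    b_g ~ N(0, Ψ),   ε_ig ~ N(0, σ²),

with z the random-effect design (intercept, plus any random slopes) and Ψ
unstructured, so intercept and slope deviations may correlate. The
exploration space is defined by one full model: free fixed effects (the
terms toggled on/off), forced covariates (kept in every candidate), one
grouping variable, and the subset of free terms eligible as random slopes.

Admissibility rules, enforced everywhere:

- a random slope requires its fixed effect in the same model;
- random slopes always come with a random intercept (no `(0 + x | g)`);
- forced covariates are never slope candidates;
- one grouping factor; additive terms only (no interactions, transforms,
  nested or crossed groups).

Under these rules each slope-eligible free predictor is independently
absent / fixed-only / fixed-with-slope while the rest are absent/present,
giving the closed-form count `2^f + 2^(f-s)·3^s` with a group and `2^f`
without. Enumeration order is stratified (fixed-only, random-intercept,
random-slope), subsets by increasing size with declaration-order
tie-breaks, so listings are byte-stable. Within-stratum order for larger
spaces is a package convention; the count, not the order, is the
substantive quantity. A safety ceiling (default 10 000 candidates) guards
against accidental exponential blow-ups and can be overridden explicitly.

## Estimation

Everything is **maximum likelihood**, never REML: the sweep compares
models with different fixed-effect sets, and REML likelihoods are not
comparable across those. The CLI recognizes a `--reml` flag only to warn
and proceed with ML.

Fixed-effects-only candidates are OLS with the ML variance divisor
(σ̂² = RSS/N), giving the closed-form log-likelihood
−(N/2)(ln 2πσ̂² + 1).

Mixed candidates maximize the profiled marginal likelihood. With
Ψ = σ²ΛΛ′ (Λ lower-triangular, diagonal ≥ 0) and W_g = I + Z_gΛΛ′Z_g′,
β̂ is generalized least squares and σ̂² = Σ r′W⁻¹r / N, leaving a search
over only the q(q+1)/2 entries of Λ. Per-group quantities are computed
through the Woodbury identity on precomputed cross-products (Z′Z, Z′X,
Z′y, X′X, X′y, y′y), so one deviance evaluation costs a q×q Cholesky per
group regardless of group sizes.

Numerical choices:

- optimizer: L-BFGS-B with bound Λ-diagonals ≥ 0; deterministic start
  Λ = 0.5·I; relative-deviance tolerance 1e−8; 500 iterations max;
- singularity: any |Λ_jj| < 1e−4 flags the fit `singular` (a variance
  component at the boundary); the fit is kept, not discarded;
- non-convergence is recorded (`converged=False`), never raised: an
  exhaustive sweep must not die on one ill-conditioned candidate. Ranking
  places NaN-criterion rows last;
- degenerate inputs raise described errors: rank-deficient designs, N ≤ p,
  perfect fits (σ̂² ≈ 0, likelihood unbounded), single-level group columns;
- ties in ranking break by fewer parameters, then formula string, making
  the sort total and reproducible.

Categorical predictors are expanded by treatment coding (first sorted
level as reference) at fit time; a categorical term counts as one term for
enumeration but contributes (levels−1) coefficients to the parameter
count.

Information criteria use the standard penalized forms AIC = −2LL + 2k and
BIC = −2LL + k·ln N with N = number of observations (not groups) and
k = fixed coefficients + q(q+1)/2 covariance parameters + 1 residual
variance. This parameter-counting convention matches the usual
mixed-model log-likelihood degrees of freedom and is applied
self-consistently everywhere.

Missing data are removed by listwise deletion over the *full* model's
columns once, before the sweep, so every candidate is fit on identical
rows — information criteria are incomparable otherwise.

## Parallelism contract

Work is partitioned by candidate index (joblib processes) and results are
reassembled in enumeration order. The output table is therefore identical
— row order exactly, values to 1e−10 — for any worker count; parallelism
is an implementation detail, not a semantics change, and elapsed time is
recorded as metadata only.

## Bayes-factor cross-validation

Criterion nominations are cross-checked with Bayes-factor arithmetic on
the natural-log scale. Two models are compared through log BFs against a
shared baseline (conventionally the forced-covariates-only null):
2·(ln BF_A0 − ln BF_B0), read on the Kass–Raftery bands — |2 ln BF| < 2
weak, [2, 6) positive, [6, 10) strong, ≥ 10 very strong — with the sign
carrying the direction of support.

When bridge-sampled BFs are unavailable the Schwarz approximation
ln BF ≈ (BIC_baseline − BIC_model)/2 converts exploration BICs into
approximate evidence. Caveats: it assumes unit-information priors and
large N, and it is a monotone transform of BIC — rankings by approximate
BF and by BIC coincide by construction, so the approximation adds
interpretability, not an independent ordering. Fully Bayesian model BFs
(bridge sampling, explicit priors, posterior model probabilities) are out
of scope.

## Synthetic data generator

`simulate_dataset` draws standard-normal predictors (optionally uniform
categoricals), per-group effect vectors b_g ~ N(0, Ψ) via eigendecomposition
(tolerating semi-definite Ψ, e.g. exactly-zero variance components), and
y = Xβ + Zb_g + ε. Generation is deterministic given the seed.

`study_shaped_spec` mirrors the layouts of three multi-country COVID-19
survey studies the method was demonstrated on: 2/4/7 free predictors,
6/2/3 forced demographic covariates, 43/43/62 countries — yielding
candidate spaces of 13, 97 and 2315. Default coefficients are arbitrary
but documented (0.5 free, 0.2 forced, intercept SD 0.5, slope SD 0.3,
residual SD 1); group sizes default to 50 so a full sweep takes seconds,
far below the studies' ~15–21k participants, which are carried as
metadata only.

What the generator does **not** emulate: the real studies' item scales,
empirical predictor distributions and correlations, missingness patterns,
or unbalanced country sizes. Passing recovery tests therefore demonstrate
the machinery is correct under the stated generative model — they do not
certify nominations on any particular real dataset, where effects are
weaker and predictors collinear.

## Test problem sizes

Recovery tests use 40 groups × 100 observations with slope SD equal to
residual SD (a strong but plausible heterogeneity level) over 20 seeded
replicates; the variance-recovery check averages 5 replicates of
40 × 50 because a single realization of a variance component with 40
groups has ~25% sampling error by itself. The independent likelihood
oracle runs on a 30-row, 3-group fixture where dense N×N algebra is
trivially cheap. These sizes keep the full suite under a minute while
leaving the statistical conclusions stable.

## Known limitations

- Single grouping factor; no crossed/nested random effects, interactions,
  non-Gaussian responses, AICc, or p-value-based selection (the last by
  design, not omission).
- Exhaustive enumeration is exponential in the free predictors; beyond
  ~13 free slope-eligible predictors the sweep is impractical on one
  machine regardless of per-fit speed.
- The Λ parameterization makes variance-component boundaries benign but
  renders the profiled deviance non-smooth exactly at the boundary;
  L-BFGS-B handles this in practice, and boundary fits are flagged rather
  than polished further.
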