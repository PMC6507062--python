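# Methods

This note records the models, conventions and numerical choices behind the
package, and what the simulation-based tests do and do not establish.

## Model and scope

All fits assume a proportional-hazards model
`h(t|X) = h0(t) exp(β'X)` for right-censored data, estimated by maximizing
the Breslow partial likelihood. One shared Newton engine (`oehr._cox`)
performs every fit in the package — the penalized spline fit, the
categorical refits inside the cut-point search, the linear fit of the
nonlinearity test, and the D-statistic fit — so that AIC values compared
across fits are on a single likelihood scale. Ties are handled by the
Breslow approximation throughout; the simulation engine produces
continuous times, so ties only arise in user data. The engine uses damped
Newton steps (step-halving on the penalized objective, which is concave)
and declares convergence when the max-norm of the penalized score falls
below 1e−6. Time-varying effects and violations of proportional hazards
are out of scope.

## Penalized spline fit of the log relative hazard

The effect of the continuous predictor x is `f(x) = B(x)'θ` with a cubic
B-spline basis on 22 evenly spaced knots spanning the observed range,
extended (not clamped) past the boundaries so every basis function is a
uniform translate — with this construction the null space of the
second-order difference penalty `P = D₂'D₂` corresponds to functions linear
in x, and the heavy-smoothing limit of the fit is exactly a linear Cox fit.
The basis has 24 columns.

The partial likelihood is invariant to adding a constant to the linear
predictor, and the basis rows sum to one, so θ is estimated in the subspace
orthogonal to the constant coefficient vector (an orthonormal complement
`Z`, θ = Zγ). Adjustment covariates enter linearly and unpenalized. The
penalized objective is `pl(θ) − (s/2)·θ'Pθ`.

* **Effective degrees of freedom**: `edf = tr[(H + sP)⁻¹H]`, with H the
  unpenalized negative Hessian at the solution, computed in the
  identifiable parametrization; `AIC = −2 pl + 2 edf`.
* **Smoothing selection**: grid search minimizing AIC over 25 log-spaced
  weights. The endpoints are placed adaptively so the grid spans edf ≈ 15
  down to ≈ 2, using the generalized eigenvalues of (P, H) from a pilot
  fit, for which `edf(s) = Σ 1/(1 + s·dᵢ)` is cheap to invert. Ties go to
  the larger (smoother) weight. Grid fits are warm-started from the
  previous solution.
* **Reporting**: the fitted curve is centered to mean zero over the
  observed x; prediction outside the observed range is refused rather than
  clamped, which keeps the cut-point search inside the support.

**U-shape diagnostic.** The curve is sampled on 200 points over the central
90% of x (splines wiggle at the boundaries); it is declared U-shaped iff
its first differences change sign exactly once, from negative to positive.
A nonlinearity p-value accompanies the flag: chi-square on
`2(pl_spline − pl_linear)` with `edf − 1` degrees of freedom (minus the
covariate count when adjusting). This is a pragmatic scale-matched test,
not an exact reference distribution; it is reported for screening, and the
graphical curve remains the primary diagnostic. The flag is conservative by
construction: a genuinely U-shaped truth can be flagged `false` on a
replicate whose AIC-selected curve keeps a small boundary wiggle, which is
why the search functions accept an explicit override.

## The equal-HR cut-point search

Candidate levels are the 5th–95th integer percentiles (linear-interpolation
/ type-7 convention, used for all percentiles in the package) of the n
fitted `log λ̂` values at the observations. For each level the horizontal
line is intersected with the curve evaluated on a 2001-point grid; on each
arm the crossing *adjacent to the valley* is taken (innermost crossing), so
small boundary wiggles cannot hijack the pair. The observation nearest in x
to each intersection (on its side of the curve minimum; ties broken by
closeness of its fitted value to the level) forms the candidate pair; if
the two observations' fitted values differ by more than 0.01, the pair is
replaced by the interpolated curve points themselves, which share the level
exactly. Levels that do not cross both arms are dropped; duplicate pairs
are deduplicated, leaving at most 91 candidates.

Each candidate pair induces low/middle/high groups (`x < c₁`,
`c₁ ≤ x ≤ c₂`, `x > c₂`; middle is the reference level) and a two-dummy Cox
refit with `AIC = −2 pl + 2k` (k = number of estimated coefficients; BIC
uses `log(number of events)`). Groups smaller than 5% of n are rejected —
an unguarded search can otherwise return degenerate groups. The returned
pair minimizes the criterion; exact ties go to the pair with more balanced
group sizes (smaller standard deviation of group counts).

## Comparators

* **Median / Q1Q3**: cuts at the empirical 50th, and 25th/75th,
  percentiles.
* **minP (maximally selected log-rank)**: the split `x ≤ c` over candidate
  values of x between its 10th and 90th percentiles maximizing the absolute
  standardized log-rank statistic. The statistic is the linear rank
  statistic of the log-rank (Savage) scores `aᵢ = dᵢ − Λ̂(tᵢ)` (Nelson–Aalen
  Λ̂), standardized by its permutational moments
  `Var(S) = m(n−m)/(n(n−1))·Σ(a−ā)²` — the convention of maximally selected
  rank statistics (R `maxstat`). The hypergeometric-variance two-sample
  log-rank test locates its maximum elsewhere on asymmetric U-shapes; the
  permutational form is the one whose Monte-Carlo behavior matches the
  published comparator results, and the two agree asymptotically at any
  fixed split. The reported p-value is the naive minimum (two-sided normal)
  and is flagged uncorrected; minP is a comparator here, not an inference
  procedure.

## Performance measures

* **Harrell's c-index**: computed by `lifelines.utils.concordance_index`
  (risk ties count 1/2); checked against an O(n²) enumeration in the tests.
* **Gönen–Heller CPE**: each unordered pair contributes
  `1/(1 + exp(−|lpᵢ − lpⱼ|))`; depends only on the fitted linear predictors,
  hence insensitive to censoring. All-equal predictors return 0.5 by
  convention. Note the estimator is invariant to a sign flip of the linear
  predictor (it measures the model as fitted, direction included).
* **Integrated Brier score**: IPCW Brier score with censoring weights from
  the Kaplan–Meier of the censoring distribution on the *training* data,
  evaluated on a 50-point grid from the smallest observed time to the 95th
  percentile of training times (truncated to test follow-up), integrated by
  the trapezoid rule and normalized by the grid span. Predicted survival
  comes from the package's Breslow baseline. Agreement with
  scikit-survival's IPCW Brier score is asserted in the tests.
* **R²_PM**: `var(lp)/(var(lp) + π²/6)`, the Cox-frame explained-variation
  form with the extreme-value error variance (sample variance, ddof = 1).
* **R²_D**: linear predictors are ranked, mapped to Blom normal scores
  (ties receive their mean score), scaled by `κ = √(8/π)`; a Cox fit on
  that single regressor gives D and `R²_D = (D²/κ²)/(D²/κ² + π²/6)`.

**Cross-validation.** Folds are stratified by event status; within each
stratum rows are keyed by (time, x) before shuffling, so the partition is
invariant to row storage order. Cut-points *and* the categorical Cox model
are re-estimated on training folds only; all five measures are evaluated on
the held-out fold; the report gives means ± SE over repeats × folds. The
default is a single two-fold split (repeats configurable, e.g. 100×5-fold).
Inside cross-validation the OEHR search runs with the U-shape gate off:
the train-fold truth is U-shaped by design in the simulations, and a
conservative flag on a half-sample fit should not abort a replicate.

## Simulation engine

The generator emulates the study conditions: predictor `x ~ N(0,1)` (no
truncation), V-shaped log hazard `s(x) = k₁(x−a)` for `x ≤ a`, `k₂(x−a)`
above (k₁ < 0 < k₂; the shifted, continuous form — the piecewise form
without the shift is discontinuous at a ≠ 0 and does not yield equal-height
cut-point pairs), Weibull event times
`T₀ = (−log U/(λ exp s(x)))^{1/v}` by inverse transform, uniform censoring
`C ~ U(0, r)` and `T = min(T₀, C)`, `d = 1{T₀ ≤ C}`. Defaults are the study
conditions: n = 500 subjects, 100 replicates, scale λ = 1, shape v = 1.
The censoring bound r is not specified analytically anywhere; it is
calibrated numerically: given a fixed 200 000-draw calibration sample of
T₀ (its own RNG substream), `P(censored) = E[min(T₀, r)]/r` is strictly
decreasing in r and is solved by bracketing + Brent to the target Pc
(tolerance ±0.005 enforced). Pc = 0 means no censoring (r = ∞).

Reproducibility: replicate datasets use `default_rng([seed, rep_index])`,
so replicates are independent and any replicate can be regenerated in
isolation.

What the generator does **not** emulate: covariate measurement error,
informative or administrative censoring, tied event times, non-Weibull
baselines, correlated adjustment covariates, or non-V nonlinearities.
Passing simulation checks therefore demonstrate correct behavior under a
clean proportional-hazards V-truth, not robustness to those features of
real data.

## Problem sizes and test tiers

The Monte-Carlo checks in the test suite run the full n = 500 design at 30
replicates per scenario (100 where no spline fit is involved), which keeps
the whole suite at a few minutes while the replicate-median standard errors
stay several times below the checked tolerances; `scripts/acceptance.py`
runs the two reported quantities at the full 100 replicates. The
`experiment` driver accepts arbitrary (n, reps) for larger sweeps.

## Known limitations

* The nonlinearity p-value uses a plug-in chi-square reference; no account
  is taken of smoothing-parameter selection.
* The minP p-value is not multiplicity-corrected (by design, see above).
* Only one covariate is discretized; adjustment covariates are supported in
  the fits, but simultaneous categorization of several covariates is not.
* Pointwise 95% bands on the diagnostic curve use the penalized
  ("Bayesian"-style) covariance of the spline coefficients at the selected
  smoothing; they are approximate and ignore smoothing selection.
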