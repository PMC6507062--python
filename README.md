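# oehr — optimal equal-HR cut-points for U-shaped hazards

Clinical and epidemiological studies routinely discretize a continuous
predictor (a biomarker, BMI, a lab value) into low / middle / high groups
before fitting a Cox proportional hazards model. When the predictor's
relationship with the log relative hazard is **U-shaped** — both very low and
very high values carry excess risk — the usual recipes fail: a median split
mixes opposite-risk patients, quartile cuts are blind to the outcome, and the
maximally selected log-rank split assumes a single step. `oehr` implements
the **optimal equal-HR method**: it groups patients so that the two cut-points
carry the *same* fitted log relative hazard, and among all such pairs picks
the one whose three-group Cox refit has minimal AIC.

## Method

With Cox model `h(t|X) = h0(t) exp(β'X)`, the relative hazard is
`λ = exp(β'X)` and `log λ` is the linear predictor. The workflow:

1. **Diagnose.** Fit `log λ(x)` with a penalized cubic B-spline (P-spline,
   22 evenly spaced knots, Eilers–Marx second-order difference penalty);
   choose the smoothing weight by minimizing `AIC = −2 pl + 2 edf`, where
   `edf = tr[(H + sP)⁻¹H]`. Inspect/verify the U shape.
2. **Sweep.** For each percentile level `Q_k` (k = 5…95) of the fitted
   `log λ̂` values, intersect the horizontal line `y = Q_k` with the curve.
   The observations nearest the two intersections form a candidate pair
   `(X₁ₖ, X₂ₖ)` subject to `|log λ̂(X₁ₖ) − log λ̂(X₂ₖ)| ≤ 0.01`; violations are
   replaced by points linearly interpolated on the curve, so candidate
   cut-points need not be observed values.
3. **Select.** Discretize x at each candidate pair (middle range is the
   reference level), refit the Cox model with two dummies, and keep the pair
   minimizing AIC (BIC available as a switch).

Comparators (median split, Q1/Q3 split, maximally selected log-rank a.k.a.
minP), five performance measures (Harrell's c-index, Gönen–Heller CPE, IPCW
integrated Brier score, Kent–O'Quigley R²_PM, Royston–Sauerbrei R²_D), a
cross-validation wrapper, a Weibull simulation engine with a V-shaped log
hazard, and a Monte-Carlo study driver are included. See
`docs/methods.md` for modelling details and numerical conventions.

## Worked example

Simulate one severe-asymmetric dataset (true log hazard
`s(x) = −4/3·(x−1)` for `x ≤ 1`, `4·(x−1)` above; n = 500, no censoring),
then diagnose and cut:

```bash
python -c "
from oehr import SimulationScenario, generate_dataset
generate_dataset(SimulationScenario(-4/3, 4, 1, n=500, reps=1, seed=1), 0).write_csv('example.csv')
"
oehr diagnose --input example.csv --out-curve curve.csv
```

```json
{
  "is_u_shaped": true,
  "minimum": 0.8854824939452763,
  "p_nonlinear": 8.046224257378298e-39,
  "edf": 7.695342235729862,
  "aic": 4904.153668500618
}
```

The spline fit flags a U shape with its minimum near the true turning point
(x = 1) and a strongly significant nonlinear term. Now all four methods:

```bash
oehr cutpoints --input example.csv --method all --out report.json
```

| method | cut1   | cut2  | AIC      | HRs (vs reference)  |
|--------|--------|-------|----------|---------------------|
| median | −0.002 | —     | 5105.27  | 0.33                |
| q1q3   | −0.643 | 0.580 | 5091.65  | 3.23, 0.57          |
| minp   | −0.020 | —     | 5096.26  | 0.32                |
| oehr   | −0.139 | 1.439 | 5034.67  | 3.91, 8.56          |

Only the equal-HR cut-points give two groups that are *both* high-risk
(HR > 1) relative to the middle range — the quartile split puts its upper
cut inside the low-risk valley (HR 0.57), and the single-cut methods
collapse the two risky tails into opposite groups. The OEHR refit also has
the lowest AIC by ~57 points.

The same workflow on a user's CSV: `oehr report config.yaml` runs
diagnose → cut → refit → cross-validate and writes a JSON/CSV bundle;
`oehr simulate-study --config scenarios.yaml --out results/` runs a
scenario sweep.

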