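# strokecausal

Multi-estimator causal analysis of stroke risk factors, with a
three-headed neural potential-outcome model (Dragonnet) and nested
weighted split-conformal quantile regression for per-patient treatment
effect intervals — developed and validated on synthetic high-risk cohorts
with known ground truth.

## The problem

In hospital cohorts of adults with hypertension (HT), diabetes (DM),
dyslipidemia (DLP) or atrial fibrillation (AF), a few percent go on to
stroke, and antiplatelet treatment is prescribed exactly to the patients
already at elevated risk (confounding by indication). Two questions matter
clinically: *how much does each risk factor causally raise stroke risk*
(an average effect per exposure, identified through backdoor adjustment on
a causal diagram), and *which untreated patients would benefit most from
antiplatelet therapy* (an individualized treatment effect, ITE, with an
honest uncertainty interval). This package implements the full toolchain
for both, for epidemiologists and methodologists who want every estimator
runnable and testable against exact ground truth.

Because patient-level hospital data cannot be shipped, the package
includes a first-class structural-causal-model cohort generator calibrated
to published cohort margins (3.5% marginal stroke incidence; stratified
rates of roughly 13%/4%/4%/4% among AF/HT/DM/DLP patients vs 2%/1%/3%/3%
among their complements). The generator knows each simulated patient's
potential outcomes exactly, which makes it the oracle for every recovery
and coverage test.

## What is implemented

| Component | Core idea |
|---|---|
| `synthetic_cohort` | logistic SCM over the stroke DAG; exact per-patient p₁, p₀, ITE; two-world forced-exposure oracle |
| `causal_graph` | the stroke DAG, Bayes-ball d-separation, minimal backdoor adjustment sets |
| `classical_estimators` | propensity stratification (auto strata), Horvitz–Thompson IPW, augmented-IPW doubly robust, logistic OR baseline, percentile bootstrap |
| `dml` | 5-fold cross-fitted double ML, interactive (AIPW) orthogonal score, linear (lasso/logistic) and nonlinear (XGBoost) variants |
| `mediation` | natural direct/indirect effects via the mediational g-formula, joint binary mediators, exact NDE + NIE = total decomposition |
| `dragonnet` | shared representation + two outcome heads + propensity head, targeted regularization, numpy backprop, AIPW-corrected ATE readout |
| `conformal_ite` | nested weighted split-CQR: per-arm quantile models → plug-in ITE bounds → conformalized bound regression, likelihood-ratio weights |
| `pipeline` / CLI | end-to-end orchestration, tidy effect tables, stratified mean-ITE summaries, run manifest |

The averaged estimand is the risk difference
E[Y(1)] − E[Y(0)]; Dragonnet additionally reports causal risk ratios
E[Y(1)]/E[Y(0)]; the conformal module reports per-patient intervals for
Y(1) − Y(0) at level 1 − α (α = .05).

## Worked example

```python
from strokecausal import (CohortSpec, generate_cohort, build_default_dag,
                          backdoor_adjustment_set, ipw_ate, dre_ate,
                          dml_ate, DMLConfig)

spec = CohortSpec(n=50_000, seed=1)          # calibrated defaults
cohort, truth = generate_cohort(spec)
df = cohort.frame
print(f"incidence: {df['y'].mean():.4f}   true antiplatelet ATE: {truth.ate:+.4f}")

dag = build_default_dag()
for exposure in ("af", "ht", "dm", "dlp"):
    adj = sorted(backdoor_adjustment_set(dag, exposure))
    est = dre_ate(df, exposure, adj)
    print(f"{exposure:>4}  adjustment={{{', '.join(adj)}}}  "
          f"risk difference = {est.point:+.4f}")

adj_t = ["age", "sex", "bmi", "ckd", "af", "ht", "dm", "dlp"]
print(f"treatment IPW: {ipw_ate(df, 't', adj_t).point:+.4f}")
print(f"treatment DML: {dml_ate(df, 't', adj_t, DMLConfig(variant='nonlinear', seed=1)).point:+.4f}")
```

prints

```
incidence: 0.0365   true antiplatelet ATE: -0.0114
  af  adjustment={age, ht}  risk difference = +0.0739
  ht  adjustment={age, dlp, dm}  risk difference = +0.0263
  dm  adjustment={age, bmi}  risk difference = +0.0067
 dlp  adjustment={age}  risk difference = +0.0049
treatment IPW: -0.0125
treatment DML: -0.0124
```

Reading it: AF is by far the strongest stroke risk factor (+7.4 percentage
points of absolute risk after adjusting for age and HT), followed by HT,
DM and DLP — and the backdoor-adjusted treatment estimates land on the
generator's true protective effect of −1.1 points where the naive arm
contrast (−0.2 points, not shown) is badly confounded.

The same analysis end-to-end, from the shell:

```bash
strokecausal simulate --n 20000 --seed 7 --out cohort.csv
strokecausal all --cohort cohort.csv --seed 7 --out results/
```

which writes `effects.csv` (estimator × exposure table), `ite_intervals.csv`
(per-patient conformal intervals for untreated-patient counterfactuals),
`ite_summary.csv` (mean ITE and IQR per HT/DM/DLP stratum), a box plot,
and a `manifest.json` with seeds and stage status.

## Layout

```
src/strokecausal/     library modules (one per component above)
tests/                pytest suite incl. end-to-end acceptance checks
scripts/              acceptance script; one-time generator calibration
docs/methods.md       model, defaults, design choices, limitations
```
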