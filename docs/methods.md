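# Methods

This package estimates average and individualized causal effects of stroke
risk factors — atrial fibrillation (AF), hypertension (HT), diabetes
mellitus (DM), dyslipidemia (DLP) — and of antiplatelet treatment on a
binary stroke outcome, in a high-risk adult cohort. Because cohorts of this
kind come from hospital records that cannot be redistributed, every method
is developed and validated against a structural causal model (SCM) with
known per-patient potential outcomes. This note records the model, the
defaults, and the design choices, and states what the synthetic validation
does and does not demonstrate.

## The causal model

The working DAG is: age → {DM, DLP, HT, CKD, AF, Y}; BMI → {DM, Y};
DM → {HT, CKD, Y}; DLP → {HT, Y}; HT → {CKD, AF, Y}; CKD → Y; AF → Y;
{HT, DM, DLP, age} → T; T → Y, where T is antiplatelet treatment and Y is
stroke. Sex is recorded but carries no arrows (a pure noise covariate).
Chronic kidney disease (CKD) and AF mediate HT's effect; HT and CKD mediate
DM's; HT mediates DLP's. Whether BMI should also point at DLP is genuinely
open; we give it edges only into DM and Y, which is what makes the DM
adjustment set {age, BMI}.

Minimal backdoor adjustment sets are found by exhaustive subset search over
non-descendants of the exposure, with validity tested by a Bayes-ball
d-separation routine on the back-door graph (the exposure's outgoing edges
removed). Bayes-ball was chosen over moralization because reachability is
easy to cross-check exhaustively against both path enumeration and
networkx's implementation on small random DAGs. Subset search is
exponential but the DAG has at most eight candidate nodes per exposure; the
code refuses graphs with more than 20 candidates. Ties among minimal sets
are broken by set size first, then lexicographically. The resulting sets on
the default DAG are {age, HT} for AF, {age, DM, DLP} for HT, {age, BMI} for
DM and {age} for DLP.

## The synthetic cohort generator

Exogenous covariates: age ~ Normal(62, 12²) truncated below at 18 years
(eligibility requires adults), sex ~ Bernoulli(0.5), BMI ~ Normal(25, 4²)
kg/m². Every endogenous binary node follows a logistic structural equation
over its graph parents, sampled in topological order; continuous parents
enter standardized ((age−62)/12, (BMI−25)/4). Treatment assignment depends
on HT, DM, DLP and age — confounding by indication — with slopes chosen so
that all propensities stay inside roughly [0.09, 0.74] (positivity by
construction). The treatment coefficient in the outcome equation is
heterogeneous: base −0.10 on the log-odds scale, plus −0.40 for DM patients
and −0.05 for HT patients, so treatment benefit concentrates in DM and
DM+HT strata. Because the outcome link is logistic, each simulated
patient's two potential-outcome probabilities p₁, p₀ — and hence the
individual treatment effect (ITE) p₁ − p₀ — are exact.

Default coefficients were calibrated once (scripts/calibrate_generator.py)
by a damped logit-scale fixed-point iteration at n = 2,000,000 against the
cohort margins the package targets: marginal stroke incidence 3.5%, and
stratified stroke rates of 13%/4%/4%/4% among AF/HT/DM/DLP patients versus
2%/1%/3%/3% among their complements. Those eight rates jointly pin the
prevalences (AF ≈ 0.136, HT ≈ 0.833, DM = DLP = 0.5); CKD prevalence was
set to 0.15 as a plausible comorbidity rate. The converged constants are
committed as package defaults. Three structural slopes were set during the
same design phase so that the generator's *causal* ordering of risk factors
is AF > HT > DM > DLP > 0 (risk-difference scale): the age→DM slope is kept
moderate (0.15) so that DM's conditional 4%-vs-3% gap is not wholly
explained by age confounding, and the DM→T and DLP→HT slopes are 0.2 and
0.3. Under the committed defaults the true two-world effects are AF ≈ 0.072
(risk ratio ≈ 4.4), HT ≈ 0.023 (≈ 2.6), DM ≈ 0.005 (≈ 1.2), DLP ≈ 0.002
(≈ 1.1), and the true antiplatelet ATE ≈ −0.0115.

Ground truth beyond the treatment contrast is produced by a two-world
forced-exposure Monte-Carlo oracle: simulate the exogenous draws once,
force the exposure node to 1 and to 0 with common random numbers for all
descendants, propagate, and contrast the analytically computed outcome
probabilities. This oracle is independent of every estimator and is the
reference in all recovery tests.

An optional *latent-risk* outcome mode additionally emits y_latent = η + ε,
where η is the outcome linear predictor under the factual treatment and
ε ~ Normal(0, 0.5²). Conformal quantile regression on a purely binary
outcome produces degenerate step quantiles, so coverage studies of the ITE
interval machinery use this continuous mode, where the true latent ITE is
the individual treatment log-odds shift (between −0.55 and −0.10 under the
defaults). The noise SD of 0.5 makes the heterogeneity signal comparable to
the noise — detectable but not trivial.

What the generator does *not* emulate: time-to-event structure and
censoring, ICD-coding error, missing data, unmeasured confounding, and
secular trends. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated assumptions (no unmeasured confounding,
positivity, correct or flexibly-learnable nuisance forms), not robustness
to those real-data pathologies.

## Average-effect estimators

All estimators consume a cohort table plus an exposure and an adjustment
set (normally the DAG-derived backdoor set).

- **Propensity scores** are plain logistic regressions, clipped to
  [0.01, 0.99]. The clip bound tames Horvitz–Thompson variance and is
  exposed as an argument.
- **Stratified propensity score (SPS)**: strata are determined
  automatically by recursive bisection of the propensity range at its
  midpoint; a split is accepted only while both children keep at least 10
  exposed and 10 unexposed patients. The ATE is the size-weighted mean of
  within-stratum outcome contrasts. (Midpoint rather than median bisection:
  median splits collapse when many scores tie.)
- **IPW**: the Horvitz–Thompson contrast mean(AY/e) − mean((1−A)Y/(1−e)),
  with a stabilized-weight variant; weights above n/10 trigger a warning.
- **Doubly robust (DRE)**: augmented IPW with per-arm L1-penalized logistic
  outcome models. The lasso pipeline standardizes features and selects its
  penalty by 5-fold cross-validation on log-loss — selection on accuracy is
  useless at 3% incidence, and the saga solver is used because it does not
  penalize the intercept. Either nuisance can be overridden, which is how
  the double-robustness tests inject deliberately misspecified models.
- **Logistic odds-ratio baseline**: multivariable logistic regression with
  a Wald 95% CI, the conventional epidemiological comparator.
- **Confidence intervals** for the propensity estimators are percentile
  bootstrap over patients (default B = 500; seeded). The bootstrap is
  deliberately uniform across estimators rather than estimator-specific
  analytic forms.

**Double machine learning** cross-fits nuisances over 5 folds (stratified
on arm × outcome so sparse cells appear in every training part) and
averages the interactive/AIPW orthogonal score. The interactive score
rather than the partially-linear one is the right choice for a
risk-difference estimand with binary treatment and outcome. The linear
variant uses the lasso-logistic outcome model and an unpenalized logistic
propensity; the nonlinear variant uses gradient-boosted trees (depth 3,
200 rounds, learning rate 0.1) for both. The whole cross-fit is repeated
over 3 fold seeds and the median estimate reported, a standard
stabilization; the standard error is the influence-function sd(ψ)/√n. A
fold that loses an exposure arm triggers one refold with a new seed, then
an error. The "final model" stage of a scalar ATE reduces to averaging the
orthogonal scores; that is how it is implemented.

## Mediation

Natural direct and indirect effects use the mediational g-formula with
binary mediators, standardizing over the empirical covariate sample.
Multiple mediators (e.g. CKD and AF for HT) are handled *jointly*, with the
joint conditional law factorized in topological order — this respects the
CKD ← HT → AF structure rather than assuming mediator independence. The
outcome model includes exposure × mediator interactions by default. With
the baseline mediator regime for the NDE and the treated regime for the
NIE, NDE + NIE telescopes to the total effect of the same fitted models;
the implementation asserts that identity to 1e-10 on every call. A
`saturated` mode replaces logistic fits with exact cell means, which makes
the estimator reproduce full-enumeration oracles exactly on tabulated toy
SCMs. Identification assumes no exposure-induced mediator–outcome
confounding, which holds in the working DAG.

## Dragonnet

The three-headed network shares a representation trunk φ(X) ∈ ℝᴾ (default
P = 200, three ELU layers) feeding: two outcome heads (two hidden layers of
100 units each; a row contributes to the loss only through its factual
head) and a single-layer sigmoid propensity head. The joint loss is the
factual binary cross-entropy plus α·BCE(ê, t) (α = 1) plus a targeted
regularization term with a trainable scalar fluctuation parameter
(strength 1.0 by default): the fluctuation nudges the outcome heads so the
plug-in effect estimate approximately solves the efficient estimating
equation.

The network is implemented directly in numpy — dense layers, manual
backpropagation (verified against finite differences), Adam, batch 512,
20% validation split, early stopping with patience 5 — because at these
sizes CPU matrix products dominate and the implementation is fully
deterministic given the seed. Continuous covariates are z-scored with
training-set statistics stored on the model.

Two ATE readouts are provided: the plug-in mean head contrast, and an AIPW
correction using the propensity head (clipped to [0.01, 0.99]). The AIPW
readout is the package's reported Dragonnet ATE: on calibrated synthetic
cohorts at n = 50,000 the plug-in retains visible regularization bias
(≈ −0.017 against a truth of ≈ −0.011) while the corrected readout lands
within sampling error. CATEs are head contrasts averaged within strata;
causal risk ratios are mean(ŷ₁)/mean(ŷ₀) with a patient-level bootstrap CI
(the decomposition RD = mean(ŷ₀)(RR − 1) then holds exactly by
construction).

## Conformal ITE intervals

The ITE is never observed, so intervals come from a nested two-stage split
construction at miscoverage α = 0.05 with an even train/evaluation split:

1. On the training half, per-arm gradient-boosted quantile regressors
   (pinball loss at α/2 and 1 − α/2; LightGBM, 300 trees, 31 leaves) give
   plug-in counterfactual intervals.
2. Each training patient combines their observed factual outcome with the
   opposite arm's counterfactual interval into plug-in ITE bounds
   [L, U]: treated patients [y − q̂⁰_hi(x), y − q̂⁰_lo(x)], controls
   [q̂¹_lo(x) − y, q̂¹_hi(x) − y].
3. The bounds are regressed on covariates, and the bound regressors are
   conformalized on the evaluation half with the CQR score
   max(m̂_L(x) − L, U − m̂_U(x)). The conformal quantile uses the standard
   weighted convention — normalized weights with a point mass at +∞ at the
   test point — with likelihood-ratio weights 1/ê(x) for treated and
   1/(1 − ê(x)) for control calibration points (a logistic ê fitted on the
   training half), compensating the covariate shift between each arm and
   the population. A uniform-weight mode is exposed for the exchangeable
   case.

The final interval is [m̂_L(x) − η, m̂_U(x) + η]. The point estimate is the
interval midpoint by default; the pipeline passes the Dragonnet CATE and
clips it into the interval so every row is a valid bracketing triple.

Two properties of this construction are worth being explicit about. First,
it is *self-correcting*: when the stage-1 plug-in bounds undercover
(because tree quantile surfaces carry model error), the stage-2
conformalization inflates η by exactly the observed miss distance, so
marginal coverage is maintained. Second, it is *conservative*: measured
coverage on synthetic cohorts is near 100% at nominal 95%, with interval
widths a few times the outcome noise SD. Width, not coverage, is where
model quality shows up; widths shrink roughly in half when outcome noise is
removed, bounded below by quantile-model error.

Stratified summaries report mean ITE and interquartile range among
*untreated* patients per {HT, DM, DLP} combination — the counterfactual
"what if the untreated had been treated" reading. AF never defines a
stratum (it is not an antiplatelet indication) but remains a covariate in
every model; passing AF as a stratum is an error.

## Pipeline and problem sizes

`run_full_analysis` derives adjustment sets from the DAG, runs the
requested estimators per exposure, adds NDE/NIE for exposures with disease
mediators, and runs Dragonnet + conformal ITEs for antiplatelet treatment;
stage failures are recorded in a JSON manifest without aborting independent
stages, and a fixed global seed makes reruns byte-identical. The CLI
(`strokecausal simulate/estimate/ite/report/all`) is a thin wrapper with
YAML config support.

Validation problem sizes were chosen to separate signal from noise at desk
scale: generator calibration checks at n = 100,000 (binomial SE ≈ 0.06
percentage points on the marginal rate); estimator recovery at n = 50,000
(influence-function SE ≈ 0.0016 on the ATE, against biases of ≈ 0.009 that
the naive contrast exhibits); conformal coverage over 200 cohorts of
n = 2,000 (Monte-Carlo SE on coverage well under one percentage point);
toy-table oracles at n ≤ 16 with exact arithmetic.

## Known limitations

- The conformal intervals are conservative by design; no attempt is made at
  the sharper "exact nested" variant or at group-conditional coverage.
- Binary-outcome conformal intervals are coarse (quantile surfaces are step
  functions); the latent-risk mode exists precisely because of this.
- The Dragonnet implementation targets CPU desk scale; no GPU path, no
  hyperparameter search.
- Mediation supports binary mediators only, and the NDE/NIE identification
  leans on the absence of exposure-induced mediator–outcome confounding.
- The generator's effect sizes are calibrated to published *margins*, not
  to any patient-level data; agreement of its true effects with published
  point estimates is a consistency observation, not a validation of the
  generator against the original cohort.
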