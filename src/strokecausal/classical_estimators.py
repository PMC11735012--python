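"""Propensity-score ATE estimators and a logistic odds-ratio baseline.

Implements the classical potential-outcome machinery used throughout the
analysis: propensity-score stratification with automatic strata (SPS),
Horvitz-Thompson inverse probability weighting (IPW), the augmented-IPW
doubly robust estimator (DRE, lasso outcome models + logistic propensity),
and an adjusted odds ratio from multivariable logistic regression.  All
confidence intervals are percentile bootstrap over patients.

Every estimator consumes a cohort DataFrame following the shared CSV schema
plus an exposure column name and an adjustment set (normally derived from
the backdoor criterion on the default DAG).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "PropensityScores",
    "EffectEstimate",
    "fit_propensity",
    "naive_difference",
    "sps_ate",
    "ipw_ate",
    "dre_ate",
    "logistic_or_baseline",
    "bootstrap_ci",
]

PROPENSITY_CLIP = (0.01, 0.99)


@dataclass
class PropensityScores:
    """Per-patient exposure probabilities, clipped away from 0 and 1."""

    e: np.ndarray
    model_description: str = "logistic regression"

    def __post_init__(self) -> None:
        self.e = np.asarray(self.e, dtype=float)
        if np.any((self.e <= 0) | (self.e >= 1)):
            raise ValueError("propensity scores must lie strictly in (0, 1)")


@dataclass
class EffectEstimate:
    """A point effect estimate with optional percentile-bootstrap 95% CI."""

    estimator: str
    exposure: str
    point: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    scale: str = "risk-difference"

    def __post_init__(self) -> None:
        if not np.isfinite(self.point):
            raise ValueError("effect estimate must be finite")


def _design(df: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    if not cols:
        return np.ones((len(df), 1))
    return df[list(cols)].to_numpy(dtype=float)


def fit_propensity(df: pd.DataFrame, exposure: str,
                   adjustment: Sequence[str],
                   clip: tuple[float, float] = PROPENSITY_CLIP
                   ) -> PropensityScores:
    """Fit a logistic propensity model of ``exposure`` on ``adjustment``.

    Scores are clipped to ``clip`` to stabilize inverse weighting.  A
    constant exposure is an error (there is no contrast to estimate).
    """
    a = df[exposure].to_numpy(dtype=float)
    if a.min() == a.max():
        raise ValueError(f"exposure {exposure!r} is constant; no contrast")
    adjustment = list(adjustment)
    if not adjustment:
        e = np.full(len(df), a.mean())
    else:
        x = _design(df, adjustment)
        model = LogisticRegression(C=np.inf, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(x, a)
        e = model.predict_proba(x)[:, 1]
    e = np.clip(e, clip[0], clip[1])
    desc = f"logistic({exposure} ~ {' + '.join(adjustment) or '1'})"
    return PropensityScores(e=e, model_description=desc)


def naive_difference(df: pd.DataFrame, exposure: str,
                     adjustment: Sequence[str] = (), outcome: str = "y"
                     ) -> EffectEstimate:
    """Unadjusted difference in mean outcomes between exposure arms."""
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    point = float(y[a == 1].mean() - y[a == 0].mean())
    return EffectEstimate("naive", exposure, point)


# ---------------------------------------------------------------------------
# stratified propensity score
# ---------------------------------------------------------------------------

def _bisect_strata(e: np.ndarray, a: np.ndarray, idx: np.ndarray,
                   min_arm: int) -> list[np.ndarray]:
    """Recursively bisect a propensity stratum at the midpoint of its range.

    A split is accepted only while both children are nonempty and keep at
    least ``min_arm`` exposed and ``min_arm`` unexposed patients.
    """
    cut = (float(e[idx].min()) + float(e[idx].max())) / 2.0
    left = idx[e[idx] <= cut]
    right = idx[e[idx] > cut]
    if not len(left) or not len(right):  # all scores identical
        return [idx]
    for part in (left, right):
        if (a[part] == 1).sum() < min_arm or (a[part] == 0).sum() < min_arm:
            return [idx]
    return (_bisect_strata(e, a, left, min_arm)
            + _bisect_strata(e, a, right, min_arm))


def sps_ate(df: pd.DataFrame, exposure: str, adjustment: Sequence[str],
            outcome: str = "y", min_arm: int = 10,
            propensity: PropensityScores | None = None) -> EffectEstimate:
    """Stratified-propensity-score ATE with automatically determined strata.

    Patients are binned on the fitted propensity score by recursive median
    bisection until any further split would leave a stratum with fewer than
    ``min_arm`` exposed or unexposed patients; the ATE is the size-weighted
    mean of within-stratum outcome differences.
    """
    e = (propensity or fit_propensity(df, exposure, adjustment)).e
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if (a == 1).sum() == 0 or (a == 0).sum() == 0:
        raise ValueError("positivity failure: an exposure arm is empty")
    strata = _bisect_strata(e, a, np.arange(len(df)), min_arm)
    ate, n = 0.0, len(df)
    for idx in strata:
        a_s, y_s = a[idx], y[idx]
        if (a_s == 1).sum() == 0 or (a_s == 0).sum() == 0:
            raise ValueError("positivity failure inside a stratum")
        ate += len(idx) / n * (y_s[a_s == 1].mean() - y_s[a_s == 0].mean())
    return EffectEstimate("sps", exposure, float(ate))


# ---------------------------------------------------------------------------
# inverse probability weighting
# ---------------------------------------------------------------------------

def ipw_ate(df: pd.DataFrame, exposure: str, adjustment: Sequence[str],
            outcome: str = "y", stabilized: bool = False,
            propensity: PropensityScores | None = None) -> EffectEstimate:
    """Horvitz-Thompson IPW ATE (optionally with stabilized weights)."""
    e = (propensity or fit_propensity(df, exposure, adjustment)).e
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    w1, w0 = a / e, (1 - a) / (1 - e)
    if max(w1.max(), w0.max()) > len(df) / 10:
        warnings.warn("extreme inverse-propensity weights detected",
                      RuntimeWarning, stacklevel=2)
    if stabilized:
        point = float(np.sum(w1 * y) / np.sum(w1) - np.sum(w0 * y) / np.sum(w0))
    else:
        point = float(np.mean(w1 * y) - np.mean(w0 * y))
    name = "ipw-stabilized" if stabilized else "ipw"
    return EffectEstimate(name, exposure, point)


# ---------------------------------------------------------------------------
# doubly robust (augmented IPW)
# ---------------------------------------------------------------------------

def _fit_arm_outcome_models(df: pd.DataFrame, exposure: str,
                            adjustment: Sequence[str], outcome: str
                            ) -> tuple[Callable, Callable]:
    """Per-arm L1-penalized logistic outcome models, penalty chosen by CV."""
    x = _design(df, adjustment)
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    models = {}
    for arm in (0, 1):
        mask = a == arm
        y_arm = y[mask]
        if y_arm.min() == y_arm.max():  # constant outcome in arm
            const = float(y_arm.mean())
            models[arm] = (lambda c: (lambda xx: np.full(len(xx), c)))(const)
            continue
        m = make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(penalty="l1", solver="saga", cv=5,
                                 scoring="neg_log_loss",
                                 Cs=np.logspace(-3, 3, 7), max_iter=3000,
                                 random_state=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m.fit(x[mask], y_arm)
        models[arm] = (lambda mm: (lambda xx: mm.predict_proba(xx)[:, 1]))(m)
    return models[0], models[1]


def dre_ate(df: pd.DataFrame, exposure: str, adjustment: Sequence[str],
            outcome: str = "y",
            propensity: PropensityScores | None = None,
            outcome_models: tuple[np.ndarray, np.ndarray] | None = None
            ) -> EffectEstimate:
    """Augmented-IPW doubly robust ATE.

    ``ATE = mean[ m1 - m0 + A (Y - m1)/e - (1-A)(Y - m0)/(1-e) ]`` where the
    outcome regressions ``m_a`` default to per-arm L1-penalized logistic fits
    and ``e`` to a logistic propensity model.  Either nuisance may be
    overridden (e.g. with oracle values or deliberately misspecified fits)
    via ``propensity`` / ``outcome_models`` — the estimator remains
    consistent if at least one nuisance is correct.
    """
    e = (propensity or fit_propensity(df, exposure, adjustment)).e
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if outcome_models is None:
        f0, f1 = _fit_arm_outcome_models(df, exposure, adjustment, outcome)
        x = _design(df, adjustment)
        m0, m1 = f0(x), f1(x)
    else:
        m0, m1 = (np.asarray(v, dtype=float) for v in outcome_models)
    psi = m1 - m0 + a * (y - m1) / e - (1 - a) * (y - m0) / (1 - e)
    return EffectEstimate("dre", exposure, float(np.mean(psi)))


# ---------------------------------------------------------------------------
# logistic odds-ratio baseline
# ---------------------------------------------------------------------------

def logistic_or_baseline(df: pd.DataFrame, exposure: str,
                         adjustment: Sequence[str], outcome: str = "y"
                         ) -> EffectEstimate:
    """Adjusted odds ratio for the exposure with a Wald 95% CI."""
    cols = [exposure, *adjustment]
    x = sm.add_constant(_design(df, cols))
    y = df[outcome].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, x).fit(disp=0)
    beta = fit.params[1]
    lo, hi = fit.conf_int()[1]
    return EffectEstimate("logistic-or", exposure, float(np.exp(beta)),
                          float(np.exp(lo)), float(np.exp(hi)),
                          scale="odds-ratio")


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(estimator: Callable[[pd.DataFrame], float],
                 df: pd.DataFrame, n_boot: int = 500, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap interval from nonparametric patient resamples.

    ``estimator`` maps a resampled DataFrame to a scalar.  More than 5%
    failing resamples aborts with an error.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 for a stable percentile CI")
    rng = np.random.default_rng(seed)
    n = len(df)
    stats, failures = [], 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            stats.append(float(estimator(df.iloc[idx].reset_index(drop=True))))
        except Exception:
            failures += 1
    if failures > 0.05 * n_boot:
        raise RuntimeError(
            f"estimator failed in {failures}/{n_boot} bootstrap resamples")
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def with_bootstrap_ci(est_fn: Callable[[pd.DataFrame], EffectEstimate],
                      df: pd.DataFrame, n_boot: int = 500,
                      seed: int = 0) -> EffectEstimate:
    """Attach a percentile-bootstrap CI to a point estimator."""
    est = est_fn(df)
    lo, hi = bootstrap_ci(lambda d: est_fn(d).point, df, n_boot, seed)
    est.ci_low, est.ci_high = min(lo, est.point), max(hi, est.point)
    return est
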