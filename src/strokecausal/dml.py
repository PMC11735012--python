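"""Cross-fitted double machine learning for the average treatment effect.

Double ML removes own-observation overfitting bias by fitting nuisance
models (outcome regressions and the propensity score) out-of-fold and
averaging a Neyman-orthogonal score over held-out folds.  For a binary
treatment and binary outcome the appropriate orthogonal score is the
interactive (AIPW-type) score

    psi_i = m1(X_i) - m0(X_i) + A_i (Y_i - m1(X_i)) / e(X_i)
                              - (1 - A_i)(Y_i - m0(X_i)) / (1 - e(X_i))

whose average solves the risk-difference estimand; the analytic standard
error is ``sd(psi)/sqrt(n)``.

Two variants are provided: ``linear`` (L1-penalized logistic outcome models
and plain logistic propensity) and ``nonlinear`` (gradient-boosted trees for
both).  To stabilize against the fold-assignment seed, the cross-fitting is
repeated over several seeds and the median point estimate is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .classical_estimators import EffectEstimate, PROPENSITY_CLIP

__all__ = ["DMLConfig", "dml_ate", "crossfit_scores"]


@dataclass
class DMLConfig:
    """Settings for cross-fitted double ML.

    ``n_reps`` independent fold assignments are run and the median estimate
    reported.  Boosted-tree defaults: depth 3, 200 rounds, learning rate 0.1.
    """

    n_folds: int = 5
    variant: str = "linear"
    seed: int = 0
    n_reps: int = 3
    xgb_params: dict = field(default_factory=lambda: dict(
        max_depth=3, n_estimators=200, learning_rate=0.1))

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.variant not in ("linear", "nonlinear"):
            raise ValueError("variant must be 'linear' or 'nonlinear'")


def _outcome_learner(variant: str, cfg: DMLConfig):
    if variant == "linear":
        return make_pipeline(
            StandardScaler(),
            LogisticRegressionCV(penalty="l1", solver="saga", cv=3,
                                 scoring="neg_log_loss",
                                 Cs=np.logspace(-3, 3, 7), max_iter=3000,
                                 random_state=0))
    return XGBClassifier(**cfg.xgb_params, verbosity=0)


def _propensity_learner(variant: str, cfg: DMLConfig):
    if variant == "linear":
        return LogisticRegression(C=np.inf, max_iter=2000)
    return XGBClassifier(**cfg.xgb_params, verbosity=0)


def _fit_predict_prob(model, x_tr, y_tr, x_te) -> np.ndarray:
    if y_tr.min() == y_tr.max():
        return np.full(len(x_te), float(y_tr.mean()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(x_tr, y_tr)
    return model.predict_proba(x_te)[:, 1]


def crossfit_scores(df: pd.DataFrame, exposure: str,
                    adjustment: Sequence[str], config: DMLConfig,
                    rep_seed: int,
                    nuisances: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
                    outcome: str = "y") -> np.ndarray:
    """One pass of K-fold cross-fitting; returns the per-patient scores.

    Every row is scored exactly once, by nuisance models that never saw it.
    ``nuisances = (m0, m1, e)`` bypasses fitting (oracle/toy usage), in which
    case the score reduces to the plain AIPW formula.
    """
    x = df[list(adjustment)].to_numpy(dtype=float)
    a = df[exposure].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    n = len(df)
    if nuisances is not None:
        m0, m1, e = (np.asarray(v, dtype=float) for v in nuisances)
    else:
        m0 = np.full(n, np.nan)
        m1 = np.full(n, np.nan)
        e = np.full(n, np.nan)
        for attempt in range(2):
            seed = rep_seed + 1000 * attempt
            folds = StratifiedKFold(config.n_folds, shuffle=True,
                                    random_state=seed)
            # stratify on arm x outcome so each training part holds both arms
            strat = (2 * a + y).astype(int)
            try:
                for tr, te in folds.split(x, strat):
                    a_tr, y_tr = a[tr], y[tr]
                    if (a_tr == 1).sum() == 0 or (a_tr == 0).sum() == 0:
                        raise RuntimeError("fold without both exposure arms")
                    for arm, m_out in ((0, m0), (1, m1)):
                        mask = a_tr == arm
                        m_out[te] = _fit_predict_prob(
                            _outcome_learner(config.variant, config),
                            x[tr][mask], y_tr[mask], x[te])
                    e[te] = _fit_predict_prob(
                        _propensity_learner(config.variant, config),
                        x[tr], a_tr, x[te])
                break
            except RuntimeError:
                if attempt == 1:
                    raise
        assert not np.isnan(m0).any(), "cross-fitting left unscored rows"
    e = np.clip(e, *PROPENSITY_CLIP)
    return m1 - m0 + a * (y - m1) / e - (1 - a) * (y - m0) / (1 - e)


def dml_ate(df: pd.DataFrame, exposure: str, adjustment: Sequence[str],
            config: DMLConfig | None = None,
            nuisances: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
            outcome: str = "y") -> EffectEstimate:
    """Cross-fitted DML ATE (risk difference) with influence-function CI.

    Runs ``config.n_reps`` fold assignments and reports the median point
    estimate with a Wald 95% CI from the median analytic standard error.
    """
    config = config or DMLConfig()
    if not list(adjustment):
        raise ValueError("DML requires a nonempty adjustment set")
    points, ses = [], []
    for rep in range(config.n_reps):
        psi = crossfit_scores(df, exposure, adjustment, config,
                              rep_seed=config.seed + rep,
                              nuisances=nuisances, outcome=outcome)
        points.append(float(np.mean(psi)))
        ses.append(float(np.std(psi, ddof=1) / np.sqrt(len(psi))))
        if nuisances is not None:
            break  # deterministic given oracle nuisances
    point = float(np.median(points))
    se = float(np.median(ses))
    name = f"dml-{config.variant}"
    return EffectEstimate(name, exposure, point,
                          point - 1.96 * se, point + 1.96 * se)
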