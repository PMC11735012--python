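"""Natural direct and indirect effects via the mediational g-formula.

For a binary exposure X, binary mediators M (possibly several, handled
jointly) and adjustment covariates Z, the natural direct effect holds the
mediator distribution at its unexposed regime while switching the exposure,

    NDE = E_Z[ sum_m ( E[Y|X=1,m,Z] - E[Y|X=0,m,Z] ) P(m|X=0,Z) ],

and the natural indirect effect switches the mediator regime while holding
the exposure at its active level,

    NIE = E_Z[ sum_m E[Y|X=1,m,Z] ( P(m|X=1,Z) - P(m|X=0,Z) ) ].

With these reference regimes NDE + NIE equals the total effect of the same
fitted models exactly (the cross terms telescope), which is asserted to
floating tolerance on every call.

Joint mediators are modeled by factorizing their conditional distribution
in topological order, P(m1|x,Z) P(m2|x,m1,Z) ..., which respects structures
such as CKD <- HT -> AF.  Identification assumes no exposure-induced
mediator-outcome confounding.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

__all__ = ["MediationSpec", "MediationEffects", "mediation_effects"]


@dataclass
class MediationSpec:
    """Exposure, ordered mediators, and adjustment covariates.

    ``mediators`` must be binary columns listed in topological order (each
    mediator's model conditions on the earlier ones). ``saturated=True``
    replaces logistic fits with exact cell-mean models over the binary
    design (only valid when Z is empty or fully discrete with few cells).
    """

    exposure: str
    mediators: tuple[str, ...]
    adjustment: tuple[str, ...] = ()
    saturated: bool = False


@dataclass
class MediationEffects:
    nde: float
    nie: float
    total: float
    nde_ci: tuple[float, float] | None = None
    nie_ci: tuple[float, float] | None = None


class _CellMeanModel:
    """Saturated model over a binary design: predicted value = cell mean."""

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_CellMeanModel":
        key = [tuple(row) for row in x.astype(int)]
        frame = pd.DataFrame({"k": key, "y": y})
        self.means_ = frame.groupby("k")["y"].mean().to_dict()
        self.default_ = float(y.mean())
        return self

    def predict_proba_1(self, x: np.ndarray) -> np.ndarray:
        return np.array([self.means_.get(tuple(r), self.default_)
                         for r in x.astype(int)])


class _LogisticModel:
    def fit(self, x: np.ndarray, y: np.ndarray) -> "_LogisticModel":
        if y.min() == y.max():
            self.const_ = float(y.mean())
            self.model_ = None
            return self
        self.const_ = None
        self.model_ = LogisticRegression(C=np.inf, max_iter=2000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.model_.fit(x, y)
        return self

    def predict_proba_1(self, x: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            return np.full(len(x), self.const_)
        return self.model_.predict_proba(x)[:, 1]


def _check_binary(df: pd.DataFrame, cols: Sequence[str]) -> None:
    for col in cols:
        vals = df[col].to_numpy()
        if not np.isin(vals, [0, 1]).all():
            raise ValueError(
                f"mediator {col!r} is not binary; only binary mediators are supported")


def mediation_effects(df: pd.DataFrame, spec: MediationSpec,
                      outcome: str = "y", n_boot: int = 0,
                      seed: int = 0) -> MediationEffects:
    """Estimate NDE, NIE and the total effect by the mediational g-formula.

    The outcome model regresses Y on exposure, mediators, their
    exposure-mediator interactions, and Z; mediator models are fitted in
    topological order.  Standardization is over the empirical Z sample.
    Optional percentile-bootstrap CIs with ``n_boot`` resamples.
    """
    _check_binary(df, [spec.exposure, *spec.mediators])
    nde, nie, total = _point_estimates(df, spec, outcome)
    assert abs((nde + nie) - total) < 1e-10, "NDE + NIE must equal the total effect"
    effects = MediationEffects(nde=nde, nie=nie, total=total)
    if n_boot:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(df), len(df))
            reps.append(_point_estimates(
                df.iloc[idx].reset_index(drop=True), spec, outcome)[:2])
        reps_arr = np.asarray(reps)
        lo, hi = np.quantile(reps_arr, [0.025, 0.975], axis=0)
        effects.nde_ci = (float(lo[0]), float(hi[0]))
        effects.nie_ci = (float(lo[1]), float(hi[1]))
    return effects


def _point_estimates(df: pd.DataFrame, spec: MediationSpec,
                     outcome: str) -> tuple[float, float, float]:
    x_col, meds, z_cols = spec.exposure, list(spec.mediators), list(spec.adjustment)
    n, k = len(df), len(meds)
    z = df[z_cols].to_numpy(dtype=float) if z_cols else np.empty((n, 0))
    xv = df[x_col].to_numpy(dtype=float)
    mv = df[meds].to_numpy(dtype=float)
    yv = df[outcome].to_numpy(dtype=float)

    model_cls = _CellMeanModel if spec.saturated else _LogisticModel

    # outcome model: exposure, mediators, exposure x mediator interactions, Z
    def y_design(xcol: np.ndarray, mcols: np.ndarray) -> np.ndarray:
        inter = xcol[:, None] * mcols
        return np.column_stack([xcol, mcols, inter, z])

    y_model = model_cls().fit(y_design(xv, mv), yv)

    # mediator models in topological order: m_j ~ x + m_<j + Z
    med_models = []
    for j in range(k):
        design = np.column_stack([xv, mv[:, :j], z])
        med_models.append(model_cls().fit(design, mv[:, j]))

    def joint_med_probs(x_level: float) -> dict[tuple[int, ...], np.ndarray]:
        """P(M = m | X = x_level, Z_i) for every joint configuration m."""
        xcol = np.full(n, x_level)
        probs: dict[tuple[int, ...], np.ndarray] = {(): np.ones(n)}
        for j, model in enumerate(med_models):
            new: dict[tuple[int, ...], np.ndarray] = {}
            for prefix, p_prefix in probs.items():
                mcols = np.tile(np.array(prefix, dtype=float), (n, 1))
                p1 = model.predict_proba_1(np.column_stack([xcol, mcols, z]))
                new[prefix + (1,)] = p_prefix * p1
                new[prefix + (0,)] = p_prefix * (1 - p1)
            probs = new
        return probs

    def y_pred(x_level: float, m_config: tuple[int, ...]) -> np.ndarray:
        xcol = np.full(n, x_level)
        mcols = np.tile(np.array(m_config, dtype=float), (n, 1))
        return y_model.predict_proba_1(y_design(xcol, mcols))

    pm0, pm1 = joint_med_probs(0.0), joint_med_probs(1.0)
    nde = nie = total = 0.0
    for m_config in itertools.product((0, 1), repeat=k):
        y1 = y_pred(1.0, m_config)
        y0 = y_pred(0.0, m_config)
        nde += float(np.mean((y1 - y0) * pm0[m_config]))
        nie += float(np.mean(y1 * (pm1[m_config] - pm0[m_config])))
        total += float(np.mean(y1 * pm1[m_config] - y0 * pm0[m_config]))
    return nde, nie, total
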