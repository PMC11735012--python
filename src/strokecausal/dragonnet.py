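"""Dragonnet: a three-headed neural potential-outcome estimator.

A shared representation phi(X) in R^P feeds two outcome heads (predicted
stroke probability under treatment and under control; each row contributes
to the loss only through its factual head) and a propensity head (a single
sigmoid layer).  The propensity cross-entropy term trades off pure outcome
prediction for covariate information relevant to treatment assignment, and
an optional targeted-regularization term with a trainable fluctuation
parameter nudges the outcome heads so that the plug-in treatment-effect
estimate solves (approximately) the efficient estimating equation.

The network is implemented directly in numpy (dense layers, ELU, manual
backpropagation, Adam) — the architecture is small enough that CPU matrix
products dominate and a deep-learning framework adds nothing.  All
randomness (initialization, validation split, batch order) is driven by a
single seed, so training is bit-reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .classical_estimators import PROPENSITY_CLIP

__all__ = [
    "DragonnetConfig",
    "DragonnetModel",
    "DragonnetPredictions",
    "fit_dragonnet",
    "predict_potential_outcomes",
    "cate",
    "ate",
    "causal_risk_ratio",
]

DEFAULT_COVARIATES = ("age", "sex", "bmi", "ckd", "af", "ht", "dm", "dlp")


@dataclass
class DragonnetConfig:
    """Architecture and optimization settings.

    ``representation_width``/``depth`` shape the shared trunk; each outcome
    head has two hidden layers (fixed) of ``head_width`` units.
    ``alpha_loss`` weights the propensity cross-entropy;
    ``targeted_regularization_strength`` weights the fluctuation term
    (0 disables it).
    """

    representation_width: int = 200
    representation_depth: int = 3
    head_width: int = 100
    head_depth: int = 2
    activation: str = "elu"
    alpha_loss: float = 1.0
    targeted_regularization_strength: float = 1.0
    epochs: int = 50
    batch_size: int = 512
    learning_rate: float = 1e-3
    validation_fraction: float = 0.2
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.representation_width < 1:
            raise ValueError("representation_width must be >= 1")
        if self.head_depth != 2:
            raise ValueError("the outcome heads use exactly 2 hidden layers")
        if self.activation != "elu":
            raise ValueError("only ELU activation is supported")


@dataclass
class DragonnetPredictions:
    """Per-patient predicted potential outcomes and propensity."""

    y1_hat: np.ndarray
    y0_hat: np.ndarray
    e_hat: np.ndarray

    def __post_init__(self) -> None:
        for name in ("y1_hat", "y0_hat", "e_hat"):
            v = getattr(self, name)
            if np.any((v <= 0) | (v >= 1)):
                raise ValueError(f"{name} must lie strictly in (0, 1)")

    @property
    def ite_hat(self) -> np.ndarray:
        return self.y1_hat - self.y0_hat


# ---------------------------------------------------------------------------
# numpy MLP machinery
# ---------------------------------------------------------------------------

def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(x))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class _MLP:
    """Dense stack with ELU hidden activations and a linear final layer."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W = [rng.normal(0.0, np.sqrt(2.0 / sizes[i]),
                             (sizes[i], sizes[i + 1]))
                  for i in range(len(sizes) - 1)]
        self.b = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def params(self) -> list[np.ndarray]:
        return self.W + self.b

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._inputs, self._pre = [], []
        h = x
        last = len(self.W) - 1
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            self._inputs.append(h)
            a = h @ w + b
            self._pre.append(a)
            h = _elu(a) if i < last else a
        return h

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        """Accumulate parameter grads; return gradient w.r.t. the input."""
        self.gW = [None] * len(self.W)
        self.gb = [None] * len(self.b)
        g = grad_out
        last = len(self.W) - 1
        for i in range(last, -1, -1):
            if i < last:
                g = g * _elu_grad(self._pre[i])
            self.gW[i] = self._inputs[i].T @ g
            self.gb[i] = g.sum(axis=0)
            g = g @ self.W[i].T
        return g

    def grads(self) -> list[np.ndarray]:
        return self.gW + self.gb


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DragonnetModel:
    """Trained Dragonnet: trunk, two outcome heads, propensity head.

    Continuous covariates are z-scored with training-split statistics stored
    on the model, so prediction-time inputs use the raw cohort scale.
    """

    def __init__(self, config: DragonnetConfig, covariates: Sequence[str]):
        self.config = config
        self.covariates = list(covariates)
        rng = np.random.default_rng(config.seed)
        d, p, h = len(self.covariates), config.representation_width, config.head_width
        trunk_sizes = [d] + [p] * config.representation_depth
        self.trunk = _MLP(trunk_sizes, rng)
        self.head0 = _MLP([p, h, h, 1], rng)
        self.head1 = _MLP([p, h, h, 1], rng)
        self.prop = _MLP([p, 1], rng)
        self.eps_param = np.zeros(1)
        self.norm_mean: np.ndarray | None = None
        self.norm_sd: np.ndarray | None = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
        self._rng = rng

    # -- data prep ---------------------------------------------------------------
    def _standardize(self, df: pd.DataFrame, fit: bool) -> np.ndarray:
        x = df[self.covariates].to_numpy(dtype=float)
        if fit:
            binary = np.array([np.isin(x[:, j], [0, 1]).all()
                               for j in range(x.shape[1])])
            self.norm_mean = np.where(binary, 0.0, x.mean(axis=0))
            sd = x.std(axis=0)
            self.norm_sd = np.where(binary | (sd == 0), 1.0, sd)
        if self.norm_mean is None:
            raise ValueError("model is not fitted")
        if list(df[self.covariates].columns) != self.covariates:
            raise ValueError("covariate schema mismatch")
        return (x - self.norm_mean) / self.norm_sd

    # -- forward / backward ------------------------------------------------------
    def _forward(self, x: np.ndarray) -> tuple[np.ndarray, ...]:
        z = self.trunk.forward(x)
        o0 = self.head0.forward(z)[:, 0]
        o1 = self.head1.forward(z)[:, 0]
        oe = self.prop.forward(z)[:, 0]
        return z, o0, o1, oe

    def _loss_terms(self, o0, o1, oe, y, t) -> tuple[float, dict]:
        cfg = self.config
        y0, y1, e = _sigmoid(o0), _sigmoid(o1), _sigmoid(oe)
        clip = lambda p: np.clip(p, 1e-7, 1 - 1e-7)
        bce = lambda p, target: -(target * np.log(clip(p))
                                  + (1 - target) * np.log(1 - clip(p)))
        n = len(y)
        loss = float(np.mean(t * bce(y1, y) + (1 - t) * bce(y0, y)))
        loss += cfg.alpha_loss * float(np.mean(bce(e, t)))
        aux = {"y0": y0, "y1": y1, "e": e}
        if cfg.targeted_regularization_strength > 0:
            e_c = np.clip(e, *PROPENSITY_CLIP)
            q = t * y1 + (1 - t) * y0
            h = t / e_c - (1 - t) / (1 - e_c)
            r = q + self.eps_param[0] * h - y
            loss += cfg.targeted_regularization_strength * float(np.mean(r * r))
            aux.update(e_c=e_c, h=h, r=r)
        return loss, aux

    def _train_batch(self, x, y, t, opt: _Adam) -> None:
        cfg = self.config
        n = len(y)
        _, o0, o1, oe = self._forward(x)
        _, aux = self._loss_terms(o0, o1, oe, y, t)
        y0, y1, e = aux["y0"], aux["y1"], aux["e"]
        go1 = t * (y1 - y) / n
        go0 = (1 - t) * (y0 - y) / n
        goe = cfg.alpha_loss * (e - t) / n
        geps = np.zeros(1)
        if cfg.targeted_regularization_strength > 0:
            beta = cfg.targeted_regularization_strength
            r, h, e_c = aux["r"], aux["h"], aux["e_c"]
            dq = 2.0 * beta * r / n
            go1 += dq * t * y1 * (1 - y1)
            go0 += dq * (1 - t) * y0 * (1 - y0)
            geps[0] = 2.0 * beta * float(np.mean(r * h))
            dh_de = -t / e_c ** 2 - (1 - t) / (1 - e_c) ** 2
            inside = (e > PROPENSITY_CLIP[0]) & (e < PROPENSITY_CLIP[1])
            goe += (2.0 * beta * r * self.eps_param[0] * dh_de
                    * e * (1 - e) * inside) / n
        gz = self.head1.backward(go1[:, None])
        gz += self.head0.backward(go0[:, None])
        gz += self.prop.backward(goe[:, None])
        self.trunk.backward(gz)
        grads = (self.trunk.grads() + self.head0.grads() + self.head1.grads()
                 + self.prop.grads() + [geps])
        opt.step(grads)

    def _all_params(self) -> list[np.ndarray]:
        return (self.trunk.params() + self.head0.params() + self.head1.params()
                + self.prop.params() + [self.eps_param])

    def evaluate_loss(self, x: np.ndarray, y: np.ndarray,
                      t: np.ndarray) -> float:
        _, o0, o1, oe = self._forward(x)
        return self._loss_terms(o0, o1, oe, y, t)[0]

    # -- training ----------------------------------------------------------------
    def fit(self, df: pd.DataFrame, exposure: str = "t",
            outcome: str = "y") -> "DragonnetModel":
        cfg = self.config
        t_all = df[exposure].to_numpy(dtype=float)
        y_all = df[outcome].to_numpy(dtype=float)
        if t_all.min() == t_all.max():
            raise ValueError("exposure is constant; Dragonnet needs both arms")
        x_all = self._standardize(df, fit=True)
        n = len(df)
        perm = self._rng.permutation(n)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr, t_tr = x_all[tr_idx], y_all[tr_idx], t_all[tr_idx]
        x_val, y_val, t_val = x_all[val_idx], y_all[val_idx], t_all[val_idx]

        opt = _Adam(self._all_params(), cfg.learning_rate)
        best_val, best_state, stale = np.inf, None, 0
        for epoch in range(cfg.epochs):
            order = self._rng.permutation(len(tr_idx))
            for start in range(0, len(order), cfg.batch_size):
                sel = order[start:start + cfg.batch_size]
                self._train_batch(x_tr[sel], y_tr[sel], t_tr[sel], opt)
            train_loss = self.evaluate_loss(x_tr, y_tr, t_tr)
            val_loss = self.evaluate_loss(x_val, y_val, t_val)
            if not np.isfinite(train_loss) or not np.isfinite(val_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: train={train_loss}, "
                    f"val={val_loss}; try a lower learning rate")
            self.history["train_loss"].append(train_loss)
            self.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val, stale = val_loss, 0
                best_state = [p.copy() for p in self._all_params()]
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
        if best_state is not None:
            for p, s in zip(self._all_params(), best_state):
                p[...] = s
        return self

    # -- prediction ---------------------------------------------------------------
    def predict(self, df: pd.DataFrame) -> DragonnetPredictions:
        x = self._standardize(df, fit=False)
        _, o0, o1, oe = self._forward(x)
        tiny = 1e-12
        return DragonnetPredictions(
            y1_hat=np.clip(_sigmoid(o1), tiny, 1 - tiny),
            y0_hat=np.clip(_sigmoid(o0), tiny, 1 - tiny),
            e_hat=np.clip(_sigmoid(oe), tiny, 1 - tiny),
        )

    # -- persistence ---------------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        arrays = {f"p{i}": p for i, p in enumerate(self._all_params())}
        arrays["norm_mean"], arrays["norm_sd"] = self.norm_mean, self.norm_sd
        meta = {"config": self.config.__dict__, "covariates": self.covariates}
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "DragonnetModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(DragonnetConfig(**meta["config"]), meta["covariates"])
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(model._all_params()):
            p[...] = data[f"p{i}"]
        model.norm_mean, model.norm_sd = data["norm_mean"], data["norm_sd"]
        return model


# ---------------------------------------------------------------------------
# functional API
# ---------------------------------------------------------------------------

def fit_dragonnet(df: pd.DataFrame, exposure: str = "t",
                  covariates: Sequence[str] = DEFAULT_COVARIATES,
                  config: DragonnetConfig | None = None,
                  outcome: str = "y") -> DragonnetModel:
    """Train a Dragonnet on a cohort DataFrame; fully seeded via the config."""
    model = DragonnetModel(config or DragonnetConfig(), covariates)
    return model.fit(df, exposure=exposure, outcome=outcome)


def predict_potential_outcomes(model: DragonnetModel,
                               df: pd.DataFrame) -> DragonnetPredictions:
    """Deterministic forward pass producing y1_hat, y0_hat, e_hat."""
    return model.predict(df)


def cate(preds: DragonnetPredictions, conditioning: Sequence[str],
         df: pd.DataFrame) -> pd.DataFrame:
    """Mean predicted risk difference within each conditioning-level stratum.

    An empty conditioning set yields the single-row overall ATE.
    """
    contrast = preds.ite_hat
    if not list(conditioning):
        return pd.DataFrame({"stratum": ["all"], "cate": [float(contrast.mean())],
                             "n": [len(contrast)]})
    frame = df[list(conditioning)].copy()
    frame["__c"] = contrast
    grouped = frame.groupby(list(conditioning), observed=True)["__c"]
    out = grouped.agg(["mean", "size"]).reset_index()
    out = out.rename(columns={"mean": "cate", "size": "n"})
    if (out["n"] == 0).any():
        warnings.warn("empty strata omitted from CATE table", RuntimeWarning,
                      stacklevel=2)
        out = out[out["n"] > 0]
    return out


def ate(preds: DragonnetPredictions, t: np.ndarray, y: np.ndarray,
        method: str = "aipw") -> float:
    """Average treatment effect from Dragonnet predictions.

    ``plugin`` averages the head contrast; ``aipw`` applies the augmented
    IPW correction with the propensity head (clipped), the standard
    bias-corrected readout for Dragonnet outputs.
    """
    if method == "plugin":
        return float(np.mean(preds.ite_hat))
    if method != "aipw":
        raise ValueError("method must be 'plugin' or 'aipw'")
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    e = np.clip(preds.e_hat, *PROPENSITY_CLIP)
    psi = (preds.y1_hat - preds.y0_hat
           + t * (y - preds.y1_hat) / e
           - (1 - t) * (y - preds.y0_hat) / (1 - e))
    return float(np.mean(psi))


def causal_risk_ratio(preds: DragonnetPredictions, n_boot: int = 500,
                      seed: int = 0) -> tuple[float, tuple[float, float]]:
    """mean(y1_hat)/mean(y0_hat) with a patient-level bootstrap CI."""
    m0 = float(np.mean(preds.y0_hat))
    if m0 < 1e-8:
        raise ValueError("mean control risk is numerically zero")
    ratio = float(np.mean(preds.y1_hat)) / m0
    rng = np.random.default_rng(seed)
    n = len(preds.y1_hat)
    reps = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        reps.append(np.mean(preds.y1_hat[idx]) / np.mean(preds.y0_hat[idx]))
    lo, hi = np.quantile(reps, [0.025, 0.975])
    return ratio, (float(lo), float(hi))
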