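"""End-to-end orchestration: cohort, estimator table, mediation, ITE bundle.

``run_full_analysis`` reproduces the shape of the full study on one cohort:
for each risk factor it derives the backdoor adjustment set from the default
DAG and runs the requested average-effect estimators; for exposures with
disease mediators it adds a natural direct/indirect decomposition; and for
antiplatelet treatment it trains a Dragonnet, builds nested weighted
split-conformal ITE intervals, and summarizes mean ITEs by risk-factor
stratum among untreated patients.  Stage failures are recorded in the run
manifest without aborting independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import causal_graph as cg
from .classical_estimators import (
    EffectEstimate,
    dre_ate,
    ipw_ate,
    logistic_or_baseline,
    naive_difference,
    sps_ate,
    with_bootstrap_ci,
)
from .conformal_ite import (
    ConformalConfig,
    nested_ite_intervals,
    stratified_ite_summary,
)
from .dml import DMLConfig, dml_ate
from .dragonnet import DragonnetConfig, causal_risk_ratio, fit_dragonnet
from .mediation import MediationSpec, mediation_effects
from .synthetic_cohort import Cohort, CohortSpec, generate_cohort, read_cohort

__all__ = ["AnalysisConfig", "run_full_analysis", "effect_comparison_table"]

logger = logging.getLogger("strokecausal")

ALL_ESTIMATORS = ("naive", "logistic-or", "sps", "ipw", "dre",
                  "dml-linear", "dml-nonlinear")


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run.

    The cohort comes either from ``cohort_csv`` or from ``cohort_spec``
    (synthetic).  ``seed`` is propagated to every stochastic component;
    ``n_boot = 0`` skips bootstrap CIs for the classical estimators.
    """

    cohort_csv: str | None = None
    cohort_spec: CohortSpec | None = None
    exposures: tuple[str, ...] = ("af", "ht", "dm", "dlp")
    estimators: tuple[str, ...] = ALL_ESTIMATORS
    run_mediation: bool = True
    run_ite: bool = True
    dragonnet: DragonnetConfig = field(default_factory=DragonnetConfig)
    conformal: ConformalConfig = field(default_factory=ConformalConfig)
    n_boot: int = 0
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.estimators:
            raise ValueError("at least one estimator is required")
        unknown = set(self.estimators) - set(ALL_ESTIMATORS)
        if unknown:
            raise ValueError(f"unknown estimators: {sorted(unknown)}")


def _config_hash(config: AnalysisConfig) -> str:
    as_text = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(as_text.encode()).hexdigest()[:16]


def _run_estimator(name: str, df: pd.DataFrame, exposure: str,
                   adjustment: list[str], config: AnalysisConfig
                   ) -> EffectEstimate:
    seed = config.seed
    dispatch = {
        "naive": lambda d: naive_difference(d, exposure),
        "logistic-or": lambda d: logistic_or_baseline(d, exposure, adjustment),
        "sps": lambda d: sps_ate(d, exposure, adjustment),
        "ipw": lambda d: ipw_ate(d, exposure, adjustment),
        "dre": lambda d: dre_ate(d, exposure, adjustment),
    }
    if name in dispatch:
        fn = dispatch[name]
        if config.n_boot and name not in ("logistic-or",):
            return with_bootstrap_ci(fn, df, n_boot=config.n_boot, seed=seed)
        return fn(df)
    variant = name.split("-", 1)[1]
    return dml_ate(df, exposure, adjustment,
                   DMLConfig(variant=variant, seed=seed))


def effect_comparison_table(results: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy exposure x estimator table of points and CI bounds."""
    if not results:
        raise ValueError("no completed estimates to tabulate")
    return pd.DataFrame([
        {"estimator": r.estimator, "exposure": r.exposure, "scale": r.scale,
         "point": r.point, "ci_low": r.ci_low, "ci_high": r.ci_high}
        for r in results
    ])


def run_full_analysis(config: AnalysisConfig) -> dict:
    """Run every requested stage; return the report bundle.

    Returns a dict with the effects table, mediation table, ITE interval
    table, stratified summary, Dragonnet risk ratios, and the manifest.
    All tables are also written as CSV under ``config.output_dir``.
    """
    t_start = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(config), "seed": config.seed,
                      "stages": {}, "versions": _versions()}

    if config.cohort_csv:
        cohort = read_cohort(config.cohort_csv)
    else:
        spec = config.cohort_spec or CohortSpec(n=20_000, seed=config.seed)
        cohort, _ = generate_cohort(spec)
        manifest["cohort_spec"] = spec.to_dict()
    df = cohort.frame
    dag = cg.build_default_dag()

    bundle: dict = {"manifest": manifest}

    # --- average effects ------------------------------------------------------
    results: list[EffectEstimate] = []
    for exposure in config.exposures:
        adjustment = sorted(cg.backdoor_adjustment_set(dag, exposure))
        for name in config.estimators:
            stage = f"effect:{exposure}:{name}"
            t0 = time.time()
            try:
                results.append(_run_estimator(name, df, exposure,
                                              adjustment, config))
                manifest["stages"][stage] = {"status": "ok",
                                             "seconds": round(time.time() - t0, 2)}
            except Exception as exc:  # stage isolation
                logger.warning("stage %s failed: %s", stage, exc)
                manifest["stages"][stage] = {"status": "error", "error": str(exc)}
    effects = effect_comparison_table(results) if results else pd.DataFrame()
    bundle["effects"] = effects

    # --- mediation ------------------------------------------------------------
    if config.run_mediation:
        med_rows = []
        topo = {node: i for i, node in enumerate(dag.topological_order())}
        for exposure in config.exposures:
            meds = sorted(cg.disease_mediators(dag, exposure), key=topo.get)
            if not meds:
                continue
            stage = f"mediation:{exposure}"
            try:
                adjustment = tuple(sorted(cg.backdoor_adjustment_set(dag, exposure)))
                spec_m = MediationSpec(exposure=exposure, mediators=tuple(meds),
                                       adjustment=adjustment)
                eff = mediation_effects(df, spec_m, n_boot=0)
                med_rows += [
                    {"estimator": "nde", "exposure": exposure,
                     "scale": "risk-difference", "point": eff.nde,
                     "ci_low": np.nan, "ci_high": np.nan},
                    {"estimator": "nie", "exposure": exposure,
                     "scale": "risk-difference", "point": eff.nie,
                     "ci_low": np.nan, "ci_high": np.nan},
                ]
                manifest["stages"][stage] = {"status": "ok"}
            except Exception as exc:
                logger.warning("stage %s failed: %s", stage, exc)
                manifest["stages"][stage] = {"status": "error", "error": str(exc)}
        bundle["mediation"] = pd.DataFrame(med_rows)

    # --- Dragonnet + conformal ITE for antiplatelet treatment ------------------
    if config.run_ite:
        stage = "ite:antiplatelet"
        try:
            dn_config = dataclasses.replace(config.dragonnet, seed=config.seed)
            model = fit_dragonnet(df, exposure="t", config=dn_config)
            preds = model.predict(df)
            rr, rr_ci = causal_risk_ratio(preds, seed=config.seed)
            cf_config = dataclasses.replace(config.conformal, seed=config.seed)
            intervals = nested_ite_intervals(df, cf_config,
                                             point_estimates=preds.ite_hat)
            summary = stratified_ite_summary(intervals, df)
            bundle["ite_intervals"] = intervals
            bundle["ite_summary"] = pd.DataFrame(
                [dataclasses.asdict(s) for s in summary])
            bundle["treatment_risk_ratio"] = {"ratio": rr, "ci": rr_ci}
            manifest["stages"][stage] = {"status": "ok"}
        except Exception as exc:
            logger.warning("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "error", "error": str(exc)}

    # --- write bundle -----------------------------------------------------------
    effects_all = [bundle.get("effects"), bundle.get("mediation")]
    effects_all = [f for f in effects_all if f is not None and len(f)]
    if effects_all:
        tidy = pd.concat(effects_all, ignore_index=True)
        _validate_effects_schema(tidy)
        tidy.to_csv(out_dir / "effects.csv", index=False)
    if "ite_intervals" in bundle:
        bundle["ite_intervals"].to_csv(out_dir / "ite_intervals.csv", index=False)
        bundle["ite_summary"].to_csv(out_dir / "ite_summary.csv", index=False)
        _export_ite_boxplot(bundle["ite_intervals"], df,
                            out_dir / "ite_by_stratum.png")
    manifest["total_seconds"] = round(time.time() - t_start, 2)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


def _validate_effects_schema(frame: pd.DataFrame) -> None:
    required = ["estimator", "exposure", "scale", "point", "ci_low", "ci_high"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"effects table missing columns: {missing}")
    have_ci = frame.dropna(subset=["ci_low", "ci_high"])
    bad = (have_ci["ci_low"] > have_ci["point"]) | (have_ci["point"] > have_ci["ci_high"])
    if bad.any():
        raise ValueError("confidence bounds do not bracket point estimates")


def _export_ite_boxplot(intervals: pd.DataFrame, df: pd.DataFrame,
                        path: Path) -> None:
    """Box plot of untreated patients' point ITEs by risk-factor stratum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    untreated = intervals[intervals["treated"] == 0]
    rows = df.iloc[untreated["patient_id"].to_numpy()]
    labels = []
    for _, r in rows[["ht", "dm", "dlp"]].iterrows():
        on = [s.upper() for s in ("ht", "dm", "dlp") if r[s] == 1]
        labels.append("+".join(on) if on else "none")
    frame = pd.DataFrame({"stratum": labels, "ite": untreated["point"].to_numpy()})
    order = frame.groupby("stratum")["ite"].mean().sort_values().index
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.boxplot([frame.loc[frame["stratum"] == s, "ite"] for s in order],
               tick_labels=list(order), showfliers=False)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("estimated ITE (risk difference)")
    ax.set_title("Mean ITE of untreated patients by risk-factor stratum")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _versions() -> dict[str, str]:
    import sklearn

    from . import __version__
    return {"strokecausal": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "sklearn": sklearn.__version__}
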