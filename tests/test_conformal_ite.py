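"""Weighted split-CQR machinery and nested ITE intervals."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from strokecausal.conformal_ite import (
    ConformalConfig,
    ITEInterval,
    fit_quantile_bounds,
    nested_ite_intervals,
    stratified_ite_summary,
    weighted_conformal_counterfactual,
    weighted_quantile,
)
from strokecausal.synthetic_cohort import CohortSpec, generate_cohort


def _gaussian_frame(rng, n, sigma=0.5, p_t=0.5, tau=1.0):
    x = rng.normal(size=(n, 2))
    t = rng.binomial(1, p_t, n).astype(float)
    mu = 1.0 + 0.8 * x[:, 0] - 0.5 * x[:, 1]
    y = mu + tau * t + rng.normal(0, sigma, n)
    return pd.DataFrame({"x1": x[:, 0], "x2": x[:, 1], "t": t, "y": y}), mu


GAUSS_CFG = ConformalConfig(covariates=("x1", "x2"), outcome="y", seed=0)


class TestWeightedQuantile:
    def test_equal_scores_return_that_score_for_any_weights(self, rng):
        scores = np.full(40, 1.7)
        for w in (np.ones(40), rng.uniform(0.1, 5.0, 40)):
            assert weighted_quantile(scores, w, 0.95) == pytest.approx(1.7)
            assert weighted_quantile(scores, w, 0.10) == pytest.approx(1.7)

    def test_uniform_weights_match_split_conformal_order_statistic(self, rng):
        scores = rng.normal(size=99)
        got = weighted_quantile(scores, np.ones(99), 0.9)
        k = int(np.ceil(0.9 * (99 + 1)))  # classic split-conformal index
        assert got == pytest.approx(np.sort(scores)[k - 1])

    def test_insufficient_mass_returns_infinity(self):
        assert weighted_quantile(np.array([1.0]), np.array([1.0]), 0.95) == np.inf

    def test_monotone_in_level(self, rng):
        scores = rng.normal(size=200)
        w = rng.uniform(0.5, 2.0, 200)
        qs = [weighted_quantile(scores, w, lev) for lev in (0.5, 0.8, 0.95)]
        assert qs[0] <= qs[1] <= qs[2]


class TestQuantileBounds:
    def test_gaussian_gap_matches_normal_quantiles(self, rng):
        """Homoskedastic Gaussian outcome: the fitted quantile gap sits near
        2 * z_{0.975} * sigma (tree quantiles run mildly narrow)."""
        sigma = 0.5
        df, _ = _gaussian_frame(rng, 12_000, sigma=sigma)
        models = fit_quantile_bounds(df, arm=1, config=GAUSS_CFG)
        x = df[df.t == 1][["x1", "x2"]]
        gap = models["hi"].predict(x) - models["lo"].predict(x)
        expected = 2 * 1.96 * sigma
        assert np.mean(gap) == pytest.approx(expected, rel=0.3)

    def test_zero_noise_quantiles_collapse_to_mean_surface(self, rng):
        """Deterministic outcome: upper and lower quantile surfaces coincide
        up to residual tree-model error and track the mean surface."""
        df, mu = _gaussian_frame(rng, 6000, sigma=0.0)
        models = fit_quantile_bounds(df, arm=0, config=GAUSS_CFG)
        m0 = df.t == 0
        x = df[m0][["x1", "x2"]]
        gap = models["hi"].predict(x) - models["lo"].predict(x)
        assert np.mean(np.abs(gap)) < 0.3
        rmse = np.sqrt(np.mean((models["lo"].predict(x) - mu[m0]) ** 2))
        assert rmse < 0.3

    def test_beats_constant_quantile_baseline_in_pinball_loss(self, rng):
        df, _ = _gaussian_frame(rng, 5000)
        models = fit_quantile_bounds(df, arm=1, config=GAUSS_CFG)
        m1 = df.t == 1
        y = df.loc[m1, "y"].to_numpy()
        q = 1 - GAUSS_CFG.alpha / 2

        def pinball(pred):
            diff = y - pred
            return np.mean(np.maximum(q * diff, (q - 1) * diff))

        fitted = pinball(models["hi"].predict(df[m1][["x1", "x2"]]))
        constant = pinball(np.quantile(y, q))
        assert fitted <= constant

    def test_missing_arm_is_an_error(self, rng):
        df, _ = _gaussian_frame(rng, 200, p_t=0.0)
        with pytest.raises(ValueError, match="absent"):
            fit_quantile_bounds(df, arm=1, config=GAUSS_CFG)


class TestCounterfactualIntervals:
    def test_exchangeable_coverage_at_nominal_level(self, rng):
        """Randomized arms: weighted CQR intervals for the treated-arm
        counterfactual cover fresh potential outcomes at >= 1 - alpha."""
        hits, total = 0, 0
        for rep in range(5):
            df, mu = _gaussian_frame(rng, 3000, sigma=0.5)
            train, calib, test = df.iloc[:1000], df.iloc[1000:2000], df.iloc[2000:]
            mu_test = mu[2000:]
            models = fit_quantile_bounds(train, arm=1, config=GAUSS_CFG)
            e = np.full(len(calib), 0.5)
            ints = weighted_conformal_counterfactual(
                calib, models, target_arm=1, propensity=e,
                df_test=test, config=GAUSS_CFG)
            y1_fresh = mu_test + 1.0 + rng.normal(0, 0.5, len(test))
            hits += ((ints[:, 0] <= y1_fresh) & (y1_fresh <= ints[:, 1])).sum()
            total += len(test)
        assert hits / total >= 0.93

    def test_too_few_calibration_points_rejected(self, rng):
        df, _ = _gaussian_frame(rng, 400)
        models = fit_quantile_bounds(df, arm=1, config=GAUSS_CFG)
        tiny = df.iloc[:30]
        with pytest.raises(ValueError, match="25"):
            weighted_conformal_counterfactual(
                tiny[tiny.t == 1], models, 1, np.full((tiny.t == 1).sum(), 0.5),
                df, GAUSS_CFG)


class TestNestedIntervals:
    def test_interval_invariants_and_split_bookkeeping(self):
        spec = CohortSpec(n=3000, seed=17, outcome_mode="latent")
        cohort, _ = generate_cohort(spec)
        cfg = ConformalConfig(outcome="y_latent", seed=5)
        ints = nested_ite_intervals(cohort.frame, cfg)
        assert len(ints) == 1500  # even split
        assert ints["patient_id"].is_unique
        assert (ints["lo"] <= ints["point"]).all()
        assert (ints["point"] <= ints["hi"]).all()
        for _, row in ints.head(3).iterrows():
            ITEInterval(point=row["point"], lo=row["lo"], hi=row["hi"])
        again = nested_ite_intervals(cohort.frame, cfg)
        pd.testing.assert_frame_equal(ints, again)

    def test_width_monotone_in_alpha(self):
        spec = CohortSpec(n=3000, seed=19, outcome_mode="latent")
        cohort, _ = generate_cohort(spec)
        widths = {}
        for alpha in (0.01, 0.1, 0.2):
            cfg = ConformalConfig(outcome="y_latent", seed=5, alpha=alpha)
            ints = nested_ite_intervals(cohort.frame, cfg)
            widths[alpha] = float((ints["hi"] - ints["lo"]).mean())
        assert widths[0.01] >= widths[0.1] >= widths[0.2]

    def test_noise_free_outcome_gives_full_coverage_and_tighter_intervals(self):
        """As outcome noise vanishes the intervals tighten (residual width
        reflects quantile-model error only) and cover every true ITE."""
        widths = {}
        for sd in (1e-8, 1.0):
            spec = CohortSpec(n=4000, seed=23, outcome_mode="latent",
                              latent_noise_sd=sd)
            cohort, gt = generate_cohort(spec)
            cfg = ConformalConfig(outcome="y_latent", seed=1)
            ints = nested_ite_intervals(cohort.frame, cfg)
            true = gt.latent_ite[ints["patient_id"].to_numpy()]
            covered = (ints["lo"] <= true) & (true <= ints["hi"])
            if sd < 1e-6:
                assert covered.mean() == 1.0
            widths[sd] = float((ints["hi"] - ints["lo"]).mean())
        assert widths[1e-8] < 0.55 * widths[1.0]

    def test_uniform_weight_mode_also_covers(self):
        spec = CohortSpec(n=2000, seed=29, outcome_mode="latent")
        cohort, gt = generate_cohort(spec)
        cfg = ConformalConfig(outcome="y_latent", seed=2, weight_mode="uniform")
        ints = nested_ite_intervals(cohort.frame, cfg)
        true = gt.latent_ite[ints["patient_id"].to_numpy()]
        assert ((ints["lo"] <= true) & (true <= ints["hi"])).mean() >= 0.95


class TestStratifiedSummary:
    @staticmethod
    def _cohort_with_true_points(n=6000, seed=31):
        spec = CohortSpec(n=n, seed=seed, outcome_mode="latent")
        cohort, gt = generate_cohort(spec)
        cfg = ConformalConfig(outcome="y_latent", seed=3)
        ints = nested_ite_intervals(cohort.frame, cfg,
                                    point_estimates=gt.ite)
        return cohort.frame, ints

    def test_counts_partition_untreated_patients(self):
        df, ints = self._cohort_with_true_points()
        summary = stratified_ite_summary(ints, df)
        assert sum(s.n for s in summary) == int((ints["treated"] == 0).sum())
        for s in summary:
            assert s.iqr_low <= s.iqr_high

    def test_diabetes_strata_benefit_most(self):
        """Treatment benefit concentrates where the generator places it:
        strata containing DM have the most negative mean ITEs."""
        df, ints = self._cohort_with_true_points()
        summary = stratified_ite_summary(ints, df)
        by_name = {s.stratum: s.mean_ite for s in summary}
        dm_means = [v for k, v in by_name.items() if "DM" in k.split("+")]
        other = [v for k, v in by_name.items() if "DM" not in k.split("+")]
        assert max(dm_means) < min(other)

    def test_constant_ites_give_degenerate_summary(self):
        df = pd.DataFrame({"ht": [0, 1, 0, 1] * 10, "dm": [0, 0, 1, 1] * 10,
                           "dlp": [0] * 40})
        ints = pd.DataFrame({"patient_id": np.arange(40),
                             "point": np.full(40, -0.02),
                             "lo": np.full(40, -0.1), "hi": np.full(40, 0.05),
                             "treated": np.zeros(40, int)})
        summary = stratified_ite_summary(ints, df)
        for s in summary:
            assert s.mean_ite == pytest.approx(-0.02)
            assert s.iqr_high - s.iqr_low == pytest.approx(0.0)

    def test_af_cannot_define_a_stratum(self):
        df, ints = self._cohort_with_true_points(n=2000, seed=37)
        with pytest.raises(ValueError, match="AF"):
            stratified_ite_summary(ints, df, strata=("af", "dm"))
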