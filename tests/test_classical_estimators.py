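"""Propensity, SPS, IPW, DRE and bootstrap behavior on toys and cohorts."""

import numpy as np
import pandas as pd
import pytest

from strokecausal.classical_estimators import (
    PropensityScores,
    bootstrap_ci,
    dre_ate,
    fit_propensity,
    ipw_ate,
    logistic_or_baseline,
    naive_difference,
    sps_ate,
)
from strokecausal.synthetic_cohort import CohortSpec, generate_cohort


def _toy_frame(a, y, **covs):
    return pd.DataFrame({"t": np.asarray(a, float),
                         "y": np.asarray(y, float),
                         **{k: np.asarray(v, float) for k, v in covs.items()}})


class TestPropensity:
    def test_coin_flip_exposure_gives_constant_half(self, rng):
        n = 4000
        df = _toy_frame(rng.binomial(1, 0.5, n), rng.binomial(1, 0.3, n),
                        x=rng.normal(size=n))
        e = fit_propensity(df, "t", ["x"]).e
        assert np.all(np.abs(e - 0.5) < 0.06)

    def test_matches_two_by_two_conditional_frequencies(self, rng):
        n = 20_000
        z = rng.binomial(1, 0.5, n)
        a = np.where(rng.uniform(size=n) < 0.9, z, 1 - z)
        df = _toy_frame(a, np.zeros(n), z=z)
        e = fit_propensity(df, "t", ["z"]).e
        for level in (0, 1):
            empirical = a[z == level].mean()
            np.testing.assert_allclose(e[z == level], empirical, atol=0.02)

    def test_decile_calibration_on_default_cohort(self, default_cohort_20k):
        _, df, _ = default_cohort_20k
        e = fit_propensity(df, "t", ["age", "ht", "dm", "dlp"]).e
        deciles = pd.qcut(e, 10, labels=False, duplicates="drop")
        for d in np.unique(deciles):
            mask = deciles == d
            assert abs(e[mask].mean() - df.loc[mask, "t"].mean()) < 0.05

    def test_constant_exposure_is_an_error(self):
        df = _toy_frame(np.ones(20), np.zeros(20), x=np.arange(20))
        with pytest.raises(ValueError, match="constant"):
            fit_propensity(df, "t", ["x"])

    def test_scores_are_clipped(self):
        with pytest.raises(ValueError):
            PropensityScores(e=np.array([0.0, 0.5]))


class TestSps:
    def test_single_stratum_equals_mean_difference(self, rng):
        n = 400
        df = _toy_frame(rng.binomial(1, 0.5, n), rng.binomial(1, 0.4, n))
        e = PropensityScores(e=np.full(n, 0.5))
        est = sps_ate(df, "t", [], propensity=e, min_arm=1000)
        assert est.point == pytest.approx(naive_difference(df, "t").point)

    def test_two_handbuilt_strata_weighted_difference(self):
        """Known cell means in two propensity strata: the SPS estimate is the
        size-weighted average of within-stratum contrasts, computed by hand."""
        # stratum A (e=0.2): 40 rows, y1 mean 0.8, y0 mean 0.5
        # stratum B (e=0.8): 60 rows, y1 mean 0.4, y0 mean 0.1
        rows = []
        for e_val, n_s, p1, p0, n1 in ((0.2, 40, 0.8, 0.5, 15), (0.8, 60, 0.4, 0.1, 45)):
            for i in range(n_s):
                a = 1.0 if i < n1 else 0.0
                frac = (i if a else i - n1) / (n1 if a else n_s - n1)
                y = 1.0 if frac < (p1 if a else p0) else 0.0
                rows.append((a, y, e_val))
        df = pd.DataFrame(rows, columns=["t", "y", "e"])
        e = PropensityScores(e=df["e"].to_numpy())
        got = sps_ate(df, "t", [], propensity=e, min_arm=5).point
        y = df["y"].to_numpy()
        a = df["t"].to_numpy()
        s = df["e"].to_numpy()
        expected = 0.0
        for e_val, w in ((0.2, 0.4), (0.8, 0.6)):
            m = s == e_val
            expected += w * (y[m][a[m] == 1].mean() - y[m][a[m] == 0].mean())
        assert got == pytest.approx(expected, abs=1e-12)

    def test_recovers_truth_on_randomized_cohort(self, randomized_cohort_20k):
        _, df, gt = randomized_cohort_20k
        est = sps_ate(df, "t", ["age", "sex", "bmi", "ckd", "af", "ht", "dm", "dlp"])
        se = np.sqrt(df["y"].var() * (1 / (df.t == 1).sum() + 1 / (df.t == 0).sum()))
        assert abs(est.point - gt.ate) < 3 * se


class TestIpw:
    def test_half_propensity_reduces_to_doubled_arm_means(self, rng):
        n = 1000
        df = _toy_frame(rng.binomial(1, 0.5, n), rng.binomial(1, 0.3, n))
        e = PropensityScores(e=np.full(n, 0.5))
        est = ipw_ate(df, "t", [], propensity=e)
        a, y = df["t"].to_numpy(), df["y"].to_numpy()
        assert est.point == pytest.approx(2 * np.mean(a * y) - 2 * np.mean((1 - a) * y))

    def test_eight_row_hand_summed_horvitz_thompson(self):
        a = [1, 1, 1, 0, 0, 0, 1, 0]
        y = [1, 0, 1, 1, 0, 0, 1, 1]
        e = [0.8, 0.6, 0.4, 0.3, 0.5, 0.7, 0.5, 0.2]
        df = _toy_frame(a, y)
        est = ipw_ate(df, "t", [], propensity=PropensityScores(e=np.array(e)))
        expected = (1 / 0.8 + 1 / 0.4 + 1 / 0.5) / 8 \
            - (1 / 0.7 + 1 / 0.8) / 8
        assert est.point == pytest.approx(expected, abs=1e-12)

    def test_covariate_permutation_invariance_with_flat_propensity(self, rng):
        n = 500
        df = _toy_frame(rng.binomial(1, 0.5, n), rng.binomial(1, 0.4, n),
                        x=rng.normal(size=n))
        e = PropensityScores(e=np.full(n, 0.5))
        est1 = ipw_ate(df, "t", ["x"], propensity=e).point
        df2 = df.assign(x=rng.permutation(df["x"].to_numpy()))
        est2 = ipw_ate(df2, "t", ["x"], propensity=e).point
        assert est1 == est2

    def test_corrects_confounding_where_naive_fails(self, default_cohort_20k):
        _, df, gt = default_cohort_20k
        adj = ["age", "sex", "bmi", "ckd", "af", "ht", "dm", "dlp"]
        est = ipw_ate(df, "t", adj)
        # influence-function SE of the Horvitz-Thompson contrast
        e = fit_propensity(df, "t", adj).e
        a, y = df["t"].to_numpy(), df["y"].to_numpy()
        psi = a * y / e - (1 - a) * y / (1 - e)
        se = psi.std() / np.sqrt(len(df))
        assert abs(est.point - gt.ate) < 3 * se
        assert abs(naive_difference(df, "t").point - gt.ate) > 3 * se


class TestDre:
    def test_oracle_nuisances_on_noiseless_outcome(self):
        """With deterministic outcomes and exact nuisances the correction
        terms vanish and AIPW equals the plug-in mean ITE exactly."""
        n = 200
        rng = np.random.default_rng(0)
        z = rng.binomial(1, 0.5, n).astype(float)
        a = rng.binomial(1, 0.3 + 0.4 * z).astype(float)
        m1 = 0.2 + 0.6 * z  # potential-outcome probabilities
        m0 = 0.1 + 0.3 * z
        y = np.where(a == 1, m1, m0)  # noiseless: Y == m_A exactly
        df = _toy_frame(a, y, z=z)
        e = PropensityScores(e=0.3 + 0.4 * z)
        est = dre_ate(df, "t", ["z"], propensity=e, outcome_models=(m0, m1))
        assert est.point == pytest.approx(np.mean(m1 - m0), abs=1e-12)

    @staticmethod
    def _aipw_se(df, m0, m1, e):
        a, y = df["t"].to_numpy(), df["y"].to_numpy()
        psi = m1 - m0 + a * (y - m1) / e - (1 - a) * (y - m0) / (1 - e)
        return psi.std() / np.sqrt(len(df))

    def test_double_robustness_both_ways(self, default_cohort_20k):
        """One correct nuisance suffices; IPW with the wrong propensity and
        the plug-in with the wrong outcome model both fail."""
        _, df, gt = default_cohort_20k
        adj = ["age", "sex", "bmi", "ckd", "af", "ht", "dm", "dlp"]
        n = len(df)
        a, y = df["t"].to_numpy(), df["y"].to_numpy()
        marginal = np.full(n, np.clip(a.mean(), 0.01, 0.99))
        bad_prop = PropensityScores(e=marginal)
        bad_m0 = np.full(n, y[a == 0].mean())  # intercept-only outcome model
        bad_m1 = np.full(n, y[a == 1].mean())
        good_e = fit_propensity(df, "t", adj).e

        # arm 1: outcome model wrong, propensity right
        est1 = dre_ate(df, "t", adj, outcome_models=(bad_m0, bad_m1))
        se1 = self._aipw_se(df, bad_m0, bad_m1, good_e)
        assert abs(est1.point - gt.ate) < 3 * se1

        # arm 2: propensity wrong, outcome model right (CV lasso default)
        est2 = dre_ate(df, "t", adj, propensity=bad_prop)
        assert abs(est2.point - gt.ate) < 0.004

        # the discriminating failures
        ipw_bad = ipw_ate(df, "t", adj, propensity=bad_prop)
        assert abs(ipw_bad.point - gt.ate) > 3 * se1
        plugin_bad = float(np.mean(bad_m1 - bad_m0))
        assert abs(plugin_bad - gt.ate) > 3 * se1


class TestLogisticOr:
    def test_two_by_two_cross_product_ratio(self):
        a = [1] * 30 + [0] * 30
        y = [1] * 20 + [0] * 10 + [1] * 10 + [0] * 20
        est = logistic_or_baseline(_toy_frame(a, y), "t", [])
        assert est.scale == "odds-ratio"
        assert est.point == pytest.approx(4.0, rel=1e-4)
        assert est.ci_low < 4.0 < est.ci_high

    def test_matches_grid_search_likelihood_oracle(self):
        """The fitted exposure coefficient maximizes the Bernoulli likelihood,
        checked against a brute-force grid over (intercept, beta)."""
        rng = np.random.default_rng(3)
        n = 400
        a = rng.binomial(1, 0.5, n).astype(float)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.9 * a)))).astype(float)
        df = _toy_frame(a, y)
        est = logistic_or_baseline(df, "t", [])

        def loglik(b0, b1):
            eta = b0 + b1 * a
            return np.sum(y * eta - np.log1p(np.exp(eta)))

        grid = np.linspace(-2, 2, 161)
        best = max(((b0, b1) for b0 in grid for b1 in grid),
                   key=lambda p: loglik(*p))
        assert np.log(est.point) == pytest.approx(best[1], abs=0.05)

    def test_null_cohort_odds_ratio_near_one(self):
        cohort, _ = generate_cohort(CohortSpec.null(n=20_000, seed=6, incidence=0.3))
        est = logistic_or_baseline(cohort.frame, "af", ["age"])
        assert est.point == pytest.approx(1.0, abs=0.15)


class TestBootstrap:
    def test_seeded_interval_is_reproducible(self, rng):
        df = _toy_frame(rng.binomial(1, 0.5, 300), rng.binomial(1, 0.4, 300))
        fn = lambda d: naive_difference(d, "t").point
        assert bootstrap_ci(fn, df, 150, seed=5) == bootstrap_ci(fn, df, 150, seed=5)
        assert bootstrap_ci(fn, df, 150, seed=5) != bootstrap_ci(fn, df, 150, seed=6)

    def test_degenerate_outcome_gives_zero_width(self, rng):
        df = _toy_frame(rng.binomial(1, 0.5, 100), np.ones(100))
        lo, hi = bootstrap_ci(lambda d: naive_difference(d, "t").point, df, 100, 1)
        assert lo == hi == 0.0

    def test_too_few_resamples_rejected(self, rng):
        df = _toy_frame(rng.binomial(1, 0.5, 50), rng.binomial(1, 0.5, 50))
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, df, 50, 1)

    def test_ipw_interval_covers_nominally(self):
        """Monte-Carlo coverage of the percentile bootstrap for the IPW
        estimator on small randomized cohorts is close to 95%."""
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            spec = CohortSpec(n=600, seed=20_000 + rep).randomized()
            cohort, gt = generate_cohort(spec)
            fn = lambda d: ipw_ate(d, "t", ["ht", "dm", "age"]).point
            lo, hi = bootstrap_ci(fn, cohort.frame, 120, seed=rep)
            hits += lo <= gt.ate <= hi
        coverage = hits / n_rep
        assert coverage >= 0.85  # 95% nominal minus Monte-Carlo slack
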