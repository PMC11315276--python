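"""Estimation statistics, factorial ANOVA, correlations and masking."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import vigispec as v


class TestMeanDifferenceCI:
    def test_identical_groups_centered_on_zero(self, rng):
        x = rng.normal(0, 1, 20)
        e = v.mean_difference_ci(x, x.copy(), seed=0)
        assert e.mean_diff == 0.0
        assert e.ci_low <= 0.0 <= e.ci_high
        assert not e.significant

    def test_matches_normal_theory_interval(self, rng):
        """Shifted normal samples: bootstrap CI ≈ the t-interval."""
        a = rng.normal(0.0, 0.1, 20)
        b = rng.normal(0.4, 0.1, 20)
        e = v.mean_difference_ci(a, b, n_boot=10_000, seed=1)
        se = np.sqrt(a.var(ddof=1) / 20 + b.var(ddof=1) / 20)
        t = sstats.t.ppf(0.975, 38)
        lo, hi = (b.mean() - a.mean()) - t * se, (b.mean() - a.mean()) + t * se
        width = hi - lo
        assert e.ci_low == pytest.approx(lo, abs=0.2 * width)
        assert e.ci_high == pytest.approx(hi, abs=0.2 * width)
        assert e.significant

    def test_bonferroni_widens_interval(self, rng):
        a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 15)
        e1 = v.mean_difference_ci(a, b, n_comparisons=1, seed=3)
        e9 = v.mean_difference_ci(a, b, n_comparisons=9, seed=3)
        assert (e9.ci_high - e9.ci_low) > (e1.ci_high - e1.ci_low)

    def test_agrees_with_scipy_bootstrap(self, rng):
        """Independent cross-check against scipy's percentile bootstrap."""
        a, b = rng.normal(0, 1, 25), rng.normal(0.7, 1, 25)
        e = v.mean_difference_ci(a, b, n_boot=20_000, seed=4)
        ref = sstats.bootstrap(
            (b, a), lambda y, x, axis=-1: np.mean(y, axis=axis) - np.mean(x, axis=axis),
            n_resamples=20_000, confidence_level=0.95, method="percentile",
            random_state=np.random.default_rng(4))
        assert e.ci_low == pytest.approx(ref.confidence_interval.low, abs=0.05)
        assert e.ci_high == pytest.approx(ref.confidence_interval.high, abs=0.05)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            v.mean_difference_ci([1, 2], [1, 2, 3], seed=0)


class TestFactorialAnova:
    def test_balanced_design_matches_brute_force_sums_of_squares(self, rng):
        rows = []
        for g in ("g1", "g2"):
            for s in ("s1", "s2"):
                for _ in range(8):
                    rows.append({"group": g, "state": s,
                                 "exponent": rng.normal(0.3 * (g == "g2")
                                                        + 0.5 * (s == "s2"), 1)})
        df = pd.DataFrame(rows)
        aov = v.factorial_anova(df, factors=["group", "state"]).terms.set_index("term")

        y = df["exponent"].to_numpy()
        A, B = df["group"].to_numpy(), df["state"].to_numpy()
        gm = y.mean()
        cell = {(a, b): y[(A == a) & (B == b)].mean()
                for a in ("g1", "g2") for b in ("s1", "s2")}
        ss_a = sum(16 * (y[A == a].mean() - gm) ** 2 for a in ("g1", "g2"))
        ss_b = sum(16 * (y[B == b].mean() - gm) ** 2 for b in ("s1", "s2"))
        ss_ab = sum(8 * (cell[a, b] - y[A == a].mean() - y[B == b].mean() + gm) ** 2
                    for a in ("g1", "g2") for b in ("s1", "s2"))
        mse = sum((yy - cell[a, b]) ** 2 for yy, a, b in zip(y, A, B)) / 28
        for term, ss in [("group", ss_a), ("state", ss_b), ("group:state", ss_ab)]:
            assert aov.loc[term, "F"] == pytest.approx(ss / mse, rel=1e-10)

    def test_planted_state_effect_detected_group_null(self):
        design = v.masking_design(n_per_group=20)
        design.groups = [v.GroupSpec("g1", 0.0, design.state_mix),
                         v.GroupSpec("g2", 0.0, design.state_mix)]
        tab = v.simulate_exponent_table(design, seed=8)
        aov = v.factorial_anova(tab, factors=["group", "state"])
        assert aov.p_for("state") < 0.01
        assert aov.p_for("group") > 0.1

    def test_saturated_design_raises(self):
        df = pd.DataFrame({"group": ["a", "a", "b", "b"],
                           "state": ["x", "y", "x", "y"],
                           "exponent": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="residual"):
            v.factorial_anova(df, factors=["group", "state"])


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        r, p = v.correlation_matrix(df)
        assert np.allclose(np.diag(r), 1.0)

    def test_anticorrelated_pair(self, rng):
        x = rng.normal(size=20)
        df = pd.DataFrame({"x": x, "y": -x, "z": rng.normal(size=20)})
        r, p = v.correlation_matrix(df)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert p.loc["x", "y"] < 1e-6

    def test_bonferroni_familywise_error_controlled(self):
        """Independent variables: any-corrected-significant rate ≤ α."""
        rng = np.random.default_rng(99)
        hits = 0
        reps = 400
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(20, 5)))
            df.columns = [f"v{i}" for i in range(5)]
            _, p = v.correlation_matrix(df)
            iu = np.triu_indices(5, 1)
            hits += (p.to_numpy()[iu] < 0.05).any()
        fwer = hits / reps
        assert fwer <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_zero_variance_flagged_not_fatal(self, rng):
        df = pd.DataFrame({"x": np.ones(10), "y": rng.normal(size=10)})
        with pytest.warns(UserWarning, match="zero-variance"):
            r, p = v.correlation_matrix(df)
        assert np.isnan(r.loc["x", "y"])


class TestAgeRegression:
    def test_exact_line_recovered(self):
        """Noiseless y = −0.0119·age + 1.64 returns those coefficients."""
        ages = np.linspace(20, 80, 30)
        y = -0.0119 * ages + 1.64
        slope, intercept, F, p = v.age_regression(y, ages)
        assert slope == pytest.approx(-0.0119, abs=1e-12)
        assert intercept == pytest.approx(1.64, abs=1e-10)
        assert p < 1e-10

    def test_zero_slope_not_significant(self, rng):
        ages = np.linspace(20, 80, 40)
        y = 1.0 + rng.normal(0, 1e-6, 40) + 0 * ages
        slope, intercept, F, p = v.age_regression(y, ages)
        assert abs(slope) < 1e-6

    def test_noisy_planted_slope_within_sampling_error(self, rng):
        ages = rng.uniform(20, 80, 50)
        y = -0.012 * ages + 1.6 + rng.normal(0, 0.15, 50)
        slope, intercept, F, p = v.age_regression(y, ages)
        se = 0.15 / (np.std(ages) * np.sqrt(50))
        assert slope == pytest.approx(-0.012, abs=2 * se)

    def test_constant_age_rejected(self):
        with pytest.raises(ValueError):
            v.age_regression([1.0, 1.1, 1.2], [50, 50, 50])


class TestMaskingAnalysis:
    def test_pooled_equals_occupancy_weighted_average(self):
        tab = pd.DataFrame({
            "subject": ["s1"] * 3, "group": ["g"] * 3,
            "state": ["a1", "a2", "a3"],
            "exponent": [1.2, 1.0, 0.8],
            "n_epochs": [100, 50, 50],
        })
        ma = v.MaskingAnalysis.__new__(v.MaskingAnalysis)
        ma.table = tab
        pooled = ma.pooled_table()
        expected = (100 * 1.2 + 50 * 1.0 + 50 * 0.8) / 200
        assert pooled["exponent"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_masking_demonstrated_on_designed_cohort(self):
        tab = v.simulate_exponent_table(v.masking_design(n_per_group=27), seed=2)
        res = v.masking_analysis(tab, seed=2)
        assert res.state_resolved_significant
        assert not res.pooled_significant
        assert res.masking_demonstrated
        assert "masks the group effect" in res.summary()

    def test_identical_groups_show_nothing(self):
        design = v.masking_design(n_per_group=15, gap=0.0)
        design.groups = [v.GroupSpec("hc", 0.0, design.state_mix),
                         v.GroupSpec("pt", 0.0, design.state_mix)]
        tab = v.simulate_exponent_table(design, seed=3)
        res = v.masking_analysis(tab, seed=3)
        assert not res.state_resolved_significant

    def test_equal_occupancy_gap_shows_in_both_branches(self):
        design = v.masking_design(n_per_group=20)
        mix = {"a1": 1 / 3, "a2": 1 / 3, "a3": 1 / 3}
        design.groups = [v.GroupSpec("hc", 0.0, mix), v.GroupSpec("pt", -0.2, mix)]
        tab = v.simulate_exponent_table(design, seed=4)
        res = v.masking_analysis(tab, seed=4)
        assert res.state_resolved_significant
        assert res.pooled_significant

    def test_single_group_rejected(self):
        tab = pd.DataFrame({"subject": list("abcd"), "group": ["g"] * 4,
                            "state": ["a1"] * 4, "exponent": [1.0] * 4})
        with pytest.raises(ValueError, match="2 groups"):
            v.MaskingAnalysis(tab)


class TestSummaryStats:
    def test_mean_and_cv(self):
        s = v.summary_stats([1.0, 1.1, 0.9])
        assert s.mean == pytest.approx(1.0)
        assert s.cv == pytest.approx(np.std([1.0, 1.1, 0.9], ddof=1) / 1.0)
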