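"""Exponential duration fits, ratio statistics and bootstrap null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pairsync.durations import (DurationSample, bootstrap_ratio_pvalue,
                                condition_comparisons,
                                durations_from_state_series, fit_exponential,
                                mu_ratio, oscillation_period)


def _sample(durations, **kw):
    kw.setdefault("individual_id", "a")
    kw.setdefault("behavior", "vigilance")
    kw.setdefault("condition", "alone")
    return DurationSample(durations_s=np.asarray(durations, dtype=float), **kw)


class TestFitExponential:
    def test_mle_is_sample_mean(self):
        fit = fit_exponential(_sample([2.0, 4.0, 6.0]))
        assert fit.mu_s == pytest.approx(4.0)
        assert fit.n == 3

    def test_equal_durations(self):
        assert fit_exponential(_sample([3.3] * 5)).mu_s == pytest.approx(3.3)

    def test_large_sample_recovers_mean(self, rng):
        x = rng.exponential(5.06, 10_000)
        assert fit_exponential(_sample(x)).mu_s == pytest.approx(5.06, abs=0.1)

    def test_loglik_matches_exponential_density(self):
        x = np.array([1.0, 2.0, 3.0])
        fit = fit_exponential(_sample(x))
        expected = np.sum(-np.log(fit.mu_s) - x / fit.mu_s)
        assert fit.log_likelihood == pytest.approx(expected)

    def test_rejects_tiny_or_nonpositive(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([1.0]))
        with pytest.raises(ValueError):
            fit_exponential(np.array([1.0, -2.0]))

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.1, 100.0))
    def test_scale_equivariance(self, c):
        x = np.array([1.0, 2.5, 4.0, 8.0])
        assert fit_exponential(c * x).mu_s == pytest.approx(
            c * fit_exponential(x).mu_s, rel=1e-9)


class TestMuRatio:
    @pytest.mark.parametrize("a,b,expected", [(3.0, 3.0, 1.0),
                                              (2.0, 4.0, 0.5),
                                              (3.17, 3.10, 3.10 / 3.17)])
    def test_values(self, a, b, expected):
        fa = fit_exponential(_sample([a, a]))
        fb = fit_exponential(_sample([b, b]))
        assert mu_ratio(fa, fb) == pytest.approx(expected, abs=1e-3)
        assert mu_ratio(fb, fa) == mu_ratio(fa, fb)  # swap invariant

    def test_in_unit_interval(self, rng):
        for _ in range(20):
            fa = fit_exponential(rng.exponential(3.0, 10))
            fb = fit_exponential(rng.exponential(5.0, 10))
            assert 0.0 < mu_ratio(fa, fb) <= 1.0


class TestBootstrapRatio:
    def test_observed_at_null_mean_gives_z_zero(self, rng):
        a = _sample(rng.exponential(4.0, 200))
        b = _sample(rng.exponential(4.0, 200), individual_id="b")
        res = bootstrap_ratio_pvalue(a, b, observed_ratio=0.0, n_boot=500, seed=1)
        center = float(np.mean(res.null_ratios))
        res2 = bootstrap_ratio_pvalue(a, b, observed_ratio=center, n_boot=500,
                                      seed=1)
        assert abs(res2.z) < 0.05
        assert res2.p_normal > 0.95

    def test_extreme_observed_rejected(self, rng):
        a = _sample(rng.exponential(4.0, 100))
        b = _sample(rng.exponential(4.0, 100), individual_id="b")
        res = bootstrap_ratio_pvalue(a, b, observed_ratio=0.2, n_boot=1000, seed=2)
        assert res.p_normal < 0.05
        assert res.p_empirical < 0.05

    def test_null_ratio_typically_accepted(self, rng):
        a = _sample(rng.exponential(4.0, 150))
        b = _sample(rng.exponential(4.0, 150), individual_id="b")
        res = bootstrap_ratio_pvalue(a, b, observed_ratio=0.95, n_boot=1000,
                                     seed=3)
        assert res.p_normal > 0.05

    def test_rejection_rate_calibrated_under_null(self, rng):
        """Treating a fresh resample as 'together' rejects ~5% at alpha=.05."""
        rejections = 0
        n_sim = 150
        for i in range(n_sim):
            a = _sample(rng.exponential(4.0, 60))
            b = _sample(rng.exponential(4.0, 60), individual_id="b")
            obs = mu_ratio(fit_exponential(rng.exponential(4.0, 60)),
                           fit_exponential(rng.exponential(4.0, 60)))
            res = bootstrap_ratio_pvalue(a, b, obs, n_boot=400, seed=1000 + i)
            rejections += res.p_normal < 0.05
        rate = rejections / n_sim
        assert 0.005 <= rate <= 0.15  # ~5% within Monte-Carlo error


class TestOscillationPeriod:
    def test_sum_of_means(self):
        assert oscillation_period(3.17, 5.06) == pytest.approx(8.23)

    def test_limit_and_symmetry(self):
        assert oscillation_period(1e-12, 4.0) == pytest.approx(4.0)
        assert oscillation_period(2.0, 3.0) == oscillation_period(3.0, 2.0)


class TestConditionComparisons:
    def _ratios(self, alone, together):
        return pd.DataFrame({"pair_id": [f"p{i}" for i in range(len(alone))],
                             "behavior": "vigilance",
                             "alone": alone, "together": together})

    def test_identical_conditions_no_shift(self):
        vals = np.linspace(0.5, 0.9, 7)
        periods = pd.DataFrame({"individual_id": [f"i{k}" for k in range(14)],
                                "alone": np.linspace(6, 9, 14),
                                "together": np.linspace(6, 9, 14)})
        table = condition_comparisons(self._ratios(vals, vals.copy()), periods)
        row = table[table.test == "mu_ratio_vigilance"].iloc[0]
        assert row.p == pytest.approx(1.0)

    def test_uniform_increase_is_extreme(self):
        periods = pd.DataFrame({"individual_id": [f"i{k}" for k in range(14)],
                                "alone": np.linspace(6, 9, 14),
                                "together": np.linspace(6, 9, 14) + 1.5})
        ratios = self._ratios(np.full(7, 0.6), np.full(7, 0.8))
        table = condition_comparisons(ratios, periods)
        row = table[table.test == "oscillation_period"].iloc[0]
        assert row.statistic == 0.0  # minimal signed-rank statistic
        assert row.p < 0.01
        assert row.n == 14

    def test_monotone_pair_periods_give_rho_one(self):
        pair_periods = pd.DataFrame({
            "pair_id": [f"p{i}" for i in range(7)] * 2,
            "condition": ["together"] * 7 + ["alone"] * 7,
            "period_1": list(range(1, 8)) * 2,
            "period_2": list(range(2, 9)) + [5, 3, 8, 1, 7, 2, 4],
        })
        periods = pd.DataFrame({"individual_id": ["i1", "i2", "i3", "i4", "i5"],
                                "alone": [6, 7, 8, 9, 10],
                                "together": [7, 8, 9, 10, 11]})
        table = condition_comparisons(self._ratios([0.5] * 7, [0.7] * 7),
                                      periods, pair_periods)
        rho_tog = table[table.test == "pair_period_correlation_together"]
        assert rho_tog.iloc[0].statistic == pytest.approx(1.0)


class TestDurationsFromStateSeries:
    def test_extracts_complete_episodes_only(self):
        # V(1s) F(2s) V(3s) F(1s) at 25 Hz; first and last truncated
        values = np.concatenate([np.ones(25), np.zeros(50), np.ones(75),
                                 np.zeros(25)])
        d = durations_from_state_series(values, 25.0)
        assert list(d["feeding"]) == [2.0]
        assert list(d["vigilance"]) == [3.0]

    def test_keep_truncated_option(self):
        values = np.concatenate([np.ones(25), np.zeros(50), np.ones(75)])
        d = durations_from_state_series(values, 25.0, drop_truncated=False)
        assert sorted(d["vigilance"]) == [1.0, 3.0]
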