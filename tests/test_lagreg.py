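"""Poisson lag regression: GLM core, RR transforms, lag models, Z-test."""

import numpy as np
import pandas as pd
import pytest

from aircausal.datatypes import AgeGroup, DiseaseCategory, StratumCountSeries
from aircausal.lagreg import (
    DistributedLagPoisson,
    compare_groups_z,
    fit_cumulative_lag,
    fit_poisson_loglinear,
    fit_single_lag,
    pearson_descriptive,
    rr_from_beta,
    select_df_aic,
)
from aircausal.simulate import HealthSimConfig, simulate_counts, simulate_exposure


def _const_design(n):
    return pd.DataFrame({"const": np.ones(n)})


class TestGLMCore:
    def test_intercept_only_is_log_mean(self):
        fit = fit_poisson_loglinear(np.array([3, 5, 7]), _const_design(3))
        assert fit.params[0] == pytest.approx(np.log(5), abs=1e-8)
        assert fit.fitted.mean() == pytest.approx(5.0, abs=1e-8)

    def test_score_identity_with_intercept(self):
        rng = np.random.default_rng(0)
        y = rng.poisson(30, size=200)
        X = _const_design(200)
        X["z"] = rng.normal(size=200)
        fit = fit_poisson_loglinear(y, X)
        assert fit.fitted.sum() == pytest.approx(y.sum(), rel=1e-8)

    def test_rank_deficiency_names_columns(self):
        X = _const_design(50)
        rng = np.random.default_rng(1)
        X["a"] = rng.normal(size=50)
        X["b"] = 2 * X["a"]
        with pytest.raises(ValueError, match="rank deficient"):
            fit_poisson_loglinear(np.ones(50, dtype=int), X)

    def test_constant_column_dropped(self):
        X = _const_design(60)
        rng = np.random.default_rng(2)
        X["z"] = rng.normal(size=60)
        X["flat"] = 3.0
        fit = fit_poisson_loglinear(rng.poisson(10, 60), X)
        assert "flat" not in fit.names

    def test_aic_definition(self):
        fit = fit_poisson_loglinear(np.array([3, 5, 7]), _const_design(3))
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2, abs=1e-10)


class TestRRTransform:
    def test_null_beta(self):
        rr, lo, hi = rr_from_beta(0.0, 0.001)
        assert rr == 1.0
        assert lo * hi == pytest.approx(1.0)  # symmetric on the log scale

    def test_closed_form_values(self):
        rr, lo, hi = rr_from_beta(0.001, 0.0005)
        assert rr == pytest.approx(1.01005, abs=5e-6)
        assert lo == pytest.approx(1.00020, abs=5e-6)
        assert hi == pytest.approx(1.02000, abs=5e-6)

    def test_zero_increment(self):
        assert rr_from_beta(0.005, 0.001, increment=0) == (1.0, 1.0, 1.0)

    def test_table_consistency_of_cumulative_transform(self):
        # beta_sum = ln(1.016)/10 per unit must print RR 1.016 per 10 units
        rr, _, _ = rr_from_beta(np.log(1.016) / 10, 0.0003)
        assert rr == pytest.approx(1.016, abs=1e-9)

    def test_monotone_in_beta_and_widens_with_se(self):
        rr1, lo1, hi1 = rr_from_beta(0.001, 0.0005)
        rr2, lo2, hi2 = rr_from_beta(0.002, 0.0005)
        assert rr2 > rr1 and lo2 > lo1 and hi2 > hi1
        _, lo3, hi3 = rr_from_beta(0.001, 0.001)
        assert lo3 < lo1 and hi3 > hi1


class TestGroupComparison:
    def test_equal_coefficients(self):
        g = compare_groups_z(0.002, 0.001, 0.002, 0.001)
        assert g.z == 0 and g.p == pytest.approx(1.0)

    def test_worked_example(self):
        g = compare_groups_z(0.003, 0.001, 0.001, 0.001)
        assert g.z == pytest.approx(1.41421, abs=1e-5)
        assert g.p == pytest.approx(0.157, abs=0.001)

    def test_antisymmetry(self):
        a = compare_groups_z(0.003, 0.001, 0.001, 0.002)
        b = compare_groups_z(0.001, 0.002, 0.003, 0.001)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_zero_ses_raise(self):
        with pytest.raises(ValueError):
            compare_groups_z(0.1, 0.0, 0.2, 0.0)


class TestPearson:
    def _counts(self, values):
        return StratumCountSeries(
            category=DiseaseCategory.TOTAL_RESP, gender="all",
            age_group=AgeGroup.ALL,
            dates=pd.date_range("2013-01-01", periods=len(values)),
            counts=np.asarray(values),
        )

    def _exposure(self, values):
        from aircausal.datatypes import DailyExposureSeries

        return DailyExposureSeries(
            pd.date_range("2013-01-01", periods=len(values)),
            np.asarray(values, float), np.ones(len(values), bool),
        )

    def test_perfect_correlation(self):
        assert pearson_descriptive(self._counts([1, 2, 3]),
                                   self._exposure([10, 20, 30])) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert pearson_descriptive(self._counts([3, 2, 1]),
                                   self._exposure([10, 20, 30])) == pytest.approx(-1.0)

    def test_worked_example(self):
        r = pearson_descriptive(self._counts([2, 4, 7]),
                                self._exposure([1, 2, 3]))
        assert r == pytest.approx(0.99340, abs=1e-5)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_descriptive(self._counts([2, 2, 2]),
                                self._exposure([1, 2, 3]))


class TestLagModels:
    def test_recovers_generating_effect(self, synthetic_study):
        exposure, counts, cfg = synthetic_study
        eff = fit_single_lag(counts, exposure, lag=0, df=7)
        assert abs(eff.beta - 0.0016) < 3 * eff.se
        assert eff.ci_low < eff.rr10 < eff.ci_high
        assert eff.rr10 == pytest.approx(np.exp(10 * eff.beta))

    def test_cumulative_recovers_lag0_truth_with_white_noise_exposure(self):
        exposure = simulate_exposure(2010, 70, 0, 0.0, 15, seed=41)
        counts = simulate_counts(
            exposure, HealthSimConfig(n_days=2000, beta1=(0.0016,), seed=42)
        )
        cum = fit_cumulative_lag(counts, exposure, max_lag=5, df=7)
        assert abs(cum.beta_sum - 0.0016) < 3 * cum.se_sum

    def test_wrong_lag_estimate_near_zero_with_white_noise_exposure(self):
        exposure = simulate_exposure(2010, 70, 0, 0.0, 15, seed=43)
        counts = simulate_counts(
            exposure, HealthSimConfig(n_days=2000, beta1=(0.0016,), seed=44)
        )
        eff = fit_single_lag(counts, exposure, lag=3, df=7)
        assert abs(eff.beta) < 4 * eff.se

    def test_adding_exposure_never_lowers_loglik(self, synthetic_study):
        exposure, counts, _ = synthetic_study
        from aircausal.lagreg import _base_design, _lagged_exposure_frame

        X0 = _base_design(counts.dates, counts.dates[0], 7)
        base = fit_poisson_loglinear(counts.counts, X0)
        X1 = X0.copy()
        X1.insert(1, "oz", _lagged_exposure_frame(counts, exposure, [0])
                  .iloc[:, 0].to_numpy())
        full = fit_poisson_loglinear(counts.counts, X1)
        assert full.loglik >= base.loglik - 1e-6

    def test_insufficient_days_raise(self):
        exposure = simulate_exposure(120, seed=45)
        counts = simulate_counts(exposure,
                                 HealthSimConfig(n_days=100, seed=46))
        with pytest.raises(ValueError, match="usable days"):
            fit_single_lag(counts, exposure, lag=0, df=7)

    def test_constant_exposure_collinear_raise(self):
        exposure = simulate_exposure(400, 70, 0, 0.0, 0.0, seed=0)
        counts = simulate_counts(exposure,
                                 HealthSimConfig(n_days=395, seed=47))
        with pytest.raises(ValueError, match="constant"):
            fit_cumulative_lag(counts, exposure, max_lag=5, df=7)


class TestDfSelection:
    def test_single_candidate(self, synthetic_study):
        _, counts, _ = synthetic_study
        chosen, table, pacf = select_df_aic(counts, [7])
        assert chosen == 7 and len(table) == 1 and len(pacf) == 15

    def test_duplicate_candidates_deduplicate_to_smaller(self, synthetic_study):
        _, counts, _ = synthetic_study
        chosen, table, _ = select_df_aic(counts, [7, 7, 7])
        assert chosen == 7 and len(table) == 1

    def test_recovers_generating_df_without_pollutant_signal(self):
        hits = 0
        n = 20
        for s in range(n):
            e = simulate_exposure(1005, seed=300 + s)
            c = simulate_counts(
                e, HealthSimConfig(n_days=1000, beta1=(0.0,), seed=400 + s)
            )
            chosen, _, _ = select_df_aic(c, [3, 5, 7, 9, 12])
            hits += chosen in (7, 9)
        assert hits >= 0.8 * n


class TestModelObject:
    def test_fit_summary_and_frame(self, synthetic_study):
        exposure, counts, _ = synthetic_study
        model = DistributedLagPoisson(counts, exposure, df=7)
        res = model.fit()
        frame = res.to_frame()
        assert list(frame["lag"]) == [f"Lag{i}" for i in range(6)] + ["Lag05"]
        assert (frame["ci_low"] <= frame["rr10"]).all()
        assert (frame["rr10"] <= frame["ci_high"]).all()
        text = res.summary()
        assert "Lag05" in text and "RR" in text

    def test_quasipoisson_widens_or_keeps_intervals(self, synthetic_study):
        exposure, counts, _ = synthetic_study
        plain = fit_single_lag(counts, exposure, 0, 7)
        quasi = fit_single_lag(counts, exposure, 0, 7, quasipoisson=True)
        assert quasi.beta == pytest.approx(plain.beta, abs=1e-10)

    def test_moving_average_mode_runs(self, synthetic_study):
        exposure, counts, _ = synthetic_study
        cum = fit_cumulative_lag(counts, exposure, 5, 7, moving_average=True)
        assert np.isfinite(cum.beta_sum) and cum.se_sum > 0
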