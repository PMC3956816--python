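"""Precision, interobserver, cross-device and normality statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ctxa import (anderson_darling_normality, interobserver_compare,
                  regress_with_see, rms_precision, t_score, welch_t)
from ctxa.densito_stats import (load_crossdevice_csv, load_longitudinal_csv,
                                load_paired_csv)
from ctxa.errors import DegenerateFitError


class TestRMSPrecision:
    def test_identical_visits_give_zero(self):
        res = rms_precision({i: [0.6, 0.6, 0.6] for i in range(5)})
        assert res.rms_sd == 0.0
        assert res.cv_percent == 0.0

    def test_hand_evaluated_two_patient_case(self):
        # patient SDs 0.01 and 0.02 -> sqrt((0.0001 + 0.0004) / 2)
        a = [0.59, 0.60, 0.61]  # sd exactly 0.01
        b = [0.68, 0.70, 0.72]  # sd exactly 0.02
        res = rms_precision({1: a, 2: b})
        assert res.rms_sd == pytest.approx(np.sqrt(2.5e-4), rel=1e-12)
        assert res.grand_mean == pytest.approx(0.65)
        assert res.cv_percent == pytest.approx(100 * np.sqrt(2.5e-4) / 0.65)

    def test_df_weighted_variant(self):
        a = [0.59, 0.60, 0.61]        # var 1e-4, df 2
        b = [0.68, 0.70, 0.72, 0.70]  # var 2.666...e-4, df 3
        va = np.var(a, ddof=1)
        vb = np.var(b, ddof=1)
        res = rms_precision({1: a, 2: b}, df_weighted=True)
        assert res.rms_sd == pytest.approx(np.sqrt((2 * va + 3 * vb) / 5))

    def test_permutation_and_scaling_invariance(self):
        rng = np.random.default_rng(2)
        series = {i: rng.normal(0.7, 0.01, 3).tolist() for i in range(8)}
        base = rms_precision(series)
        shuffled = {k: v[::-1] for k, v in reversed(list(series.items()))}
        assert rms_precision(shuffled).rms_sd == pytest.approx(base.rms_sd)
        scaled = {k: [3.0 * x for x in v] for k, v in series.items()}
        res = rms_precision(scaled)
        assert res.rms_sd == pytest.approx(3.0 * base.rms_sd, rel=1e-12)
        assert res.cv_percent == pytest.approx(base.cv_percent, rel=1e-12)

    def test_short_series_excluded_or_error(self):
        series = {1: [0.6, 0.61, 0.59], 2: [0.7], 3: [0.65, 0.66]}
        res = rms_precision(series)
        assert res.n_patients == 2
        assert res.n_excluded == 1
        with pytest.raises(ValueError):
            rms_precision(series, on_short="error")

    def test_dataframe_input(self):
        df = pd.DataFrame({
            "patient_id": [1, 1, 2, 2], "visit": [0, 1, 0, 1],
            "bmd": [0.6, 0.62, 0.7, 0.7],
        })
        res = rms_precision(df)
        assert res.n_patients == 2
        assert res.rms_sd == pytest.approx(
            np.sqrt((np.var([0.6, 0.62], ddof=1) + 0.0) / 2))


class TestInterobserver:
    def test_identical_observers(self):
        x = [0.6, 0.7, 0.8, 0.65]
        res = interobserver_compare(x, x)
        assert res.mean_difference == 0.0
        assert res.percent_difference == 0.0
        assert res.p == 1.0

    def test_shift_recovery_over_replicates(self):
        # known shift delta recovered within 2 SE on average
        rng = np.random.default_rng(17)
        delta, sigma, n, reps = 0.007, 0.01, 28, 1000
        obs1 = rng.normal(0.65, 0.12, (reps, n))
        obs2 = obs1 + delta + rng.normal(0.0, sigma, (reps, n))
        diffs = (obs2 - obs1).mean(axis=1)
        se = sigma / np.sqrt(n)
        assert abs(diffs.mean() - delta) < 2 * se
        res = interobserver_compare(obs1[0], obs2[0])
        assert res.paired and res.n == n

    def test_percent_difference_uses_observer1_denominator(self):
        res = interobserver_compare([0.5, 0.5, 0.5], [0.55, 0.55, 0.55])
        assert res.percent_difference == pytest.approx(10.0)

    def test_paired_p_matches_scipy(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.6, 0.1, 12)
        b = a + rng.normal(0.005, 0.01, 12)
        res = interobserver_compare(a, b)
        t, p = stats.ttest_rel(b, a)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)

    def test_length_mismatch_is_pairing_error(self):
        with pytest.raises(ValueError, match="length"):
            interobserver_compare([1.0, 2.0, 3.0], [1.0, 2.0])


class TestRegressWithSEE:
    def test_perfect_line(self):
        x = np.array([0.4, 0.6, 0.8, 1.0])
        res = regress_with_see(x, x)
        assert res.slope == pytest.approx(1.0)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.see == pytest.approx(0.0, abs=1e-12)

    def test_four_point_normal_equations_oracle(self):
        x = np.array([0.5, 0.6, 0.7, 0.9])
        y = np.array([0.42, 0.55, 0.61, 0.78])
        res = regress_with_see(x, y)
        n = 4
        sx, sy = x.sum(), y.sum()
        slope = (n * (x * y).sum() - sx * sy) / (n * (x**2).sum() - sx**2)
        intercept = (sy - slope * sx) / n
        resid = y - slope * x - intercept
        see = np.sqrt((resid**2).sum() / (n - 2))
        r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        assert res.slope == pytest.approx(slope, rel=1e-12)
        assert res.intercept == pytest.approx(intercept, rel=1e-12)
        assert res.see == pytest.approx(see, rel=1e-12)
        assert res.pearson_r == pytest.approx(r, rel=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_data_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        x = rng.normal(0.7, 0.15, n)
        y = 1.01 * x - 0.1 + rng.normal(0.0, 0.04, n)
        if np.ptp(x) == 0:
            return
        res = regress_with_see(x, y)
        sx, sy = x.sum(), y.sum()
        slope = (n * (x * y).sum() - sx * sy) / (n * (x**2).sum() - sx**2)
        intercept = (sy - slope * sx) / n
        see = np.sqrt(((y - slope * x - intercept) ** 2).sum() / (n - 2))
        assert res.slope == pytest.approx(slope, rel=1e-10)
        assert res.intercept == pytest.approx(intercept, rel=1e-8, abs=1e-10)
        assert res.see == pytest.approx(see, rel=1e-8, abs=1e-12)

    def test_zero_variance_x_is_degenerate(self):
        with pytest.raises(DegenerateFitError):
            regress_with_see([0.5, 0.5, 0.5], [0.4, 0.5, 0.6])


class TestWelch:
    def test_identical_groups(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_scipy_reference(self):
        a = [1.0, 2.0, 3.0]
        b = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = welch_t(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-10)
        assert res.df == pytest.approx(ref.df, rel=1e-10)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_variances(self):
        assert welch_t([2.0, 2.0], [2.0, 2.0]).p == 1.0
        with pytest.raises(DegenerateFitError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestAndersonDarling:
    def test_matches_scipy_statistic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        res = anderson_darling_normality(x)
        assert res.a2 == pytest.approx(stats.anderson(x, dist="norm").statistic,
                                       rel=1e-9)
        assert res.a2_adjusted == pytest.approx(
            res.a2 * (1 + 0.75 / 100 + 2.25 / 100**2))

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.6, 0.1, 64)
        assert anderson_darling_normality(3 * x + 7).a2 == pytest.approx(
            anderson_darling_normality(x).a2, rel=1e-9)

    def test_rejects_exponential_samples(self):
        rng = np.random.default_rng(5)
        rejected = sum(
            anderson_darling_normality(rng.exponential(size=200)).reject
            for _ in range(100))
        assert rejected >= 99

    def test_type_i_error_near_nominal(self):
        rng = np.random.default_rng(8)
        rejected = sum(
            anderson_darling_normality(rng.normal(size=200)).reject
            for _ in range(1000))
        assert 0.03 <= rejected / 1000 <= 0.07

    def test_small_or_constant_input_rejected(self):
        with pytest.raises(ValueError):
            anderson_darling_normality([1.0] * 5)
        with pytest.raises(DegenerateFitError):
            anderson_darling_normality([1.0] * 10)


class TestTScore:
    def test_standardisation(self):
        assert t_score(0.55, 0.85, 0.12) == pytest.approx((0.55 - 0.85) / 0.12)
        with pytest.raises(ValueError):
            t_score(0.55, 0.85, 0.0)


class TestCSVSchemas:
    def test_round_trips(self, tmp_path):
        lon = tmp_path / "lon.csv"
        pd.DataFrame({"patient_id": [1, 1], "visit": [0, 1],
                      "bmd": [0.6, 0.61]}).to_csv(lon, index=False)
        assert len(load_longitudinal_csv(lon)) == 2
        paired = tmp_path / "paired.csv"
        pd.DataFrame({"study_id": [1], "obs1": [0.6],
                      "obs2": [0.61]}).to_csv(paired, index=False)
        assert len(load_paired_csv(paired)) == 1
        cross = tmp_path / "cross.csv"
        pd.DataFrame({"subject_id": [1], "ctxa": [0.6], "dxa": [0.7],
                      "site": [1]}).to_csv(cross, index=False)
        assert len(load_crossdevice_csv(cross)) == 1

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        pd.DataFrame({"patient_id": [1], "bmd": [0.6]}).to_csv(bad, index=False)
        with pytest.raises(ValueError, match="visit"):
            load_longitudinal_csv(bad)
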