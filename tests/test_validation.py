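"""Validation metrics, threshold checks, noise bounds and y-scrambling."""

import numpy as np
import pytest
from scipy import stats

from pcmlearn.bioactivity import BioactivityTable
from pcmlearn.validation import (
    bootstrap_sd,
    ccc,
    metrics_report,
    q2,
    r2_zero,
    rmse,
    selectivity_metrics,
    simulate_max_performance,
    tropsha_check,
    y_scrambling_curve,
)


class TestRmse:
    def test_perfect_prediction_zero(self):
        y = np.array([5.0, 6.0, 7.0])
        assert rmse(y, y) == 0.0

    def test_unit_residuals(self):
        assert rmse([0.0, 0.0], [1.0, 1.0]) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        assert rmse([5.0, 6.0, 7.0], [5.5, 6.5, 6.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            rmse([1.0, 2.0], [1.0])


class TestQ2:
    def test_perfect_prediction_is_one(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q2(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0])
        assert q2(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_hand_worked_example(self):
        assert q2([1.0, 2.0, 3.0], [1.0, 2.0, 4.0]) == pytest.approx(0.5)

    def test_constant_observations_raise(self):
        with pytest.raises(ValueError):
            q2([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestR2Zero:
    def test_identity_prediction(self):
        r2_0, s = r2_zero([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r2_0, s) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_doubled_predictions_scale_absorbed(self):
        r2_0, s = r2_zero([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert s == pytest.approx(0.5)
        assert r2_0 == pytest.approx(1.0)

    def test_anticorrelated_inputs_can_go_negative(self):
        rng = np.random.default_rng(0)
        y = rng.uniform(4, 10, 50)
        y_pred = 14 - y + rng.normal(0, 0.2, 50)
        r2_0, _ = r2_zero(y, y_pred)
        assert r2_0 < 0

    def test_scale_invariance_property(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            y = rng.normal(6, 1, 30)
            y_pred = y + rng.normal(0, 0.5, 30)
            scale = rng.uniform(0.1, 10)
            base, _ = r2_zero(y, y_pred)
            scaled, _ = r2_zero(y, scale * y_pred)
            assert scaled == pytest.approx(base, abs=1e-10)

    def test_all_zero_predictions_raise(self):
        with pytest.raises(ValueError):
            r2_zero([1.0, 2.0], [0.0, 0.0])


class TestCcc:
    def test_identity_is_one(self):
        y = np.array([4.0, 6.0, 8.0])
        assert ccc(y, y) == pytest.approx(1.0)

    def test_large_shift_penalized_toward_zero(self):
        rng = np.random.default_rng(2)
        y = rng.normal(6, 1, 200)
        shifted = y + 10
        value = ccc(y, shifted)
        # closed form: 2*var / (2*var + shift^2)
        expected = 2 * np.var(y) / (2 * np.var(y) + 100)
        assert value == pytest.approx(expected, abs=1e-12)
        assert 0 < value < 0.05

    def test_sign_flip_on_zero_mean_is_minus_one(self):
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert ccc(y, -y) == pytest.approx(-1.0)

    def test_bounded_by_pearson_property(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            y = rng.normal(size=25)
            y_pred = rng.normal(size=25) + rng.uniform(-1, 1) * y
            assert abs(ccc(y, y_pred)) <= abs(stats.pearsonr(y, y_pred).statistic) + 1e-12

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            ccc([1.0, 1.0], [1.0, 2.0])


class TestTropsha:
    @staticmethod
    def _report(q2_val, r2_0_val):
        rng = np.random.default_rng(0)
        y = rng.normal(6, 1, 10)
        base = metrics_report(y, y + rng.normal(0, 0.1, 10))
        return type(base)(
            rmse=base.rmse, q2=q2_val, r2_zero=r2_0_val, ccc=base.ccc,
            slope=base.slope, n=base.n, context=base.context,
        )

    def test_sound_model_passes(self):
        result = tropsha_check(self._report(0.61, 0.9), self._report(0.61, 0.61))
        assert result.passed

    def test_weak_internal_q2_fails(self):
        result = tropsha_check(self._report(0.4, 0.9), self._report(0.9, 0.9))
        assert not result.passed
        assert any("q2_int" in reason for reason in result.reasons)

    def test_thresholds_are_strict_inequalities(self):
        at_threshold = tropsha_check(self._report(0.5, 0.9), self._report(0.6, 0.6))
        assert not at_threshold.passed
        eps = 1e-9
        above = tropsha_check(self._report(0.5 + eps, 0.9), self._report(0.6 + eps, 0.6 + eps))
        assert above.passed


class TestBootstrap:
    def test_perfect_predictions_zero_sd(self):
        y = np.arange(10.0)
        mean, sd = bootstrap_sd(rmse, y, y, reps=50, seed=0)
        assert (mean, sd) == (0.0, 0.0)

    def test_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(4)
        sds = []
        for n in (50, 200, 800):
            y = rng.normal(6, 1, n)
            y_pred = y + rng.normal(0, 0.5, n)
            _, sd = bootstrap_sd(rmse, y, y_pred, reps=300, seed=1)
            sds.append(sd)
        assert sds[0] > sds[1] > sds[2]
        assert sds[0] / sds[2] == pytest.approx(4.0, rel=0.5)  # ~1/sqrt(n)

    def test_reproducible_from_seed(self):
        rng = np.random.default_rng(5)
        y = rng.normal(6, 1, 40)
        y_pred = y + rng.normal(0, 0.3, 40)
        assert bootstrap_sd(q2, y, y_pred, reps=100, seed=3) == bootstrap_sd(
            q2, y, y_pred, reps=100, seed=3
        )

    def test_metric_returning_tuple_uses_first_element(self):
        rng = np.random.default_rng(6)
        y = rng.normal(6, 1, 40)
        mean, _ = bootstrap_sd(r2_zero, y, y, reps=20, seed=0)
        assert mean == pytest.approx(1.0)


class TestNoiseSimulation:
    def test_zero_noise_gives_exact_metrics(self):
        pool = np.random.default_rng(0).uniform(4, 10, 2000)
        result = simulate_max_performance(pool, sigma=0.0, sample_size=200, reps=20, seed=0)
        assert np.allclose(result.rmse_values, 0.0)
        assert np.allclose(result.q2_values, 1.0)
        assert np.allclose(result.r2_zero_values, 1.0)

    def test_mean_rmse_approaches_sigma(self):
        pool = np.random.default_rng(1).uniform(4, 10, 20000)
        result = simulate_max_performance(
            pool, sigma=0.68, sample_size=10000, reps=30, seed=1
        )
        assert result.mean_min_rmse == pytest.approx(0.68, rel=0.02)

    def test_max_q2_matches_variance_ratio(self):
        rng = np.random.default_rng(2)
        pool = rng.normal(7, 1.2, 30000)
        result = simulate_max_performance(pool, sigma=0.68, sample_size=5000, reps=50, seed=2)
        expected = 1 - 0.68**2 / 1.2**2
        assert result.mean_max_q2 == pytest.approx(expected, abs=0.02)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            simulate_max_performance(np.ones(10), sigma=-0.1)

    def test_oversized_sample_needs_replacement_opt_in(self):
        pool = np.arange(10.0)
        with pytest.raises(ValueError, match="replace=True"):
            simulate_max_performance(pool, sample_size=20, reps=2)
        result = simulate_max_performance(pool, sample_size=20, reps=2, replace=True)
        assert result.sample_size == 20

    def test_reproducible_from_seed(self):
        pool = np.random.default_rng(3).uniform(4, 10, 1000)
        a = simulate_max_performance(pool, sample_size=100, reps=10, seed=9)
        b = simulate_max_performance(pool, sample_size=100, reps=10, seed=9)
        assert np.array_equal(a.rmse_values, b.rmse_values)


class TestYScrambling:
    @staticmethod
    def _split_data(seed=0, n=300, p=8, noise=0.3):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = X @ np.linspace(1, 2, p) + rng.normal(0, noise, n)
        cut = int(0.8 * n)
        return X[:cut], y[:cut], X[cut:], y[cut:]

    def test_fraction_zero_reproduces_unscrambled_model(self):
        from sklearn.linear_model import LinearRegression

        X_train, y_train, X_test, y_test = self._split_data()
        curve = y_scrambling_curve(
            LinearRegression(), X_train, y_train, X_test, y_test,
            fractions=(0.0,), seed=0,
        )
        model = LinearRegression().fit(X_train, y_train)
        assert curve.reports[0].rmse == pytest.approx(
            rmse(y_test, model.predict(X_test)), abs=1e-12
        )

    def test_full_scrambling_destroys_signal(self):
        from sklearn.linear_model import LinearRegression

        X_train, y_train, X_test, y_test = self._split_data(seed=1)
        q2_values = [
            y_scrambling_curve(
                LinearRegression(), X_train, y_train, X_test, y_test,
                fractions=(1.0,), seed=seed,
            ).reports[0].q2
            for seed in range(5)
        ]
        assert np.mean(q2_values) <= 0

    def test_metric_trend_decreases_with_fraction(self):
        from sklearn.linear_model import LinearRegression

        X_train, y_train, X_test, y_test = self._split_data(seed=2)
        fractions = (0.0, 0.5, 1.0)
        r2_by_fraction = np.zeros(len(fractions))
        for seed in range(5):
            curve = y_scrambling_curve(
                LinearRegression(), X_train, y_train, X_test, y_test,
                fractions=fractions, seed=seed,
            )
            r2_by_fraction += [report.r2_zero for report in curve.reports]
        r2_by_fraction /= 5
        assert r2_by_fraction[0] > r2_by_fraction[1] > r2_by_fraction[2]

    def test_invalid_fraction_rejected(self):
        from sklearn.linear_model import LinearRegression

        X_train, y_train, X_test, y_test = self._split_data()
        with pytest.raises(ValueError):
            y_scrambling_curve(
                LinearRegression(), X_train, y_train, X_test, y_test, fractions=(1.5,)
            )


class TestSelectivityMetrics:
    def test_dual_annotated_overlap_and_values(self):
        entries = {
            ("c1", "A"): 6.0, ("c1", "B"): 8.0,
            ("c2", "A"): 7.0, ("c2", "B"): 5.0,
            ("c3", "A"): 6.5,  # only on A
        }
        table = BioactivityTable(entries=entries, n_source_records={k: 1 for k in entries})
        rmse_ab, r2_0, n_shared = selectivity_metrics(table, "A", "B")
        assert n_shared == 2
        assert rmse_ab == pytest.approx(2.0)

    def test_no_overlap_raises(self):
        entries = {("c1", "A"): 6.0, ("c2", "B"): 7.0}
        table = BioactivityTable(entries=entries, n_source_records={k: 1 for k in entries})
        with pytest.raises(ValueError):
            selectivity_metrics(table, "A", "B")
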