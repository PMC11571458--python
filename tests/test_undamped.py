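import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foamimpact import (
    PeakPoint,
    attenuation_ratio,
    fit_exponential,
    fit_transfer_function,
    predict_undamped,
    transfer_functions,
    undamped_force_table,
)
from foamimpact import TestCondition as Condition


class TestFitExponential:
    def test_noise_free_parameter_recovery(self):
        a, b = 25000.0, -60.0
        x = np.array([0.013, 0.028, 0.044])
        f = a * np.exp(b * x)
        fit = fit_exponential(x, f)
        assert fit.a == pytest.approx(a, rel=1e-3)
        assert fit.b == pytest.approx(b, rel=1e-3)

    def test_two_points_match_closed_form(self):
        x = np.array([0.01, 0.03])
        f = np.array([8000.0, 2500.0])
        fit = fit_exponential(x, f)
        b = math.log(f[1] / f[0]) / (x[1] - x[0])
        a = f[0] * math.exp(-b * x[0])
        assert fit.b == pytest.approx(b, rel=1e-9)
        assert fit.a == pytest.approx(a, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-6)

    def test_constant_forces_give_zero_exponent(self):
        fit = fit_exponential([0.01, 0.02, 0.03], [4000.0, 4000.0, 4000.0])
        assert fit.b == 0.0
        assert fit.a == 4000.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0.01], [100.0])
        with pytest.raises(ValueError):
            fit_exponential([0.01, 0.02], [100.0, -5.0])
        with pytest.raises(ValueError):
            fit_exponential([0.02, 0.02], [100.0, 200.0])

    def test_residuals_orthogonal_to_jacobian(self):
        # first-order optimality of the nonlinear least squares
        rng = np.random.default_rng(5)
        x = np.linspace(0.01, 0.05, 12)
        f = 30000 * np.exp(-55 * x) * (1 + rng.normal(0, 0.03, x.size))
        fit = fit_exponential(x, f)
        r = f - fit(x)
        J_a = np.exp(fit.b * x)
        J_b = fit.a * x * np.exp(fit.b * x)
        scale = np.sum(np.abs(r)) * np.max(np.abs(J_b)) + 1e-9
        assert abs(np.dot(r, J_a)) / scale < 1e-5
        assert abs(np.dot(r, J_b)) / scale < 1e-5

    def test_accepts_peak_points(self):
        pts = [
            PeakPoint(9000.0, 0.012, Condition(0.5, 1, "s", 1)),
            PeakPoint(4000.0, 0.025, Condition(0.5, 2, "s", 1)),
            PeakPoint(2500.0, 0.038, Condition(0.5, 3, "s", 1)),
        ]
        fit = fit_exponential(pts)
        assert fit.a > 9000.0
        assert fit.b < 0


class TestUndampedTable:
    def test_exact_exponential_groups_recovered(self):
        a_by_group = {(0.25, 1): 12000.0, (0.50, 1): 40000.0}
        b = -65.0
        peaks = []
        for (h, rep), a in a_by_group.items():
            for i, (layers, x) in enumerate([(1, 0.014), (2, 0.027), (3, 0.040)]):
                peaks.append(
                    PeakPoint(a * math.exp(b * x), x, Condition(h, layers, f"s{i}", rep))
                )
        table = undamped_force_table(peaks)
        assert len(table) == 2
        for (h, rep), a in a_by_group.items():
            row = table[(table.drop_height == h) & (table.repetition == rep)]
            assert row["a"].iloc[0] == pytest.approx(a, rel=1e-6)

    def test_single_layer_group_skipped(self):
        peaks = [
            PeakPoint(9000.0, 0.012, Condition(0.5, 1, "s1", 1)),
            PeakPoint(8800.0, 0.013, Condition(0.5, 1, "s2", 1)),
        ]
        table = undamped_force_table(peaks)
        assert table.empty

    def test_undamped_force_rises_with_repetition(self, study):
        # degraded mats absorb less, so extrapolated undamped force grows
        _, results = study
        und = results["undamped"]
        for h in (0.15, 0.25, 0.50):
            sub = und[und.drop_height == h].sort_values("repetition")
            a = sub["a"].to_numpy()
            assert a[1] > a[0]


class TestTransferFunction:
    def test_exact_line_through_origin(self):
        m = np.array([1000.0, 2000.0, 3500.0])
        tf = fit_transfer_function(m, 2.8 * m)
        assert tf.slope == pytest.approx(2.8, rel=1e-12)
        assert tf.r_squared == pytest.approx(1.0, abs=1e-12)
        assert tf.ci95[0] == pytest.approx(tf.ci95[1], abs=1e-9)

    def test_slope_matches_grid_search_oracle(self):
        rng = np.random.default_rng(3)
        m = rng.uniform(1000, 9000, 5)
        u = 3.1 * m * (1 + rng.normal(0, 0.1, 5))
        tf = fit_transfer_function(m, u)
        ks = np.linspace(0.5, 8.0, 150001)
        sse = ((u[:, None] - ks[None, :] * m[:, None]) ** 2).sum(axis=0)
        k_grid = ks[np.argmin(sse)]
        assert tf.slope == pytest.approx(k_grid, abs=(ks[1] - ks[0]))

    def test_slope_equals_closed_form(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(500, 5000, 8)
        u = rng.uniform(2000, 30000, 8)
        tf = fit_transfer_function(m, u)
        assert tf.slope == pytest.approx(np.sum(m * u) / np.sum(m * m), rel=1e-14)

    def test_ci_contains_slope_and_r2_bounded(self):
        rng = np.random.default_rng(9)
        m = rng.uniform(1000, 9000, 20)
        u = 2.5 * m + rng.normal(0, 500, 20)
        tf = fit_transfer_function(m, u)
        assert tf.ci95[0] <= tf.slope <= tf.ci95[1]
        assert 0.0 <= tf.r_squared <= 1.0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_transfer_function([1000.0], [2800.0])


class TestPredictionAndRatios:
    @pytest.mark.parametrize(
        "measured, slope, expected",
        [(2.9, 2.8, 8.1), (3.8, 2.8, 10.6), (0.0, 2.8, 0.0)],
    )
    def test_predict_undamped_rounds_to_reported_values(
        self, measured, slope, expected
    ):
        assert round(predict_undamped(measured, slope), 1) == expected

    def test_negative_force_rejected(self):
        with pytest.raises(ValueError):
            predict_undamped(-1.0, 2.8)

    @pytest.mark.parametrize(
        "k_multi, k_single, expected",
        [(6.1, 2.8, 2.2), (11.1, 2.8, 4.0), (2.8, 2.8, 1.0)],
    )
    def test_attenuation_ratios_round_to_reported_values(
        self, k_multi, k_single, expected
    ):
        assert round(attenuation_ratio(k_multi, k_single), 1) == expected


class TestTransferOnStudy:
    def test_slopes_strictly_increase_with_layers(self, study):
        _, results = study
        tfs = results["transfer"]
        assert tfs[1].slope < tfs[2].slope < tfs[3].slope

    def test_pairs_pool_specimen_level_points(self, study):
        _, results = study
        # 3 heights x 3 reps x 3 specimens + 0.5 m extra block 5 reps x 3
        assert results["transfer"][1].n_points == 42
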