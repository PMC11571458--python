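import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from foamimpact import (
    StudyConfig,
    build_table1,
    force_increase_table,
    posthoc_consecutive_t,
    rm_anova,
    shapiro_wilk,
)

# Published repeated-loading means used as rendering/regression inputs.
PRINTED_MEANS = {
    1: [10017.0, 12867.0, 13642.0, 13967.0, 14250.0],
    2: [3858.0, 4525.0, 4683.0, 4767.0, 4833.0],
    3: [2342.0, 2558.0, 2608.0, 2600.0, 2617.0],
}
PRINTED_INCREASES = {
    1: [28, 36, 39, 42],
    2: [17, 21, 24, 25],
    3: [9, 11, 11, 12],
}


def _brute_force_rm_anova(m):
    """Independent sums-of-squares decomposition, written out longhand."""
    m = np.asarray(m, float)
    n_s, n_r = m.shape
    gm = m.mean()
    ss_treat = n_s * np.sum((m.mean(axis=0) - gm) ** 2)
    ss_subj = n_r * np.sum((m.mean(axis=1) - gm) ** 2)
    ss_total = np.sum((m - gm) ** 2)
    ss_err = ss_total - ss_treat - ss_subj
    df_t, df_e = n_r - 1, (n_r - 1) * (n_s - 1)
    F = (ss_treat / df_t) / (ss_err / df_e)
    eta2 = ss_treat / (ss_treat + ss_err)
    p = sps.f.sf(F, df_t, df_e)
    return F, p, eta2


class TestForceIncrease:
    @pytest.mark.parametrize("layer", [1, 2, 3])
    def test_printed_percentages_reproduced_from_printed_means(self, layer):
        pct = force_increase_table(PRINTED_MEANS[layer])
        assert [round(v) for v in pct[1:]] == PRINTED_INCREASES[layer]

    def test_equal_means_give_zero(self):
        assert np.allclose(force_increase_table([5.0, 5.0, 5.0]), 0.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            force_increase_table([0.0, 10.0])


class TestShapiroWilk:
    def test_null_coverage_under_normal_sampling(self):
        hits = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(100.0, 5.0, 20)
            _, p = shapiro_wilk(x)
            hits += p > 0.05
        assert hits >= 90

    def test_detects_exponential_departure(self):
        rejections = 0
        for seed in range(50):
            x = np.random.default_rng(seed).exponential(1.0, 30)
            _, p = shapiro_wilk(x)
            rejections += p < 0.05
        assert rejections > 25

    def test_degenerate_and_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            shapiro_wilk([1.0, 2.0])


class TestRmAnova:
    def test_matches_hand_sums_of_squares(self):
        m = [[10, 12, 13], [11, 13, 14.5], [9, 11, 12]]
        F, p, eta2 = rm_anova(m)
        F0, p0, eta0 = _brute_force_rm_anova(m)
        assert F == pytest.approx(F0, rel=1e-9)
        assert p == pytest.approx(p0, rel=1e-9)
        assert eta2 == pytest.approx(eta0, rel=1e-9)

    def test_no_repetition_effect_is_not_significant(self):
        rng = np.random.default_rng(2)
        base = np.array([100.0, 110.0, 95.0])  # specimen offsets only
        m = base[:, None] + rng.normal(0, 1.0, (3, 5))
        F, p, eta2 = rm_anova(m)
        assert p > 0.05
        assert 0.0 <= eta2 <= 1.0

    def test_incomplete_matrix_rejected(self):
        m = np.array([[1.0, 2.0], [3.0, np.nan]])
        with pytest.raises(ValueError):
            rm_anova(m)


class TestPosthoc:
    def test_identical_samples_give_half_p(self):
        m = np.array([[10.0, 10.0], [12.0, 12.0], [11.0, 11.0]])
        res = posthoc_consecutive_t(m)
        assert res.loc[0, "t"] == 0.0
        assert res.loc[0, "p"] == 0.5
        assert not res.loc[0, "degenerate"]

    def test_constant_shift_flagged_degenerate(self):
        m = np.array([[10.0, 12.0], [11.0, 13.0], [9.0, 11.0]])
        res = posthoc_consecutive_t(m)
        assert res.loc[0, "degenerate"]
        assert np.isnan(res.loc[0, "p"])

    def test_hand_computed_t_statistic(self):
        # differences (2, 2.1, 1.9): t = mean/sd * sqrt(3) = 34.64
        m = np.array([[10.0, 12.0], [11.0, 13.1], [9.0, 10.9]])
        res = posthoc_consecutive_t(m)
        d = np.array([2.0, 2.1, 1.9])
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert res.loc[0, "t"] == pytest.approx(t_hand, rel=1e-9)
        assert res.loc[0, "t"] == pytest.approx(34.64, abs=0.01)
        assert res.loc[0, "p"] < 0.001

    def test_one_sided_direction_is_increase(self):
        rng = np.random.default_rng(0)
        up = np.column_stack([np.full(6, 10.0), 12 + rng.normal(0, 0.3, 6)])
        down = up[:, ::-1]
        assert posthoc_consecutive_t(up).loc[0, "p"] < 0.01
        assert posthoc_consecutive_t(down).loc[0, "p"] > 0.99


class TestBuildTable1:
    def _metrics_from_matrix(self, matrices):
        rows = []
        for layer, m in matrices.items():
            for i in range(m.shape[0]):
                for r in range(m.shape[1]):
                    rows.append(
                        {
                            "drop_height_m": 0.50,
                            "n_layers": layer,
                            "specimen_id": f"L{layer}S{i}",
                            "repetition": r + 1,
                            "force_at_eref_n": m[i, r],
                        }
                    )
        return pd.DataFrame(rows)

    def test_hand_built_matrix_passes_through_exactly(self):
        rng = np.random.default_rng(1)
        m = 10000 + np.cumsum(rng.uniform(100, 500, (3, 5)), axis=1)
        metrics = self._metrics_from_matrix({1: m})
        cfg = StudyConfig()
        results = build_table1(metrics, 30.0, cfg)
        np.testing.assert_allclose(results[1].force_matrix, m)
        np.testing.assert_allclose(results[1].means, m.mean(axis=0))
        np.testing.assert_allclose(results[1].stds, m.std(axis=0, ddof=1))

    def test_missing_cells_reported(self):
        rng = np.random.default_rng(1)
        m = 10000 + rng.uniform(0, 500, (3, 5))
        metrics = self._metrics_from_matrix({2: m})
        metrics = metrics[
            ~((metrics.specimen_id == "L2S1") & (metrics.repetition == 4))
        ]
        with pytest.raises(ValueError, match="missing"):
            build_table1(metrics, 30.0, StudyConfig())

    def test_study_table_is_significant_and_monotone(self, study):
        _, results = study
        for layer, r in results["repeated"].items():
            assert r.anova_p < 0.05
            assert 0.0 <= r.eta_squared <= 1.0
            assert r.posthoc_p[0] < 0.05  # second strike clearly stiffer
            assert r.increase_pct[0] == 0.0
            # mean force saturates upward across strikes
            assert np.all(np.diff(r.means) > -1e-9)
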