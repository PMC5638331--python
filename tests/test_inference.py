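"""Hotelling T², critical values, effect sizes, and pairwise step tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import volvar
from volvar.config import SimulationConfig
from volvar.inference import (
    PAIRWISE_COMPARISONS,
    generalized_eta_squared,
    hotelling_critical,
    hotelling_one_sample,
    pairwise_step_tests,
    repeated_measures_test,
    within_subject_ss,
)


class TestHotellingStatistic:
    def test_all_zero_contrasts(self):
        assert hotelling_one_sample(np.zeros((10, 3))) == 0.0

    def test_three_subject_hand_example(self):
        # mean 2, unbiased variance 1 -> T2 = 3 * 2^2 / 1 = 12
        assert hotelling_one_sample([[1.0], [2.0], [3.0]]) == pytest.approx(12.0, rel=1e-12)

    def test_p1_equals_squared_one_sample_t(self, rng):
        for _ in range(25):
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.5, 2), size=rng.integers(5, 40))
            t, _ = stats.ttest_1samp(x, 0.0)
            assert hotelling_one_sample(x[:, None]) == pytest.approx(t**2, rel=1e-10)

    def test_affine_invariance(self, rng):
        D = rng.normal(0.3, 1.0, size=(40, 3))
        t2 = hotelling_one_sample(D)
        for _ in range(20):
            A = rng.normal(size=(3, 3))
            while abs(np.linalg.det(A)) < 1e-3:
                A = rng.normal(size=(3, 3))
            assert hotelling_one_sample(D @ A) == pytest.approx(t2, rel=1e-8)

    def test_n_not_greater_than_p_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            hotelling_one_sample(np.eye(3))

    def test_collinear_contrasts_rejected(self, rng):
        col = rng.normal(1.0, 1.0, size=(20, 1))
        with pytest.raises(ValueError, match="singular"):
            hotelling_one_sample(np.hstack([col, 2 * col]))


class TestCriticalValues:
    def test_default_df_matches_f_scaling_in_n(self):
        for p, n in [(3, 20), (4, 115), (1, 10)]:
            expected = p * (n - 1) / (n - p) * stats.f.ppf(0.95, p, n - p)
            assert hotelling_critical(p, n) == pytest.approx(expected, rel=1e-12)

    def test_p1_reduces_to_squared_t_critical(self):
        n, alpha = 30, 0.05
        t_crit = stats.t.ppf(1 - alpha / 2, n - 1)
        assert hotelling_critical(1, n, alpha) == pytest.approx(t_crit**2, rel=1e-10)

    def test_monotone_increasing_in_p(self):
        cvs = [hotelling_critical(p, 115) for p in (1, 2, 4, 5, 20)]
        assert all(a < b for a, b in zip(cvs, cvs[1:]))

    def test_monotone_decreasing_in_n(self):
        cvs = [hotelling_critical(4, n) for n in (10, 20, 50, 115, 1000)]
        assert all(a > b for a, b in zip(cvs, cvs[1:]))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hotelling_critical(4, 4)
        with pytest.raises(ValueError):
            hotelling_critical(4, 115, alpha=1.5)
        with pytest.raises(ValueError):
            hotelling_critical(0, 10)


class TestRepeatedMeasures:
    @pytest.mark.parametrize(
        "factor, expected_p",
        [("step", 4), ("roi", 5), ("step_x_roi", 20), ("run", 4), ("day", 2)],
    )
    def test_contrast_dimensions(self, small_ratios, factor, expected_p):
        res = repeated_measures_test(small_ratios, factor)
        assert res.p_contrasts == expected_p
        assert res.n_subjects == 30
        assert res.reject == (res.t2 > res.critical_value)

    def test_equal_biases_no_noise_retain_everywhere(self, noise_free_config):
        ratios = volvar.ratio_correct(volvar.generate_volume_table(noise_free_config))
        res = repeated_measures_test(ratios, "step")
        assert res.t2 == 0.0
        assert not res.reject

    def test_step_effect_of_one_to_two_percent_is_detected(self):
        # biases in the 1-2% range conventionally read as meaningful
        cfg = SimulationConfig(
            n_participants=115,
            n_runs=1,
            step_bias={"RROT": {r: 0.985 for r in volvar.ROIS},
                       "N4BC": {r: 1.01 for r in volvar.ROIS}},
            seed=17,
        )
        ratios = volvar.ratio_correct(volvar.generate_volume_table(cfg))
        assert repeated_measures_test(ratios, "step").reject

    def test_incomplete_crossing_refused(self, small_ratios):
        with pytest.raises(ValueError, match="incomplete"):
            repeated_measures_test(small_ratios.iloc[:-1], "step")

    def test_unknown_factor_rejected(self, small_ratios):
        with pytest.raises(ValueError, match="factor"):
            repeated_measures_test(small_ratios, "scanner")


class TestGeneralizedEtaSquared:
    def test_null_factor_gives_zero(self):
        y = np.tile(np.arange(1.0, 5.0)[:, None, None], (1, 3, 2))  # subjects differ, no effect
        assert generalized_eta_squared(within_subject_ss(y), "A") == 0.0

    def test_pure_effect_without_error_gives_one(self):
        y = np.tile(np.array([1.0, 2.0, 3.0])[None, :, None], (6, 1, 2))
        assert generalized_eta_squared(within_subject_ss(y), "A") == 1.0

    def test_zero_total_ss_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            generalized_eta_squared(within_subject_ss(np.ones((4, 3, 2))), "A")

    def test_matches_reference_anova_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        n, a, b = 15, 4, 3
        y = (
            rng.normal(0, 1, (n, a, b))
            + rng.normal(0, 1, (n, 1, 1))
            + np.linspace(0, 0.6, a)[None, :, None]
        )
        ss = within_subject_ss(y)
        rows = [
            {"subj": i, "A": f"a{j}", "B": f"b{k}", "y": y[i, j, k]}
            for i in range(n)
            for j in range(a)
            for k in range(b)
        ]
        aov = pg.rm_anova(
            data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subj",
            detailed=True, effsize="ng2",
        ).set_index("Source")
        assert generalized_eta_squared(ss, "A") == pytest.approx(aov.loc["A", "ng2"], abs=1e-8)
        assert generalized_eta_squared(ss, "B") == pytest.approx(aov.loc["B", "ng2"], abs=1e-8)
        assert generalized_eta_squared(ss, "AB") == pytest.approx(aov.loc["A * B", "ng2"], abs=1e-8)


class TestPairwiseStepTests:
    def test_grid_shape_and_comparisons(self, small_ratios):
        results = pairwise_step_tests(small_ratios)
        assert len(results) == 7 * 6
        assert list(dict.fromkeys(r.comparison for r in results)) == [
            f"{a} vs {b}" for a, b in PAIRWISE_COMPARISONS
        ]
        for r in results:
            assert r.df == 29
            assert r.significant == (r.p_value < r.alpha / 7)

    def test_bonferroni_threshold(self, small_ratios):
        r = pairwise_step_tests(small_ratios, alpha=0.05)[0]
        assert r.alpha / r.n_comparisons == pytest.approx(0.05 / 7, rel=1e-12)
        assert 0.05 / 7 == pytest.approx(0.00714, abs=5e-6)

    def test_identical_paired_samples_give_zero_t(self, noise_free_config):
        ratios = volvar.ratio_correct(volvar.generate_volume_table(noise_free_config))
        for r in pairwise_step_tests(ratios):
            assert r.t == 0.0
            assert not r.significant

    def test_matches_hand_computed_paired_t(self, rng):
        # 5-subject paired example: t = dbar / (s_d / sqrt(n))
        cfg = SimulationConfig(n_participants=5, n_scans=2, n_runs=1, seed=23)
        ratios = volvar.ratio_correct(volvar.generate_volume_table(cfg))
        cells = ratios.groupby(["participant_id", "step", "roi"])["ratio"].mean()
        a = cells.xs(("ORIG", "LHip"), level=("step", "roi")).to_numpy()
        b = cells.xs(("RROT", "LHip"), level=("step", "roi")).to_numpy()
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        result = [
            r for r in pairwise_step_tests(ratios)
            if r.comparison == "ORIG vs RROT" and r.roi == "LHip"
        ][0]
        assert result.t == pytest.approx(expected, rel=1e-12)

    def test_missing_step_level_rejected(self, small_ratios):
        subset = small_ratios[small_ratios["step"] != "FS"]
        with pytest.raises(ValueError, match="missing step"):
            pairwise_step_tests(subset)
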