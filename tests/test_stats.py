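"""Mixed model, Satterthwaite df, BH adjustment, effect sizes, boxplots."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from fibremorph.stats import (
    bh_adjust,
    boxplot_summary,
    cohens_d,
    effect_category,
    fit_metric_lmm,
    nerve_ttest,
    results_to_frame,
    significance_stars,
)
from fibremorph.synthetic import simulate_metric_table


def step_up_oracle(p: np.ndarray) -> np.ndarray:
    """Independent BH step-up: q_(i) = min_{j>=i} m p_(j)/j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBHAdjust:
    def test_hand_worked_case(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.037]), [0.037])

    def test_matches_independent_step_up_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), step_up_oracle(p), atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_q_dominates_p_and_is_monotone_in_sorted_order(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_case(self):
        # means differ by 1, both sds exactly 1
        assert cohens_d([0.0, 1.0, 2.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 30), rng.normal(0.6, 1.3, 25)
        assert cohens_d(a, b) == pytest.approx(cohens_d(10 * a, 10 * b))

    def test_unsigned(self):
        assert cohens_d([0.0, 1.0, 2.0], [5.0, 6.0, 7.0]) > 0
        assert cohens_d([5.0, 6.0, 7.0], [0.0, 1.0, 2.0]) == \
            cohens_d([0.0, 1.0, 2.0], [5.0, 6.0, 7.0])

    def test_zero_pooled_sd_undefined(self):
        with pytest.warns(UserWarning, match="pooled sd"):
            assert np.isnan(cohens_d([1.0, 1.0], [2.0, 2.0]))


class TestEffectCategory:
    @pytest.mark.parametrize("d,expected", [
        (0.0, "none"), (0.19, "none"), (0.2, "small"), (0.49, "small"),
        (0.5, "medium"), (0.79, "medium"), (0.8, "large"), (3.0, "large"),
    ])
    def test_bins(self, d, expected):
        assert effect_category(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            effect_category(-0.1)


class TestStars:
    @pytest.mark.parametrize("q,expected", [
        (0.5, "ns"), (0.1, "*"), (0.009, "**"), (0.0009, "***"),
        (0.00009, "****"),
    ])
    def test_annotation_convention(self, q, expected):
        assert significance_stars(q) == expected


class TestNerveTTest:
    def test_identical_groups_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        assert nerve_ttest(a, a) == pytest.approx(1.0)

    def test_symmetric_under_swap(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        assert nerve_ttest(a, b) == pytest.approx(nerve_ttest(b, a))

    def test_null_calibration(self):
        rng = np.random.default_rng(11)
        rejections = sum(
            nerve_ttest(rng.normal(0, 1, 15), rng.normal(0, 1, 15)) < 0.05
            for _ in range(500))
        assert 0.03 <= rejections / 500 <= 0.07

    def test_zero_variance_both_groups_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(nerve_ttest([2.0, 2.0], [2.0, 2.0]))


class TestBoxplotSummary:
    def test_stated_formula_on_one_to_five(self):
        s = boxplot_summary([1, 2, 3, 4, 5])
        assert (s.q1, s.median, s.q3) == (2.0, 3.0, 4.0)
        assert s.whisker_lo == -1.0 and s.whisker_hi == 7.0
        assert s.mean == 3.0 and len(s.outliers) == 0

    def test_constant_vector(self):
        s = boxplot_summary([4.0] * 6)
        assert s.q1 == s.median == s.q3 == s.mean == 4.0
        assert len(s.outliers) == 0

    def test_outliers_are_exactly_points_beyond_whiskers(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            v = rng.standard_t(df=3, size=60)
            s = boxplot_summary(v)
            expected = v[(v < s.whisker_lo) | (v > s.whisker_hi)]
            np.testing.assert_array_equal(np.sort(s.outliers), np.sort(expected))


class TestMixedModel:
    def test_matches_external_satterthwaite_reference(self):
        """Balanced 3-condition fixture cross-checked against
        lmerTest::contest1D (R) on the identical CSV."""
        table = simulate_metric_table(n_conditions=3, animals_per_condition=5,
                                      images_per_animal=4, effect=[0.4, 0.1],
                                      animal_sd=0.3, residual_sd=0.25, seed=42)
        res = {r.contrast: r for r in fit_metric_lmm(table, "value")}
        reference = {
            "G1 vs G2": (-0.7186514, 0.1770121, 12.0, 0.00158199),
            "G1 vs G3": (-0.0062929, 0.1770121, 12.0, 0.9722251),
            "G2 vs G3": (0.7123585, 0.1770121, 12.0, 0.00168623),
        }
        for contrast, (est, se, df, p) in reference.items():
            r = res[contrast]
            assert r.estimate == pytest.approx(est, abs=2e-5)
            assert r.se == pytest.approx(se, rel=1e-4)
            assert r.df == pytest.approx(df, rel=0.02)
            assert r.p == pytest.approx(p, rel=0.03)

    def test_zero_animal_variance_reduces_to_two_sample_comparison(self):
        # one image per animal: the random intercept is absorbed into the
        # residual and the model collapses to an ordinary comparison
        table = simulate_metric_table(2, 12, 1, effect=0.3, animal_sd=0.0,
                                      residual_sd=0.3, seed=21)
        r = fit_metric_lmm(table, "value")[0]
        t_p = sps.ttest_ind(table.query("condition == 'G1'")["value"],
                            table.query("condition == 'G2'")["value"]).pvalue
        assert r.p == pytest.approx(t_p, rel=0.10)

    def test_duplicating_rows_leaves_inference_unchanged(self):
        table = simulate_metric_table(2, 6, 3, effect=0.3, animal_sd=0.3,
                                      residual_sd=0.15, seed=22)
        p1 = fit_metric_lmm(table, "value")[0].p
        p2 = fit_metric_lmm(pd.concat([table, table], ignore_index=True),
                            "value")[0].p
        assert abs(p2 - p1) / p1 < 0.05

    def test_significance_flag_is_exactly_q_below_alpha(self):
        table = simulate_metric_table(3, 6, 3, effect=[0.8, 0.0],
                                      animal_sd=0.2, residual_sd=0.2, seed=23)
        for r in fit_metric_lmm(table, "value"):
            assert r.significant == (r.q < 0.1)
            assert r.q >= r.p - 1e-12

    def test_log_transform_drops_nonpositive_values(self):
        table = simulate_metric_table(2, 5, 3, effect=0.2, seed=24,
                                      baseline=1.0)
        table.loc[0, "value"] = -1.0
        res = fit_metric_lmm(table, "value", log_transform=True)
        assert res[0].n_a + res[0].n_b == len(table) - 1

    def test_satterthwaite_df_bounded_by_residual_df(self):
        table = simulate_metric_table(2, 5, 4, effect=0.1, animal_sd=0.4,
                                      residual_sd=0.2, seed=25)
        r = fit_metric_lmm(table, "value")[0]
        assert 1.0 <= r.df <= len(table) - 2

    def test_results_frame_columns(self):
        table = simulate_metric_table(2, 4, 2, seed=26)
        frame = results_to_frame(fit_metric_lmm(table, "value"))
        assert {"contrast", "estimate", "se", "df", "p", "q", "d",
                "d_category", "significant", "stars"} <= set(frame.columns)
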