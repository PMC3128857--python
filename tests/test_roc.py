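"""ROC/AUC primitives: Mann-Whitney statistic, binormal model, thresholds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from gesdx import (
    BinormalParams,
    GroupedMarkers,
    InvalidInputError,
    SensitivityThresholds,
    binormal_auc,
    binormal_sens_spec,
    confusion_at_threshold,
    empirical_auc,
    empirical_roc_points,
    threshold_at_sensitivity,
    thresholds_at_levels,
)
from conftest import auc_by_pair_enumeration

scores = st.lists(
    st.integers(min_value=-5, max_value=5).map(float), min_size=1, max_size=15
)


class TestEmpiricalAUC:
    @pytest.mark.parametrize(
        "d, c, expected",
        [
            ([1], [0], 1.0),  # perfect separation
            ([5], [5], 0.5),  # all ties
            ([3, 5, 7], [2, 5, 6], 5.5 / 9),  # mixed, one tie pair
        ],
    )
    def test_examples(self, d, c, expected):
        assert empirical_auc(d, c) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(scores, scores)
    def test_matches_pair_enumeration_and_complement(self, d, c):
        auc = empirical_auc(d, c)
        assert auc == pytest.approx(auc_by_pair_enumeration(d, c), abs=1e-12)
        assert auc + empirical_auc(c, d) == pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(scores, scores)
    def test_invariant_under_monotone_transform(self, d, c):
        f = lambda x: np.expm1(np.asarray(x) / 2.0)  # strictly increasing
        assert empirical_auc(d, c) == pytest.approx(
            empirical_auc(f(d), f(c)), abs=1e-12
        )

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            empirical_auc([], [1.0])


class TestROCPoints:
    def test_endpoints_and_perfect_point(self):
        pts = empirical_roc_points([1], [0])
        assert tuple(pts[0]) == (0.0, 0.0)
        assert tuple(pts[-1]) == (1.0, 1.0)
        assert any(np.allclose(p, (0.0, 1.0)) for p in pts)

    @settings(derandomize=True, max_examples=100)
    @given(scores, scores)
    def test_trapezoid_area_equals_auc(self, d, c):
        pts = empirical_roc_points(d, c)
        area = np.trapezoid(pts[:, 1], pts[:, 0])
        assert area == pytest.approx(empirical_auc(d, c), abs=1e-12)


class TestBinormal:
    def test_equal_means_gives_half(self):
        bp = BinormalParams([1.0, 2.0], [1.0, 2.0], np.eye(2), 2 * np.eye(2))
        assert binormal_auc(bp, [0.3, 0.7]) == pytest.approx(0.5)

    def test_negating_alpha_flips_auc(self):
        bp = BinormalParams([1.0], [0.0], [[1.0]], [[2.0]])
        a = binormal_auc(bp, [1.0])
        assert binormal_auc(bp, [-1.0]) == pytest.approx(1.0 - a)

    def test_unit_separation_matches_sampling(self, rng):
        # p=1 with mean gap sqrt(var_X+var_Y): AUC = Phi(1) ~ 0.8413
        bp = BinormalParams([np.sqrt(2.0)], [0.0], [[1.0]], [[1.0]])
        assert binormal_auc(bp, [1.0]) == pytest.approx(norm.cdf(1.0))
        d = rng.normal(np.sqrt(2.0), 1.0, 100_000)
        c = rng.normal(0.0, 1.0, 100_000)
        assert binormal_auc(bp, [1.0]) == pytest.approx(
            empirical_auc(d, c), abs=0.005
        )

    def test_zero_variance_rejected(self):
        bp = BinormalParams([1.0], [0.0], [[0.0]], [[0.0]])
        with pytest.raises(InvalidInputError):
            binormal_auc(bp, [1.0])

    def test_sens_spec_at_diseased_mean_and_limits(self):
        bp = BinormalParams([1.0], [0.0], [[1.0]], [[1.0]])
        sens, _ = binormal_sens_spec(bp, [1.0], 1.0)
        assert sens == pytest.approx(0.5)
        sens_lo, spec_lo = binormal_sens_spec(bp, [1.0], -50.0)
        assert sens_lo == pytest.approx(1.0) and spec_lo == pytest.approx(0.0)
        # sensitivity strictly decreasing in the cutoff
        s = [binormal_sens_spec(bp, [1.0], cc)[0] for cc in (-1, 0, 1, 2)]
        assert all(a > b for a, b in zip(s, s[1:]))


class TestThresholds:
    def test_order_statistic_rule(self):
        c = threshold_at_sensitivity(list(range(1, 11)), 0.9)
        assert c < 2  # below the 2nd smallest score
        achieved = np.mean(np.arange(1, 11) > c)
        assert achieved >= 0.9

    def test_largest_admissible_cutoff(self, rng):
        w = rng.normal(size=37)
        for level in (0.7, 0.8, 0.9):
            c = threshold_at_sensitivity(w, level)
            assert np.mean(w > c) >= level
            # the next-larger candidate cutoff violates the level
            above = np.sort(np.unique(w[w > c]))
            next_c = above[0] + (above[1] - above[0]) / 2
            assert np.mean(w > next_c) < level

    def test_median_cutoff_at_level_half(self, rng):
        w = np.sort(rng.normal(size=501))
        c = threshold_at_sensitivity(w, 0.5)
        assert abs(c - np.median(w)) < np.ptp(w) * 0.02

    def test_normal_quantile_recovery(self, rng):
        w = rng.normal(1.0, 1.0, 10_000)
        c = threshold_at_sensitivity(w, 0.8)
        assert c == pytest.approx(1.0 - 0.8416, abs=0.05)

    def test_binormal_inversion(self):
        bp = BinormalParams([1.0], [0.0], [[1.0]], [[1.0]])
        c = threshold_at_sensitivity(
            level=0.9, basis="binormal", params=bp, alpha=[1.0]
        )
        assert c == pytest.approx(1.0 - 1.2816, abs=1e-3)

    def test_all_tied_scores_saturate_with_warning(self):
        with pytest.warns(RuntimeWarning, match="saturat"):
            c = threshold_at_sensitivity([4.0, 4.0, 4.0], 0.9)
        assert c < 4.0

    def test_thresholds_ordered_with_levels(self, rng):
        w = rng.normal(size=200)
        thr = thresholds_at_levels((0.7, 0.8, 0.9), scores_diseased=w)
        assert thr.cutoffs[0] >= thr.cutoffs[1] >= thr.cutoffs[2]

    def test_inconsistent_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            SensitivityThresholds((0.7, 0.9), (0.0, 1.0), "empirical")


class TestConfusion:
    @pytest.mark.parametrize(
        "d, c, cutoff, expected",
        [
            ([2, 3], [0, 1], 1.5, (2, 0, 2, 0)),
            ([2, 3], [0, 1], 99.0, (0, 2, 2, 0)),
            ([3, 5, 7], [2, 5, 6], 5.0, (1, 2, 2, 1)),  # 5 is not > 5
        ],
    )
    def test_counts(self, d, c, cutoff, expected):
        assert confusion_at_threshold(d, c, cutoff) == expected

    def test_partition(self, rng):
        d, c = rng.normal(1, 1, 40), rng.normal(0, 1, 25)
        tp, fn, tn, fp = confusion_at_threshold(d, c, 0.3)
        assert tp + fn == 40 and tn + fp == 25


def test_grouped_markers_validation():
    with pytest.raises(InvalidInputError):
        GroupedMarkers([[1.0]], [[0.0], [1.0]])  # m < 2
    with pytest.raises(InvalidInputError):
        GroupedMarkers([[1.0], [np.inf]], [[0.0], [1.0]])
    gm = GroupedMarkers([[1, 2], [3, 4]], [[0, 1], [2, 3]], ("h3", "h4"))
    sub = gm.subset(["h4"])
    assert sub.p == 1 and sub.diseased[:, 0].tolist() == [2.0, 4.0]
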