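import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinthresh.roc import (
    DegenerateInputError,
    RocDirection,
    auc,
    auc_delong_ci,
    build_roc,
    candidate_cutoffs,
    select_closest_to_corner,
)

HIGHER = RocDirection.HIGHER_PREDICTS_POSITIVE
LOWER = RocDirection.LOWER_PREDICTS_POSITIVE


def brute_force_auc(scores, labels):
    """O(n^2) pair counting: the definition of the Mann-Whitney AUC."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    wins = sum(1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg)
    return wins / (len(pos) * len(neg))


small_datasets = st.tuples(
    st.lists(st.integers(0, 12), min_size=1, max_size=15),
    st.lists(st.integers(0, 12), min_size=1, max_size=15),
)


class TestBuildRoc:
    def test_perfect_separation_has_corner_point(self):
        scores = [25, 30, 5, 10]
        labels = [1, 1, 0, 0]
        curve = build_roc(scores, labels, HIGHER)
        cuts = [p.cutoff for p in curve.points]
        assert 17.5 in cuts
        p = curve.points[cuts.index(17.5)]
        assert p.sensitivity == 1.0 and p.specificity == 1.0

    def test_midpoint_between_integer_improvements_exists(self):
        # integer 0-12 instrument with improvements at 1 and 2 offers 1.5
        curve = build_roc([1, 2, 2, 1], [0, 1, 1, 0], HIGHER)
        assert 1.5 in [p.cutoff for p in curve.points]

    def test_all_identical_scores_yield_only_sentinels(self):
        curve = build_roc([4, 4, 4], [1, 1, 0], HIGHER)
        # cutoffs 3 and 5: everything positive, then everything negative
        assert [p.cutoff for p in curve.points] == [3.0, 5.0]
        assert [(p.sensitivity, p.specificity) for p in curve.points] == [
            (1.0, 0.0),
            (0.0, 1.0),
        ]

    def test_curve_spans_both_extremes(self, rng):
        s = rng.normal(size=50)
        y = rng.random(50) < 0.4
        curve = build_roc(s, y, HIGHER)
        sens = [p.sensitivity for p in curve.points]
        spec = [p.specificity for p in curve.points]
        assert sens[0] == 1.0 and spec[0] == 0.0
        assert sens[-1] == 0.0 and spec[-1] == 1.0
        assert all(a >= b for a, b in zip(sens, sens[1:]))  # monotone sweep

    def test_single_class_raises(self):
        with pytest.raises(DegenerateInputError):
            build_roc([1, 2, 3], [1, 1, 1], HIGHER)

    def test_shift_invariance(self, rng):
        s = rng.integers(0, 10, 30).astype(float)
        y = rng.random(30) < 0.5
        if y.all() or not y.any():
            y[0] = ~y[0]
        a = build_roc(s, y, HIGHER)
        b = build_roc(s + 100.0, y, HIGHER)
        assert [(p.sensitivity, p.specificity) for p in a.points] == [
            (p.sensitivity, p.specificity) for p in b.points
        ]


class TestClosestToCorner:
    def test_hand_computed_distances(self):
        # d1 = hypot(.10, .22) = 0.2418 beats d2 = hypot(.40, .05) = 0.4031
        from clinthresh.roc import ROCCurve, ROCPoint

        curve = ROCCurve(
            [ROCPoint(1.0, 0.90, 0.78), ROCPoint(2.0, 0.60, 0.95)], 5, 5, HIGHER
        )
        sel = select_closest_to_corner(curve)
        assert sel.cutoff == 1.0
        assert sel.distance_to_corner == pytest.approx(0.24166, abs=1e-4)

    def test_perfect_point_selected_with_zero_distance(self):
        curve = build_roc([25, 30, 5, 10], [1, 1, 0, 0], HIGHER)
        sel = select_closest_to_corner(curve)
        assert sel.distance_to_corner == 0.0
        assert sel.sensitivity == sel.specificity == 1.0

    def test_tie_broken_by_higher_sensitivity(self):
        from clinthresh.roc import ROCCurve, ROCPoint

        curve = ROCCurve(
            [ROCPoint(1.0, 0.7, 0.9), ROCPoint(2.0, 0.9, 0.7)], 5, 5, HIGHER
        )
        assert select_closest_to_corner(curve).sensitivity == 0.9

    @given(small_datasets)
    @settings(max_examples=150, deadline=None)
    def test_matches_exhaustive_minimization(self, data):
        pos, neg = data
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg), bool)
        curve = build_roc(scores, labels, HIGHER)
        sel = select_closest_to_corner(curve)
        best = min(p.distance_to_corner for p in curve.points)
        assert sel.distance_to_corner == pytest.approx(best)
        # tie-break: no point with equal distance has higher sensitivity
        ties = [
            p
            for p in curve.points
            if p.distance_to_corner == pytest.approx(sel.distance_to_corner)
        ]
        assert sel.sensitivity == max(t.sensitivity for t in ties)


class TestAUC:
    def test_hand_counted_pairs(self):
        # pairs (3,2)+ (3,4)- (5,2)+ (5,4)+ -> 3/4
        assert auc([3, 5, 2, 4], [1, 1, 0, 0], HIGHER) == 0.75

    def test_perfect_separation(self):
        assert auc([10, 9, 1, 2], [1, 1, 0, 0], HIGHER) == 1.0

    def test_uninformative_scores_near_half(self, rng):
        s = rng.normal(size=4000)
        y = rng.random(4000) < 0.5
        assert auc(s, y, HIGHER) == pytest.approx(0.5, abs=0.05)

    @given(small_datasets)
    @settings(max_examples=200, deadline=None)
    def test_equals_brute_force_pair_counting(self, data):
        pos, neg = data
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg), bool)
        assert auc(scores, labels, HIGHER) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @given(small_datasets)
    @settings(max_examples=100, deadline=None)
    def test_direction_reversal_complements(self, data):
        pos, neg = data
        scores = np.array(pos + neg, float)
        labels = np.array([1] * len(pos) + [0] * len(neg), bool)
        assert auc(scores, labels, LOWER) == pytest.approx(
            1.0 - auc(scores, labels, HIGHER)
        )

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        s = rng.integers(0, 20, 300).astype(float)
        y = rng.random(300) < 0.4
        assert auc(s, y, HIGHER) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


class TestDeLong:
    def test_matches_hand_computed_placement_variance(self):
        # positives {3,5}, negatives {2,4}: V10 = {.5, 1}, V01 = {1, .5},
        # var = .125/2 + .125/2 = 0.125
        est = auc_delong_ci([3, 5, 2, 4], [1, 1, 0, 0], HIGHER)
        assert est.auc == 0.75
        assert est.variance == pytest.approx(0.125)

    def test_auc_equals_mann_whitney_exactly(self, rng):
        s = rng.integers(0, 15, 200).astype(float)
        y = rng.random(200) < 0.5
        est = auc_delong_ci(s, y, HIGHER)
        assert est.auc == pytest.approx(auc(s, y, HIGHER), abs=1e-12)

    def test_perfect_separation_degenerate_ci(self):
        est = auc_delong_ci([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0], HIGHER)
        assert est.auc == 1.0 and est.variance == 0.0
        assert (est.ci_low, est.ci_high) == (1.0, 1.0)

    def test_ci_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 200, 800):
            s = np.concatenate([rng.normal(1, 1, n), rng.normal(0, 1, n)])
            y = np.array([1] * n + [0] * n, bool)
            est = auc_delong_ci(s, y, HIGHER)
            widths.append(est.ci_high - est.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_ci_clipped_to_unit_interval(self):
        est = auc_delong_ci([3, 4, 1, 3.5], [1, 1, 0, 0], HIGHER)
        assert 0.0 <= est.ci_low <= est.auc <= est.ci_high <= 1.0

    def test_too_few_per_class_raises(self):
        with pytest.raises(DegenerateInputError):
            auc_delong_ci([1, 2, 3], [1, 0, 0], HIGHER)


def test_candidate_cutoffs_bracket_all_observations():
    cuts = candidate_cutoffs(np.array([1.0, 2.0, 5.0]))
    assert list(cuts) == [0.0, 1.5, 3.5, 6.0]
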