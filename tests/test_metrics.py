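import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from delmar import (
    binarize_top_fraction,
    hausdorff_metric,
    icc,
    intensity_similarity,
    match_components,
    spatial_similarity,
)
from delmar.metrics import similarity_matrix
from delmar.metrics import test_retest_matrix as retest_matrix


class TestBinarize:
    def test_exact_count(self):
        rng = np.random.default_rng(0)
        assert binarize_top_fraction(rng.standard_normal(100), 0.05).size == 5

    def test_full_fraction_selects_all(self):
        assert binarize_top_fraction(np.arange(10.0), 1.0).size == 10

    def test_selects_largest_values(self):
        idx = binarize_top_fraction(np.array([5.0, 4.0, 3.0, 2.0, 1.0]), 0.4)
        assert set(idx.tolist()) == {0, 1}

    def test_ties_break_to_lower_index(self):
        idx = binarize_top_fraction(np.ones(10), 0.3)
        np.testing.assert_array_equal(np.sort(idx), [0, 1, 2])


class TestSpatialSimilarity:
    def test_identical_maps(self):
        v = np.random.default_rng(1).standard_normal(200)
        assert spatial_similarity(v, v) == 1.0

    def test_disjoint_active_sets(self):
        x = np.r_[np.ones(5), np.zeros(95)]
        y = np.r_[np.zeros(95), np.ones(5)]
        assert spatial_similarity(x, y) == 0.0

    def test_partial_overlap_hand_count(self):
        # component active set covers 2 of the template's 4 active voxels
        template = np.r_[4.0, 3.0, 2.0, 1.0, np.zeros(6)]
        component = np.r_[4.0, 3.0, 0.0, 0.0, 2.0, 1.0, np.zeros(4)]
        assert spatial_similarity(component, template, fraction=0.4) == 0.5

    def test_asymmetric_by_construction(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 100))
        x[:3] += 10  # component set bigger overlap one way
        s_xy = spatial_similarity(x, y, fraction=0.1)
        s_yx = spatial_similarity(y, x, fraction=0.1)
        # values computed both ways; the definition itself divides by the
        # template only, so symmetry is not guaranteed
        assert 0 <= s_xy <= 1 and 0 <= s_yx <= 1

    def test_jaccard_variant_is_symmetric(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 100))
        assert spatial_similarity(x, y, symmetric=True) == \
            spatial_similarity(y, x, symmetric=True)


class TestIntensitySimilarity:
    @pytest.mark.parametrize("x, y, expected", [
        ([2.0], [1.0], 3.0),
        ([1.0, 3.0], [2.0, 1.0], 5.0),
    ])
    def test_hand_computed_sums(self, x, y, expected):
        assert intensity_similarity(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_identical_maps_hit_epsilon_guard(self):
        v = np.array([1.0, 1.0])
        assert intensity_similarity(v, v) == pytest.approx(4e8)


class TestHausdorffMetric:
    def test_identical_maps_give_one(self):
        v = np.abs(np.random.default_rng(4).standard_normal(100))
        assert hausdorff_metric(v, v) == pytest.approx(1.0)

    def test_disjoint_active_sets_give_zero(self):
        x = np.r_[np.ones(5), np.zeros(95)]
        y = np.r_[np.zeros(95), np.ones(5)]
        assert hausdorff_metric(x, y) == 0.0

    def test_small_hand_counts(self):
        # single shared active voxel: X = 2 min(2,1) = 2, Y = 2 + 1 = 3
        assert hausdorff_metric(np.array([2.0, 0.0]), np.array([1.0, 0.5]),
                                fraction=0.5) == pytest.approx(2 / 3)
        # two shared active voxels:
        # X = 2 (min(2,1) + min(1.5,1.2)) = 4.4, Y = (2+1) + (1.5+1.2) = 5.7
        x = np.array([2.0, 1.5, 0.0, 0.0])
        y = np.array([1.0, 1.2, 0.1, 0.0])
        assert hausdorff_metric(x, y, fraction=0.5) == pytest.approx(4.4 / 5.7)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(arrays(float, 40, elements=st.floats(0, 100)),
           arrays(float, 40, elements=st.floats(0, 100)))
    def test_bounded_and_symmetric(self, x, y):
        h_xy = hausdorff_metric(x, y, fraction=0.2)
        h_yx = hausdorff_metric(y, x, fraction=0.2)
        assert 0.0 <= h_xy <= 1.0
        assert h_xy == pytest.approx(h_yx)

    def test_noise_degrades_expected_similarity(self):
        rng = np.random.default_rng(5)
        base = np.abs(rng.standard_normal(500))
        means = []
        for amp in (0.0, 0.5, 1.0, 2.0):
            vals = [hausdorff_metric(base, base + amp * np.abs(rng.standard_normal(500)))
                    for _ in range(20)]
            means.append(np.mean(vals))
        assert all(a >= b - 1e-9 for a, b in zip(means, means[1:]))


class TestMatchComponents:
    def test_two_by_two_enumeration(self):
        # use a pearson-free path: inject the similarity matrix via maps that
        # realise it is overkill; check the assignment rule on a toy instead
        comps = np.array([[10.0, 0.0, 0, 0], [0.0, 10.0, 0, 0]])
        sim = match_components(comps, comps, metric="spatial", fraction=0.5)
        assert sim.assignment == {0: 0, 1: 1}
        np.testing.assert_allclose(np.diag(sim.values), 1.0)

    def test_matches_brute_force_over_all_injections(self):
        rng = np.random.default_rng(6)
        comps = rng.standard_normal((5, 60))
        tmpls = rng.standard_normal((4, 60))
        sim = match_components(comps, tmpls, metric="hausdorff", fraction=0.2)
        values = similarity_matrix(comps, tmpls, metric="hausdorff", fraction=0.2)
        best = max(
            (sum(values[c, t] for c, t in zip(perm, range(4)))
             for perm in itertools.permutations(range(5), 4)),
        )
        assert sum(sim.matched_values) == pytest.approx(best)

    def test_too_few_components_rejected(self):
        with pytest.raises(ValueError, match="at least as many"):
            match_components(np.ones((2, 10)), np.ones((3, 10)))

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="unknown metric"):
            match_components(np.ones((2, 10)), np.ones((2, 10)), metric="dice")


class TestTestRetest:
    def test_identical_sessions_match_perfectly(self):
        rng = np.random.default_rng(7)
        maps = np.abs(rng.standard_normal((4, 100)))
        trt = retest_matrix(maps, maps)
        assert trt.mean_matched == pytest.approx(1.0)

    def test_unrelated_sessions_score_lower(self):
        rng = np.random.default_rng(8)
        s1 = np.abs(rng.standard_normal((4, 200)))
        s2 = np.abs(rng.standard_normal((4, 200)))
        paired = retest_matrix(s1, s1).mean_matched
        unrelated = retest_matrix(s1, s2).mean_matched
        assert unrelated < paired


class TestIcc:
    def test_perfect_grouping_gives_one(self):
        table = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
        assert icc(table) == pytest.approx(1.0)

    def test_matches_hand_anova(self):
        table = np.array([[1.0, 2.0], [4.0, 6.0], [7.0, 9.0]])
        n, k = table.shape
        grand = table.mean()
        msb = k * ((table.mean(1) - grand) ** 2).sum() / (n - 1)
        msw = ((table - table.mean(1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        expected = (msb - msw) / (msb + (k - 1) * msw)
        assert icc(table) == pytest.approx(expected)

    def test_matches_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(9)
        table = rng.standard_normal((6, 3)) + np.arange(6)[:, None]
        long = pd.DataFrame({
            "targets": np.repeat(np.arange(6), 3),
            "raters": np.tile(np.arange(3), 6),
            "scores": table.ravel(),
        })
        ref = pingouin.intraclass_corr(long, targets="targets", raters="raters",
                                       ratings="scores")
        expected = float(ref["ICC"].iloc[0])  # first row: one-way random ICC(1,1)
        assert icc(table) == pytest.approx(expected, abs=1e-9)

    def test_null_structure_is_near_zero(self):
        rng = np.random.default_rng(10)
        vals = [icc(rng.standard_normal((10, 3))) for _ in range(1000)]
        assert abs(np.mean(vals)) <= 0.2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 4)))
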