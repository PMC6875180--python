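"""Discretization, mutual information, and mRMR relevance/redundancy scores."""

import numpy as np
import pytest

from netscale.mrmr import (
    DiscretizedFeatures,
    discretize,
    mi_matrix,
    mutual_information,
    per_feature_mid,
    redundancy_distance_regression,
    redundancy_matrix,
    subset_mid_curve,
    table_scores,
)


def disc_from_states(states):
    states = np.asarray(states, dtype=np.int8)
    return DiscretizedFeatures(
        states=states,
        mean=np.zeros(states.shape[1]),
        sd=np.ones(states.shape[1]),
        alpha=1.0,
    )


class TestDiscretize:
    def test_direct_rule_application(self):
        X = np.array([[0.0], [10.0], [-10.0]])
        disc = discretize(X, alpha=0.5)
        assert disc.states[:, 0].tolist() == [0, 1, -1]

    def test_location_scale_invariance(self, rng):
        X = rng.standard_normal((30, 4))
        Y = 3.5 * X - 7.0
        np.testing.assert_array_equal(
            discretize(X).states, discretize(Y).states
        )

    def test_constant_feature_warns_zero(self):
        X = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning, match="constant"):
            disc = discretize(X)
        assert np.all(disc.states[:, 1] == 0)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            discretize(np.zeros((3, 1)), alpha=0.0)


class TestMutualInformation:
    def test_self_information_uniform_binary(self):
        a = np.array([0, 0, 1, 1])
        assert mutual_information(a, a) == pytest.approx(1.0)

    def test_empirical_independence(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_hand_enumerated_joint_table(self):
        # joint of a=(0,0,1,1), b=(0,0,0,1): p(0,0)=1/2, p(1,0)=1/4, p(1,1)=1/4
        expect = (
            0.5 * np.log2(0.5 / (0.5 * 0.75))
            + 0.25 * np.log2(0.25 / (0.5 * 0.75))
            + 0.25 * np.log2(0.25 / (0.5 * 0.25))
        )
        assert mutual_information([0, 0, 1, 1], [0, 0, 0, 1]) == pytest.approx(expect)

    def test_symmetric_nonnegative_relabel_invariant(self, rng):
        a = rng.integers(-1, 2, size=50)
        b = rng.integers(-1, 2, size=50)
        ab = mutual_information(a, b)
        assert ab >= 0
        assert ab == pytest.approx(mutual_information(b, a))
        relabel = {-1: 7, 0: 3, 1: 5}
        a2 = np.array([relabel[v] for v in a])
        assert mutual_information(a2, b) == pytest.approx(ab)

    def test_nats_option_and_length_mismatch(self):
        a = np.array([0, 0, 1, 1])
        assert mutual_information(a, a, base=np.e) == pytest.approx(np.log(2))
        with pytest.raises(ValueError):
            mutual_information(a, a[:3])


class TestTableScores:
    def test_singleton_subset_literal_formula(self):
        states = np.array([[0], [0], [1], [1]])
        labels = np.array([0, 1, 0, 1])
        disc = disc_from_states(states)
        D, R, mid = table_scores(disc, labels, [0])
        assert D == pytest.approx(mutual_information(labels, states[:, 0]))
        assert R == pytest.approx(1.0)  # I(i,i) = H(i) = 1 bit
        assert mid == pytest.approx(D - R)

    def test_zero_relevance_when_labels_independent(self):
        states = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        labels = np.array([0, 1, 1, 0])  # independent of both columns
        D, R, mid = table_scores(disc_from_states(states), labels, [0, 1])
        assert D == pytest.approx(0.0)
        assert mid == pytest.approx(-R)

    def test_mid_identity_exact(self, rng):
        states = rng.integers(-1, 2, size=(30, 6))
        labels = rng.integers(0, 2, size=30)
        D, R, mid = table_scores(disc_from_states(states), labels, [0, 2, 4])
        assert abs(mid - (D - R)) < 1e-12


class TestPerFeatureMID:
    def test_single_feature_scores_relevance(self):
        states = np.array([[0], [0], [1], [1]])
        labels = np.array([0, 0, 1, 1])
        scores, order = per_feature_mid(disc_from_states(states), labels)
        assert scores[0] == pytest.approx(1.0)
        assert order.tolist() == [0]

    def test_duplicate_feature_penalized(self, rng):
        col = rng.integers(-1, 2, size=40)
        labels = (col > 0).astype(int)
        states = np.column_stack([col, col])
        disc = disc_from_states(states)
        scores, order = per_feature_mid(disc, labels)
        rel = mutual_information(labels, col)
        h = mutual_information(col, col)
        first, second = order
        assert scores[first] == pytest.approx(rel)
        assert scores[second] == pytest.approx(rel - h)
        assert scores[second] <= 0

    def test_invariant_to_column_order(self, rng):
        states = rng.integers(-1, 2, size=(40, 5))
        labels = rng.integers(0, 2, size=40)
        disc = disc_from_states(states)
        scores, _ = per_feature_mid(disc, labels)
        perm = rng.permutation(5)
        scores_p, _ = per_feature_mid(disc_from_states(states[:, perm]), labels)
        np.testing.assert_allclose(scores_p, scores[perm], atol=1e-12)


class TestSubsetMidCurve:
    def test_full_prefix_is_global_mean(self, rng):
        scores = rng.standard_normal(9)
        sizes, means = subset_mid_curve(scores, np.arange(9), step=3)
        assert sizes.tolist() == [3, 6, 9]
        assert means[-1] == pytest.approx(scores.mean())

    def test_step_larger_than_count_single_point(self, rng):
        scores = rng.standard_normal(4)
        sizes, means = subset_mid_curve(scores, np.arange(4), step=10)
        assert sizes.tolist() == [4]

    def test_invalid_step(self):
        with pytest.raises(ValueError):
            subset_mid_curve(np.zeros(3), np.arange(3), step=0)


class TestRedundancy:
    def test_identical_and_independent_pairs(self):
        a = np.array([0, 0, 1, 1] * 5)
        b = np.array([0, 1, 0, 1] * 5)
        disc = disc_from_states(np.column_stack([a, a, b]))
        red = redundancy_matrix(disc, [0, 1, 2])
        assert red[0, 1] == pytest.approx(1.0)  # H of a uniform binary feature
        assert red[0, 2] == pytest.approx(0.0)
        assert np.all(np.diag(red) == 0)

    def test_matches_pairwise_calls(self, rng):
        states = rng.integers(-1, 2, size=(25, 4))
        disc = disc_from_states(states)
        red = redundancy_matrix(disc, [0, 1, 2, 3])
        np.testing.assert_allclose(red, red.T)
        for i in range(4):
            for j in range(i + 1, 4):
                assert red[i, j] == pytest.approx(
                    mutual_information(states[:, i], states[:, j])
                )

    def test_subset_too_small(self):
        with pytest.raises(ValueError):
            redundancy_matrix(disc_from_states(np.zeros((4, 2), dtype=int)), [0])


class TestRedundancyDistanceRegression:
    def test_exact_linear_fit(self):
        dist = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        red = 2.0 - 0.3 * dist
        res = redundancy_distance_regression(red, dist)
        assert res["slope"] == pytest.approx(-0.3)
        assert res["adjusted_r2"] == pytest.approx(1.0)

    def test_matrix_input_uses_upper_triangle(self, rng):
        m = rng.random((5, 5))
        red = (m + m.T) / 2
        dist = np.abs(np.subtract.outer(np.arange(5.0), np.arange(5.0)))
        res = redundancy_distance_regression(red, dist)
        assert res["n_pairs"] == 10

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            redundancy_distance_regression([0.1, 0.2], [1.0, 2.0])
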