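import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seqmeg.seqness import (brute_force_sequenceness, empirical_two_tailed_level,
                            enumerate_label_classes, length_n_curve,
                            mean_diff_curve, pairwise_matrix,
                            pairwise_sequenceness, permutation_thresholds,
                            permute_matrix, sample_order_thresholds,
                            sequenceness_curve, transition_transform)


def _random_stochastic(rng, n=6):
    M = rng.random((n, n)) + 0.05
    return M / M.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# transition_transform
# ---------------------------------------------------------------------------

class TestTransitionTransform:
    def test_identity_matrix(self, rng):
        X = rng.random((50, 6))
        np.testing.assert_array_equal(transition_transform(X, np.eye(6)), X)

    def test_one_hot_forward(self, T):
        X = np.zeros((5, 6))
        X[2, 0] = 1.0  # S1 active at one bin
        XF = transition_transform(X, T)
        assert XF[2, 1] == 0.5 and XF[2, 4] == 0.5  # successors S2, S5
        assert XF[2].sum() == 1.0

    def test_two_steps_associative(self, T, rng):
        X = rng.random((40, 6))
        XFF = transition_transform(X, T, steps=2)
        np.testing.assert_allclose(XFF, transition_transform(X, T) @ T,
                                   atol=1e-14)

    def test_reverse_uses_transpose(self, T, rng):
        X = rng.random((40, 6))
        np.testing.assert_array_equal(transition_transform(X, T, reverse=True),
                                      X @ T.T)

    def test_shape_mismatch(self, T):
        with pytest.raises(ValueError):
            transition_transform(np.zeros((10, 5)), T)


# ---------------------------------------------------------------------------
# sequenceness_curve and the explicit-loop oracle
# ---------------------------------------------------------------------------

class TestSequencenessCurve:
    def test_oracle_equivalence_random_inputs(self, T):
        rng = np.random.default_rng(0)
        for i in range(20):
            X = rng.random((120, 6))
            M = T if i % 2 == 0 else _random_stochastic(rng)
            got = sequenceness_curve(X, M, [30.0, 70.0]).diff
            want = [brute_force_sequenceness(X, M, lag) for lag in (30.0, 70.0)]
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_forward_orientation_pinned(self, T):
        """Planted forward chain (state then its successor at +lag) gives
        positive forward sequenceness at that lag."""
        X = np.full((300, 6), 0.1)
        state = 0
        for t0 in range(10, 280, 30):
            X[t0, state] = 0.9
            X[t0 + 4, (state + 1) % 6] = 0.9  # the 'up' (+1) successor
            state = (state + 2) % 6
        curve = sequenceness_curve(X, T, [40.0])
        assert curve.forward[0] > 0.1
        assert curve.diff[0] > 0.1

    def test_transpose_antisymmetry(self, T, rng):
        X = rng.random((150, 6))
        lags = [10.0, 40.0, 90.0]
        d1 = sequenceness_curve(X, T, lags).diff
        d2 = sequenceness_curve(X, T.T, lags).diff
        np.testing.assert_allclose(d1, -d2, atol=1e-12)

    def test_relabeling_equivariance(self, T, rng):
        X = rng.random((150, 6))
        perm = rng.permutation(6)
        Tp = permute_matrix(T, perm)
        c1 = sequenceness_curve(X, T, [20.0, 40.0])
        c2 = sequenceness_curve(X[:, perm], Tp, [20.0, 40.0])
        np.testing.assert_allclose(c1.forward, c2.forward, atol=1e-12)
        np.testing.assert_allclose(c1.reverse, c2.reverse, atol=1e-12)

    def test_zero_variance_columns_give_zero(self, T):
        X = np.full((100, 6), 0.25)
        curve = sequenceness_curve(X, T, [40.0])
        assert curve.forward[0] == 0.0 and curve.reverse[0] == 0.0
        assert brute_force_sequenceness(X, T, 40.0) == 0.0

    def test_values_bounded(self, T, rng):
        X = rng.random((200, 6))
        c = sequenceness_curve(X, T)
        assert np.all(np.abs(c.forward) <= 1) and np.all(np.abs(c.reverse) <= 1)
        assert np.all(np.abs(c.diff) <= 2)

    def test_rejects_lag_beyond_trial(self, T):
        with pytest.raises(ValueError):
            sequenceness_curve(np.random.rand(15, 6), T, [140.0])

    def test_rejects_offgrid_lag(self, T):
        with pytest.raises(ValueError):
            sequenceness_curve(np.random.rand(100, 6), T, [15.0])

    def test_null_noise_small(self, T):
        """i.i.d. noise: |diff| stays within ~3 analytic SEs at every lag."""
        rng = np.random.default_rng(42)
        n = 2000
        X = rng.random((n, 6))
        c = sequenceness_curve(X, T, [10.0, 40.0, 100.0, 200.0])
        se = 1.0 / np.sqrt(n)          # per-correlation SE under the null
        assert np.all(np.abs(c.diff) < 3 * se * 2)

    @given(arrays(float, (30, 6), elements=st.floats(0.01, 0.99)))
    @settings(max_examples=20, deadline=None)
    def test_antisymmetry_property(self, X):
        g_T = np.array(
            [[0, .5, 0, 0, .5, 0], [0, 0, .5, 0, 0, .5], [.5, 0, 0, .5, 0, 0],
             [0, .5, 0, 0, .5, 0], [0, 0, .5, 0, 0, .5], [.5, 0, 0, .5, 0, 0]])
        d1 = sequenceness_curve(X, g_T, [40.0]).diff[0]
        d2 = sequenceness_curve(X, g_T.T, [40.0]).diff[0]
        assert abs(d1 + d2) < 1e-10


# ---------------------------------------------------------------------------
# length-n curves
# ---------------------------------------------------------------------------

class TestLengthN:
    def test_planted_forward_triplets_positive(self, T):
        X = np.full((400, 6), 0.05)
        for t0 in range(10, 370, 40):
            X[t0, 0] = 0.9        # S1
            X[t0 + 4, 1] = 0.9    # S2 = up successor
            X[t0 + 8, 2] = 0.9    # S3
        c3 = length_n_curve(X, T, 3, [20.0, 40.0, 60.0])
        assert np.argmax(c3.forward) == 1
        assert c3.diff[1] > 0

    def test_relabeling_equivariance(self, T, rng):
        X = rng.random((200, 6))
        perm = rng.permutation(6)
        c1 = length_n_curve(X, T, 3, [30.0, 40.0])
        c2 = length_n_curve(X[:, perm], permute_matrix(T, perm), 3, [30.0, 40.0])
        np.testing.assert_allclose(c1.diff, c2.diff, atol=1e-12)

    def test_rejects_bad_n(self, T):
        with pytest.raises(ValueError):
            length_n_curve(np.random.rand(100, 6), T, 1, [40.0])

    def test_rejects_short_trial(self, T):
        with pytest.raises(ValueError):
            length_n_curve(np.random.rand(20, 6), T, 5, [60.0])


# ---------------------------------------------------------------------------
# pairwise sequenceness
# ---------------------------------------------------------------------------

class TestPairwise:
    def test_antisymmetric_exact(self, rng):
        X = rng.random((150, 6))
        for i, j in [(0, 1), (2, 5), (3, 4)]:
            s_ij = pairwise_sequenceness(X, (i, j), 40.0)
            s_ji = pairwise_sequenceness(X, (j, i), 40.0)
            assert s_ij == -s_ji

    def test_matrix_antisymmetric(self, rng):
        M = pairwise_matrix(rng.random((150, 6)), 40.0)
        np.testing.assert_allclose(M, -M.T, atol=1e-14)

    def test_planted_pair_dominates(self):
        X = np.full((600, 6), 0.1)
        # plant reverse events on the S1->S2 edge: S2 then S1 at +40 ms
        for t0 in range(10, 560, 30):
            X[t0, 1] = 0.9
            X[t0 + 4, 0] = 0.9
        M = pairwise_matrix(X, 40.0)
        assert abs(M[1, 0]) == np.abs(M).max()
        assert M[1, 0] > 0  # S2 followed by S1

    def test_rejects_equal_pair(self, rng):
        with pytest.raises(ValueError):
            pairwise_sequenceness(rng.random((100, 6)), (2, 2), 40.0)

    def test_noise_within_null_band(self):
        rng = np.random.default_rng(8)
        X = rng.random((3000, 6))
        M = pairwise_matrix(X, 40.0)
        off = M[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 6 / np.sqrt(3000)


# ---------------------------------------------------------------------------
# label classes
# ---------------------------------------------------------------------------

class TestLabelClasses:
    def test_default_graph_has_30_classes(self, T):
        lc = enumerate_label_classes(T)
        assert lc.n_classes == 30
        assert lc.identity_index is not None
        assert lc.reversal_index is not None
        assert len(lc.shuffle_representatives()) == 28

    def test_class_sizes_partition_720(self, T):
        lc = enumerate_label_classes(T)
        assert set(lc.class_sizes) == {24}
        assert sum(lc.class_sizes) == 720

    def test_fully_symmetric_matrix_one_class(self):
        M = np.full((4, 4), 1 / 3)
        np.fill_diagonal(M, 0.0)
        lc = enumerate_label_classes(M)
        assert lc.n_classes == 1

    def test_asymmetric_matrix_720_classes(self):
        rng = np.random.default_rng(0)
        M = _random_stochastic(rng)
        lc = enumerate_label_classes(M)
        assert lc.n_classes == 720
        assert set(lc.class_sizes) == {1}

    def test_representative_matrices_distinct(self, T):
        lc = enumerate_label_classes(T)
        keys = {permute_matrix(T, p).tobytes() for p in lc.representatives}
        assert len(keys) == lc.n_classes


# ---------------------------------------------------------------------------
# permutation thresholds
# ---------------------------------------------------------------------------

class TestPermutationThresholds:
    def test_global_dominates_per_lag(self, T, rng):
        X_trials = [rng.random((120, 6)) for _ in range(4)]
        null = permutation_thresholds(X_trials, T, [20.0, 40.0, 60.0])
        assert np.all(null.global_threshold >= null.per_lag_threshold - 1e-15)

    def test_uses_28_shuffles_on_default_graph(self, T, rng):
        X_trials = [rng.random((120, 6)) for _ in range(2)]
        null = permutation_thresholds(X_trials, T, [40.0])
        assert null.n_shuffles == 28
        assert null.nominal_level == pytest.approx(1 / 28)

    def test_observed_matches_mean_diff_curve(self, T, rng):
        X_trials = [rng.random((120, 6)) for _ in range(3)]
        null = permutation_thresholds(X_trials, T, [20.0, 40.0])
        np.testing.assert_allclose(
            null.observed, mean_diff_curve(X_trials, T, [20.0, 40.0]),
            atol=1e-12)

    def test_planted_signal_detected(self, T):
        rng = np.random.default_rng(5)
        X_trials = []
        for _ in range(6):
            X = rng.random((400, 6)) * 0.2 + 0.1
            for t0 in range(10, 370, 40):   # forward chains, 40 ms lag
                s = int(rng.integers(6))
                X[t0, s] = 0.9
                X[t0 + 4, (s + 1) % 6] = 0.9
            X_trials.append(X)
        null = permutation_thresholds(X_trials, T, [20.0, 40.0, 60.0, 80.0])
        assert null.exceeds_global
        assert null.p_value == pytest.approx(1 / 28)
        assert float(null.lags_ms[np.argmax(np.abs(null.observed))]) == 40.0

    def test_subsampling_shuffles(self, T, rng):
        X_trials = [rng.random((120, 6))]
        null = permutation_thresholds(X_trials, T, [40.0], max_shuffles=10,
                                      rng=rng)
        assert null.n_shuffles == 10

    def test_empirical_level_helper(self):
        assert empirical_two_tailed_level(28) == pytest.approx(1 / 28)
        with pytest.raises(ValueError):
            empirical_two_tailed_level(0)


class TestSampleOrderNull:
    def test_requires_rng(self, T):
        with pytest.raises(ValueError):
            sample_order_thresholds([np.random.rand(100, 6)], T, [40.0])

    def test_shapes(self, T, rng):
        null = sample_order_thresholds([rng.random((100, 6))], T,
                                       [20.0, 40.0], n_shuffles=5, rng=rng)
        assert null.shuffle_curves.shape == (5, 2)
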