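import numpy as np
import pytest

from hicstruct import gcnn
from hicstruct.gcnn import GCNNParams, init_params


def brute_force_consolidate(X, W, i):
    """Scalar loop over the weighted-mean aggregation definition."""
    n, e = X.shape
    num = np.zeros(e)
    den = 0.0
    for j in range(n):
        if j != i and W[i, j] > 0:
            num += W[i, j] * X[j]
            den += W[i, j]
    if den == 0:
        return np.zeros(e)
    return num / den


def brute_force_update(x_i, c_i, w1, w2):
    e = len(x_i)
    out = np.zeros(e)
    for r in range(e):
        for c in range(e):
            out[r] += w1[r, c] * x_i[c] + w2[r, c] * c_i[c]
    return out


class TestConsolidate:
    def test_single_neighbor_returns_neighbor_feature(self, rng):
        X = rng.standard_normal((3, 4))
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.37
        np.testing.assert_allclose(gcnn.consolidate(X, W, 0), X[1], atol=1e-12)

    def test_symmetric_features_cancel(self):
        f = np.array([1.0, -2.0, 3.0])
        X = np.vstack([np.zeros(3), f, -f])
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = W[0, 2] = W[2, 0] = 2.0
        np.testing.assert_allclose(gcnn.consolidate(X, W, 0), np.zeros(3), atol=1e-12)

    @pytest.mark.parametrize("n,e", [(5, 3), (12, 6), (20, 8)])
    def test_matches_scalar_oracle(self, rng, n, e):
        X = rng.standard_normal((n, e))
        W = rng.random((n, n))
        W = (W + W.T) / 2
        W[W < 0.3] = 0.0  # sparsify to exercise the neighborhood mask
        np.fill_diagonal(W, 0.0)
        for i in range(n):
            np.testing.assert_allclose(
                gcnn.consolidate(X, W, i), brute_force_consolidate(X, W, i), atol=1e-12
            )

    def test_isolated_node_zero_vector(self, rng):
        X = rng.standard_normal((3, 4))
        W = np.zeros((3, 3))
        W[1, 2] = W[2, 1] = 1.0
        np.testing.assert_array_equal(gcnn.consolidate(X, W, 0), np.zeros(4))

    def test_diagonal_excluded_from_aggregation(self, rng):
        X = rng.standard_normal((2, 3))
        W = np.array([[5.0, 1.0], [1.0, 5.0]])  # heavy diagonal must not leak in
        np.testing.assert_allclose(gcnn.consolidate(X, W, 0), X[1], atol=1e-12)


class TestUpdate:
    def test_identity_w1(self, rng):
        p = init_params(4, hidden=(3, 3, 3), seed=0)
        p.w1 = np.eye(4)
        p.w2 = np.zeros((4, 4))
        x = rng.standard_normal(4)
        np.testing.assert_allclose(gcnn.update(x, rng.standard_normal(4), p), x, atol=1e-12)

    def test_identity_w2(self, rng):
        p = init_params(4, hidden=(3, 3, 3), seed=0)
        p.w1 = np.zeros((4, 4))
        p.w2 = np.eye(4)
        c = rng.standard_normal(4)
        np.testing.assert_allclose(gcnn.update(rng.standard_normal(4), c, p), c, atol=1e-12)

    def test_matches_explicit_arithmetic(self, rng):
        p = init_params(4, hidden=(3, 3, 3), seed=1)
        x = rng.standard_normal(4)
        c = rng.standard_normal(4)
        np.testing.assert_allclose(
            gcnn.update(x, c, p), brute_force_update(x, c, p.w1, p.w2), atol=1e-12
        )

    def test_shape_mismatch_rejected(self, rng):
        p = init_params(4, hidden=(3, 3, 3), seed=0)
        with pytest.raises(ValueError, match="dimension"):
            gcnn.update(rng.standard_normal(5), rng.standard_normal(5), p)


class TestForward:
    def test_zero_parameters_zero_structure(self, rng):
        p = init_params(6, hidden=(4, 3, 2), seed=0)
        p.w1[:] = 0
        p.w2[:] = 0
        for w in p.mlp_w:
            w[:] = 0
        X = rng.standard_normal((5, 6))
        W = np.ones((5, 5)) - np.eye(5)
        s = gcnn.forward(X, W, p)
        np.testing.assert_array_equal(s.coords, np.zeros((5, 3)))

    def test_permutation_equivariance(self, rng):
        n, e = 8, 5
        p = init_params(e, hidden=(4, 3, 2), seed=2)
        X = rng.standard_normal((n, e))
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        perm = rng.permutation(n)
        y = gcnn.forward(X, W, p).coords
        y_perm = gcnn.forward(X[perm], W[np.ix_(perm, perm)], p).coords
        np.testing.assert_allclose(y_perm, y[perm], atol=1e-10)

    def test_same_params_any_node_count(self, rng):
        p = init_params(5, hidden=(4, 3, 2), seed=3)
        for n in (10, 20):
            X = rng.standard_normal((n, 5))
            W = rng.random((n, n))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            assert gcnn.forward(X, W, p).coords.shape == (n, 3)

    def test_dimension_mismatch_rejected(self, rng):
        p = init_params(5, hidden=(4, 3, 2), seed=0)
        X = rng.standard_normal((4, 7))
        W = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="dimension"):
            gcnn.forward(X, W, p)


class TestBackward:
    def test_gradients_match_finite_differences(self, rng):
        n, e = 6, 4
        p = init_params(e, hidden=(3, 3, 2), seed=4)
        for b in p.mlp_b:  # move activations off the ReLU kink at exactly 0
            b += rng.standard_normal(b.shape) * 0.1
        X = rng.standard_normal((n, e))
        W = rng.random((n, n))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0.0)
        S = gcnn.aggregation_matrix(W)
        T = rng.standard_normal((n, 3))  # arbitrary target for a quadratic loss

        def loss_of(p_):
            Y = gcnn.forward_coords(X, S, p_)
            return 0.5 * np.sum((Y - T) ** 2)

        Y, cache = gcnn.forward_coords(X, S, p, want_cache=True)
        grads = gcnn.backward(Y - T, cache, p)
        for a in cache["acts"]:  # sanity: no activation sits on the kink
            assert np.abs(a).min() > 1e-4

        eps = 1e-6
        for name, arr in [("w1", p.w1), ("w2", p.w2), ("mw1", p.mlp_w[1]), ("mb2", p.mlp_b[2])]:
            idx = (0,) if arr.ndim == 1 else (1, 2)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss_of(p)
            arr[idx] = orig - eps
            lm = loss_of(p)
            arr[idx] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=1e-4, abs=1e-6)


class TestCheckpoint:
    def test_roundtrip(self, tmp_path, rng):
        p = init_params(6, hidden=(4, 3, 2), seed=5)
        f = tmp_path / "ckpt.npz"
        gcnn.save_params(p, f, extra={"gamma_star": 0.8})
        q, meta = gcnn.load_params(f)
        np.testing.assert_array_equal(p.w1, q.w1)
        np.testing.assert_array_equal(p.mlp_w[3], q.mlp_w[3])
        assert meta["gamma_star"] == 0.8
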