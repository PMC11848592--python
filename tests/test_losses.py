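"""GCN forward pass, classifier, loss terms, and gradient correctness."""

import numpy as np
import pytest

from msiseg import (
    Embedding,
    GCNParams,
    ResponseMap,
    build_adjacency,
    classify,
    gcn_forward,
    loss_ent,
    loss_scr,
    loss_sim,
    loss_tv,
    normalize_adjacency,
)
from msiseg.embed import _BN_EPS, _encoder_backward, _encoder_forward, EncoderParams
from msiseg.graph import NormalizedAdjacency
from msiseg.segment import _gcn_backward, _tv_grad
import scipy.sparse as sp


def line_embedding(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    pix = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
    return Embedding(values, (1, n), pix)


def grid_response(grid_values):
    """ResponseMap from an (r, c, k) or (r, c) array of response values."""
    arr = np.asarray(grid_values, dtype=float)
    if arr.ndim == 2:
        arr = arr[..., None]
    nr, nc, k = arr.shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pix = np.stack([rows.ravel(), cols.ravel()], axis=1)
    return ResponseMap(arr.reshape(nr * nc, k), (nr, nc), pix)


def identity_adjacency(n):
    return NormalizedAdjacency(sp.identity(n, format="csr"), np.ones(n))


class TestGcnForward:
    def test_identity_propagation(self, rng):
        E = rng.random((6, 4))  # nonnegative
        emb = line_embedding(E)
        params = GCNParams.identity(4)
        resp, _ = gcn_forward(identity_adjacency(6), emb, params)
        assert np.allclose(resp.response, E / np.sqrt(1.0 + _BN_EPS), atol=1e-12)

    def test_relu_zeroes_negative_channel(self):
        E = np.array([[-1.0, 2.0]])
        params = GCNParams.identity(2)
        resp, _ = gcn_forward(identity_adjacency(1), line_embedding(E), params)
        assert resp.response[0, 0] == 0.0
        assert resp.response[0, 1] > 0.0

    def test_matches_dense_two_multiply_oracle(self, rng):
        n, l, k = 7, 4, 3
        E = rng.normal(size=(n, l))
        emb = line_embedding(E)
        g = build_adjacency(emb, cutoff=np.inf if False else 1e9)
        nz = normalize_adjacency(g)
        params = GCNParams(
            W0=rng.normal(size=(l, k)), W1=rng.normal(size=(k, k)),
            gamma=rng.random(k) + 0.5, beta=rng.normal(size=k),
            running_mean=rng.normal(size=k), running_var=rng.random(k) + 0.5,
        )
        resp, _ = gcn_forward(nz, emb, params)
        A = nz.matrix.toarray()
        H1 = np.maximum(A @ E @ params.W0, 0.0)
        H2 = A @ H1 @ params.W1
        expected = (params.gamma * (H2 - params.running_mean)
                    / np.sqrt(params.running_var + _BN_EPS) + params.beta)
        assert np.abs(resp.response - expected).max() <= 1e-10

    def test_permutation_equivariance(self, rng):
        n, l, k = 9, 3, 4
        E = rng.normal(size=(n, l))
        emb = line_embedding(E)
        nz = normalize_adjacency(build_adjacency(emb, 2.0))
        params = GCNParams.init(l, k, rng)
        resp, _ = gcn_forward(nz, emb, params)
        perm = rng.permutation(n)
        P = sp.csr_matrix((np.ones(n), (np.arange(n), perm)), shape=(n, n))
        nz_p = NormalizedAdjacency((P @ nz.matrix @ P.T).tocsr(), nz.degrees[perm])
        emb_p = Embedding(E[perm], emb.grid_shape, emb.pixel_index[perm])
        resp_p, _ = gcn_forward(nz_p, emb_p, params)
        assert np.allclose(resp_p.response, resp.response[perm], atol=1e-12)


class TestClassify:
    def test_argmax_example(self):
        seg = classify(grid_response(np.array([[[0.1, 0.7, 0.2]]])))
        assert seg.labels.tolist() == [2]

    def test_tie_breaks_to_smallest_channel(self):
        seg = classify(grid_response(np.array([[[0.5, 0.5]]])))
        assert seg.labels.tolist() == [1]

    def test_matches_per_spot_scan(self, rng):
        R = rng.normal(size=(4, 5, 6))
        seg = classify(grid_response(R))
        flat = R.reshape(20, 6)
        expected = [1 + max(range(6), key=lambda i: (flat[s, i], -i))
                    for s in range(20)]
        assert seg.labels.tolist() == expected


class TestLossSim:
    def test_zero_when_confident(self):
        r = grid_response(np.array([[[0.0, 0.0]]]))
        r._probs = np.array([[1.0, 0.0]])
        assert loss_sim(r, np.array([1])) == 0.0

    def test_uniform_binary_softmax_gives_log2(self):
        r = grid_response(np.zeros((2, 2, 2)))  # equal logits -> uniform
        assert loss_sim(r, np.ones(4, dtype=int)) == pytest.approx(np.log(2))

    def test_matches_hand_loop(self, rng):
        R = rng.normal(size=(3, 4, 5))
        r = grid_response(R)
        pseudo = rng.integers(1, 6, size=12)
        got = loss_sim(r, pseudo)
        P = r.probs
        expected = np.mean([-np.log(P[s, pseudo[s] - 1]) for s in range(12)])
        assert got == pytest.approx(expected, abs=1e-9)


class TestLossTv:
    def test_constant_map_is_zero(self):
        assert loss_tv(grid_response(np.full((3, 3), 2.5))) == 0.0

    def test_printed_two_by_two_example(self):
        assert loss_tv(grid_response(np.array([[0.0, 1.0], [0.0, 1.0]]))) == 2.0

    def test_matches_double_loop_oracle(self, rng):
        R = rng.normal(size=(4, 5, 3))
        got = loss_tv(grid_response(R))
        expected = 0.0
        for x in range(4):
            for y in range(5):
                if x + 1 < 4:
                    expected += np.abs(R[x + 1, y] - R[x, y]).sum()
                if y + 1 < 5:
                    expected += np.abs(R[x, y + 1] - R[x, y]).sum()
        assert got == pytest.approx(expected, abs=1e-9)


class TestLossEnt:
    def test_per_pixel_one_hot_is_exactly_zero(self):
        r = grid_response(np.zeros((2, 2, 3)))
        r._probs = np.eye(3)[[0, 1, 2, 0]].astype(float)
        assert loss_ent(r, form="per_pixel") == 0.0

    def test_per_pixel_uniform_rows(self):
        k = 4
        r = grid_response(np.zeros((2, 2, k)))
        assert loss_ent(r, form="per_pixel") == pytest.approx(np.log(k) / k)

    def test_marginal_collapsed_gives_log_k(self):
        k = 5
        r = grid_response(np.zeros((2, 3, k)))
        r._probs = np.tile(np.eye(k)[0], (6, 1))
        assert loss_ent(r, form="marginal") == pytest.approx(np.log(k))

    def test_marginal_balanced_gives_zero(self):
        k = 3
        r = grid_response(np.zeros((1, 3, k)))
        r._probs = np.eye(k).astype(float)
        assert loss_ent(r, form="marginal") == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        for _ in range(5):
            r = grid_response(rng.normal(size=(3, 3, 4)))
            assert loss_ent(r, form="marginal") >= 0.0
            assert loss_ent(r, form="per_pixel") >= 0.0


class TestLossScr:
    def test_zero_when_matching_with_certainty(self):
        r = grid_response(np.zeros((1, 2, 2)))
        r._probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        scribble = np.array([[1, 2]])
        assert loss_scr(r, scribble) == 0.0

    def test_single_cell_quarter_probability(self):
        r = grid_response(np.zeros((1, 2, 4)))  # uniform softmax = 0.25
        scribble = np.array([[3, 0]])
        assert loss_scr(r, scribble) == pytest.approx(-np.log(0.25))

    def test_matches_masked_hand_loop(self, rng):
        R = rng.normal(size=(4, 4, 3))
        r = grid_response(R)
        scribble = rng.integers(0, 4, size=(4, 4))
        if not scribble.any():
            scribble[0, 0] = 1
        got = loss_scr(r, scribble)
        P = r.probs
        terms = []
        for s, (row, col) in enumerate(r.pixel_index):
            lab = scribble[row, col]
            if lab > 0:
                terms.append(-np.log(P[s, lab - 1]))
        assert got == pytest.approx(np.mean(terms), abs=1e-9)

    def test_empty_scribble_is_an_error(self):
        r = grid_response(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="no labeled"):
            loss_scr(r, np.zeros((2, 2), dtype=int))


class TestGradients:
    """Hand-derived backward passes checked against central differences."""

    @staticmethod
    def _fd(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = x[idx]
            x[idx] = orig + eps
            fp = f()
            x[idx] = orig - eps
            fm = f()
            x[idx] = orig
            g[idx] = (fp - fm) / (2 * eps)
        return g

    def test_encoder_backward_matches_finite_differences(self, rng):
        X = rng.normal(size=(7, 3))
        p = EncoderParams.init(3, 4, 2, rng)
        p.b1[:] = rng.normal(size=4)
        T = rng.normal(size=(7, 2))  # loss = sum(E * T)

        def loss():
            E, _ = _encoder_forward(X, p, training=True, bn_momentum=0.0)
            return float((E * T).sum())

        E, cache = _encoder_forward(X, p, training=True, bn_momentum=0.0)
        grads = _encoder_backward(T, p, cache)
        for name in ("W1", "b1", "gamma", "beta", "W2", "b2"):
            fd = self._fd(loss, getattr(p, name))
            assert np.allclose(grads[name], fd, rtol=1e-4, atol=1e-6), name

    def test_gcn_backward_matches_finite_differences(self, rng):
        n, l, k = 6, 3, 4
        E = rng.normal(size=(n, l))
        emb = line_embedding(E)
        nz = normalize_adjacency(build_adjacency(emb, 5.0))
        params = GCNParams.init(l, k, rng)
        T = rng.normal(size=(n, k))

        def loss():
            resp, _ = gcn_forward(nz, emb, params, training=True, bn_momentum=0.0)
            return float((resp.response * T).sum())

        resp, cache = gcn_forward(nz, emb, params, training=True, bn_momentum=0.0)
        grads, dE = _gcn_backward(T, params, cache)
        for name in ("W0", "W1", "gamma", "beta"):
            fd = self._fd(loss, getattr(params, name))
            assert np.allclose(grads[name], fd, rtol=1e-4, atol=1e-6), name
        fd_E = self._fd(loss, emb.values)
        assert np.allclose(dE, fd_E, rtol=1e-4, atol=1e-6)

    def test_tv_gradient_matches_finite_differences(self, rng):
        nr, nc, k = 3, 4, 2
        V = rng.normal(size=(nr * nc, k))  # generic values, no exact ties
        rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
        pix = np.stack([rows.ravel(), cols.ravel()], axis=1)
        _, g = _tv_grad(V, (nr, nc), pix, reduction="mean")
        fd = self._fd(
            lambda: _tv_grad(V, (nr, nc), pix, reduction="mean")[0], V
        )
        assert np.allclose(g, fd, rtol=1e-4, atol=1e-6)
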