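"""Parametric UMAP dimensionality reduction for MSI spectra.

The encoder is a two-layer fully connected network (input -> hidden with
batch normalization and ReLU -> linear output, no activation on the
second layer) trained to minimize the UMAP cross-entropy between fuzzy
simplicial memberships p_ij computed in the high-dimensional spectrum
space and low-dimensional similarities

    q_ij = (1 + a * ||e_i - e_j||^(2b))^(-1).

Because the map is parametric, unseen spectra (e.g. an adjacent tissue
slice) are projected by a single forward pass, which is what makes
cross-slice knowledge transfer possible.

Networks are implemented directly in NumPy with hand-derived gradients;
the architecture is small and fixed, and the gradients are verified
against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .core import MSIDataset

__all__ = [
    "EncoderParams",
    "Embedding",
    "FuzzyMemberships",
    "find_ab_params",
    "compute_fuzzy_memberships",
    "encode",
    "project",
    "umap_loss",
    "fit_warmup",
]

_EPS_Q = 1e-7  # clip for q inside logs
_BN_EPS = 1e-5


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class EncoderParams:
    """Weights of the two-layer encoder, plus batch-norm statistics.

    ``running_mean``/``running_var`` are the inference-time normalization
    statistics of the hidden layer, updated with momentum during training.
    """

    W1: np.ndarray  # (n_ions, hidden)
    b1: np.ndarray  # (hidden,)
    gamma: np.ndarray  # (hidden,)
    beta: np.ndarray  # (hidden,)
    running_mean: np.ndarray  # (hidden,)
    running_var: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden, latent)
    b2: np.ndarray  # (latent,)

    @property
    def n_ions(self) -> int:
        return self.W1.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.W2.shape[1]

    @classmethod
    def init(cls, n_ions: int, hidden: int, latent: int,
             rng: np.random.Generator) -> "EncoderParams":
        if latent < 2:
            raise ValueError("latent dimension must be >= 2")
        W1 = rng.normal(0, np.sqrt(2.0 / n_ions), size=(n_ions, hidden))
        W2 = rng.normal(0, np.sqrt(1.0 / hidden), size=(hidden, latent))
        return cls(
            W1=W1, b1=np.zeros(hidden), gamma=np.ones(hidden),
            beta=np.zeros(hidden), running_mean=np.zeros(hidden),
            running_var=np.ones(hidden), W2=W2, b2=np.zeros(latent),
        )

    def copy(self) -> "EncoderParams":
        return EncoderParams(**{k: v.copy() for k, v in vars(self).items()})


@dataclass
class Embedding:
    """Per-spot latent vectors together with their grid placement."""

    values: np.ndarray  # (n_spots, latent)
    grid_shape: tuple[int, int]
    pixel_index: np.ndarray  # (n_spots, 2)

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def save_csv(self, path) -> None:
        """Export as row,col,e_1..e_l for external plotting."""
        import pandas as pd

        df = pd.DataFrame(self.values,
                          columns=[f"e_{i + 1}" for i in range(self.dim)])
        df.insert(0, "col", self.pixel_index[:, 1])
        df.insert(0, "row", self.pixel_index[:, 0])
        df.to_csv(path, index=False)


@dataclass
class FuzzyMemberships:
    """Symmetrized fuzzy simplicial set memberships p_ij.

    ``rho[i]`` is the distance from point i to its nearest neighbor and
    ``sigma[i]`` the bandwidth calibrated so the smoothed neighbor weights
    sum to log2(n_neighbors).
    """

    matrix: sp.csr_matrix  # symmetric, zero diagonal, values in [0, 1]
    n_neighbors: int
    rho: np.ndarray
    sigma: np.ndarray


# ---------------------------------------------------------------------------
# a, b curve fit
# ---------------------------------------------------------------------------

def find_ab_params(spread: float = 1.0, min_dist: float = 0.1) -> tuple[float, float]:
    """Fit the low-dimensional similarity curve parameters a, b.

    Least-squares fit of ``(1 + a d^(2b))^(-1)`` to the target membership
    curve that is 1 below ``min_dist`` and decays as
    ``exp(-(d - min_dist)/spread)`` beyond it — the standard UMAP
    calibration of its output kernel.
    """

    def curve(x, a, b):
        return 1.0 / (1.0 + a * x ** (2 * b))

    xv = np.linspace(0, spread * 3, 300)
    yv = np.where(xv < min_dist, 1.0, np.exp(-(xv - min_dist) / spread))
    (a, b), _ = scipy.optimize.curve_fit(curve, xv, yv)
    return float(a), float(b)


# ---------------------------------------------------------------------------
# fuzzy simplicial memberships
# ---------------------------------------------------------------------------

def _calibrate_sigma(dists: np.ndarray, rho: np.ndarray, target: float,
                     tol: float = 1e-5, max_iter: int = 100) -> np.ndarray:
    """Per-point bisection for sigma_i solving sum_j exp(-(d_ij-rho_i)+/sigma) = target.

    The weight sum is increasing in sigma; the bracket is expanded upward
    until it contains the target, then bisected.  For degenerate points
    whose neighbor distances all equal rho (the sum is constant) sigma
    falls back to the mean neighbor distance.
    """
    n = dists.shape[0]
    gaps = np.maximum(dists - rho[:, None], 0.0)

    def weight_sum(sigma):
        return np.exp(-gaps / sigma[:, None]).sum(axis=1)

    lo = np.full(n, 1e-12)
    hi = np.ones(n)
    for _ in range(64):
        need = weight_sum(hi) < target
        if not need.any():
            break
        hi[need] *= 2.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        too_small = weight_sum(mid) < target
        lo = np.where(too_small, mid, lo)
        hi = np.where(too_small, hi, mid)
        if np.all(hi - lo < tol * np.maximum(hi, 1.0)):
            break
    sigma = 0.5 * (lo + hi)
    degenerate = gaps.max(axis=1) <= 0
    if degenerate.any():
        fallback = np.maximum(dists.mean(axis=1), 1e-12)
        sigma = np.where(degenerate, np.maximum(fallback, 1.0), sigma)
    return sigma


def compute_fuzzy_memberships(
    data, n_neighbors: int = 15
) -> FuzzyMemberships:
    """Compute the symmetrized fuzzy simplicial set over spectra.

    ``data`` is an :class:`MSIDataset` or a plain (n, d) array.  For each
    point, conditional memberships over its ``n_neighbors`` nearest
    neighbors are ``exp(-(d_ij - rho_i)+ / sigma_i)`` with rho_i the
    nearest-neighbor distance and sigma_i calibrated by bisection so the
    memberships sum to log2(n_neighbors); the directed matrix p' is then
    symmetrized as ``p = p' + p'^T - p' * p'^T`` (probabilistic t-conorm).
    """
    X = data.intensities if isinstance(data, MSIDataset) else np.asarray(data)
    n = X.shape[0]
    if n_neighbors < 2:
        raise ValueError("n_neighbors must be >= 2")
    if n_neighbors >= n:
        raise ValueError("n_neighbors must be smaller than the number of spots")
    nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X)
    dists, idx = nn.kneighbors(X)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self
    rho = dists[:, 0]
    target = np.log2(n_neighbors)
    sigma = _calibrate_sigma(dists, rho, target)
    vals = np.exp(-np.maximum(dists - rho[:, None], 0.0) / sigma[:, None])
    rows = np.repeat(np.arange(n), n_neighbors)
    P = sp.csr_matrix((vals.ravel(), (rows, idx.ravel())), shape=(n, n))
    P.setdiag(0)
    P.eliminate_zeros()
    PT = P.T.tocsr()
    sym = P + PT - P.multiply(PT)
    sym = sym.tocsr()
    sym.data = np.clip(sym.data, 0.0, 1.0)
    return FuzzyMemberships(sym, n_neighbors, rho, sigma)


# ---------------------------------------------------------------------------
# encoder forward / backward
# ---------------------------------------------------------------------------

def _encoder_forward(X: np.ndarray, p: EncoderParams, training: bool,
                     bn_momentum: float = 0.1):
    """Forward pass; returns (embedding, cache) — cache is None in eval mode."""
    A = X @ p.W1 + p.b1
    if training:
        mu = A.mean(axis=0)
        var = A.var(axis=0)
        p.running_mean = (1 - bn_momentum) * p.running_mean + bn_momentum * mu
        p.running_var = (1 - bn_momentum) * p.running_var + bn_momentum * var
    else:
        mu, var = p.running_mean, p.running_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (A - mu) * inv_std
    B = p.gamma * xhat + p.beta
    Z = np.maximum(B, 0.0)
    E = Z @ p.W2 + p.b2
    cache = (X, xhat, inv_std, B, Z) if training else None
    return E, cache


def _encoder_backward(dE: np.ndarray, p: EncoderParams, cache):
    """Gradients of all encoder parameters given dLoss/dE (training mode)."""
    X, xhat, inv_std, B, Z = cache
    n = X.shape[0]
    dW2 = Z.T @ dE
    db2 = dE.sum(axis=0)
    dZ = dE @ p.W2.T
    dB = dZ * (B > 0)
    dgamma = (dB * xhat).sum(axis=0)
    dbeta = dB.sum(axis=0)
    dxhat = dB * p.gamma
    dA = (inv_std / n) * (
        n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    dW1 = X.T @ dA
    db1 = dA.sum(axis=0)
    return {"W1": dW1, "b1": db1, "gamma": dgamma, "beta": dbeta,
            "W2": dW2, "b2": db2}


def encode(ds: MSIDataset, params: EncoderParams) -> Embedding:
    """Deterministic evaluation-mode projection of a dataset."""
    if ds.n_ions != params.n_ions:
        raise ValueError(
            f"encoder expects {params.n_ions} ions, dataset has {ds.n_ions}"
        )
    E, _ = _encoder_forward(ds.intensities, params, training=False)
    return Embedding(E, ds.grid_shape, ds.pixel_index.copy())


def project(ds_new: MSIDataset, params: EncoderParams,
            mz_train: Optional[np.ndarray] = None,
            mz_atol: float = 1e-4) -> Embedding:
    """Project unseen spectra through the trained encoder.

    When the training m/z axis is supplied, the new data's axis must
    match it within ``mz_atol`` Da; otherwise the caller is told to
    re-align peaks to the training axis.
    """
    if mz_train is not None:
        if ds_new.n_ions != len(mz_train) or not np.allclose(
            ds_new.mz, mz_train, rtol=0, atol=mz_atol
        ):
            raise ValueError(
                "m/z axis of the new dataset does not match the training axis; "
                "re-align peaks to the training axis before projecting"
            )
    return encode(ds_new, params)


# ---------------------------------------------------------------------------
# UMAP loss
# ---------------------------------------------------------------------------

def _q_from_d2(d2: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 / (1.0 + a * np.power(np.maximum(d2, 0.0), b))


def umap_loss(
    memberships: FuzzyMemberships,
    emb: Embedding,
    a: float,
    b: float,
    negative_ratio: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """UMAP fuzzy cross-entropy between memberships p and similarities q.

    With ``negative_ratio=None`` the full-batch sum over all unordered
    pairs i < j is returned (quadratic; intended for small instances and
    oracle checks).  Otherwise the sampled estimate used in training is
    returned: every stored edge contributes its attractive term weighted
    by p_ij, plus ``negative_ratio`` uniformly sampled repulsive terms
    per edge with p = 0.  The loss is >= 0 and vanishes iff p = q on all
    evaluated pairs.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    E = emb.values
    if negative_ratio is None:
        P = np.asarray(memberships.matrix.todense())
        d2 = ((E[:, None, :] - E[None, :, :]) ** 2).sum(axis=2)
        q = np.clip(_q_from_d2(d2, a, b), _EPS_Q, 1 - _EPS_Q)
        upper = np.triu(np.ones(len(E), dtype=bool), k=1)
        p = P[upper]
        q = q[upper]
        with np.errstate(divide="ignore", invalid="ignore"):
            att = np.where(p > 0, p * (np.log(p) - np.log(q)), 0.0)
            rep = np.where(p < 1, (1 - p) * (np.log1p(-p) - np.log1p(-q)), 0.0)
        return float((att + rep).sum())
    if rng is None:
        rng = np.random.default_rng()
    coo = sp.triu(memberships.matrix, k=1).tocoo()
    loss, _ = _sampled_umap_loss_grad(E, coo.row, coo.col, coo.data, a, b,
                                      negative_ratio, rng, want_grad=False)
    return float(loss)


def _scatter_add_rows(out: np.ndarray, idx: np.ndarray, g: np.ndarray) -> None:
    """out[idx] += g with repeated indices, via a flat bincount."""
    n, d = out.shape
    flat = (idx[:, None] * d + np.arange(d)).ravel()
    out += np.bincount(flat, weights=g.ravel(), minlength=n * d).reshape(n, d)


def _sampled_umap_loss_grad(
    E: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    pvals: np.ndarray,
    a: float,
    b: float,
    negative_ratio: int,
    rng: np.random.Generator,
    want_grad: bool = True,
    edge_batch: int = 0,
):
    """Edge-sampled UMAP loss and its gradient w.r.t. the embedding.

    Attractive terms use positive edges weighted by p_ij (treated as
    target 1); repulsive terms pair each edge head with ``negative_ratio``
    uniformly drawn points (target 0).  With ``edge_batch`` > 0, that many
    edges are drawn per call with probability proportional to p_ij and
    unit weight — the standard UMAP edge-sampling SGD scheme — instead of
    visiting every edge.  Squared distances in the repulsive gradient are
    stabilized by +1e-3 as in standard UMAP SGD.
    """
    n = E.shape[0]
    if edge_batch and edge_batch < rows.size:
        pick = rng.choice(rows.size, size=edge_batch,
                          p=pvals / pvals.sum(), replace=True)
        rows, cols = rows[pick], cols[pick]
        pvals = np.ones(edge_batch)
    diff = E[rows] - E[cols]
    d2 = np.maximum((diff**2).sum(axis=1), 1e-12)
    pow_b = np.power(d2, b)
    qa = 1.0 + a * pow_b
    loss = float((pvals * np.log(qa)).sum())
    # negatives
    heads = np.repeat(rows, negative_ratio)
    tails = rng.integers(0, n, size=heads.size)
    keep = heads != tails
    heads, tails = heads[keep], tails[keep]
    diff_n = E[heads] - E[tails]
    d2n = np.maximum((diff_n**2).sum(axis=1), 1e-12)
    qan = 1.0 + a * np.power(d2n, b)
    qn = np.clip(1.0 / qan, _EPS_Q, 1 - _EPS_Q)
    loss += float(-np.log1p(-qn).sum())
    if not want_grad:
        return loss, None
    # d/d d2 of log(1 + a d2^b), weighted by p
    coef = pvals * a * b * (pow_b / d2) / qa
    g = (2.0 * coef)[:, None] * diff
    # d/d d2 of -log(1 - q) with the standard (d2 + eps) stabilizer
    coef_n = -b / ((1e-3 + d2n) * qan)
    gn = np.clip((2.0 * coef_n)[:, None] * diff_n, -4.0, 4.0)
    dE = np.zeros_like(E)
    _scatter_add_rows(
        dE,
        np.concatenate([rows, cols, heads, tails]),
        np.concatenate([g, -g, gn, -gn]),
    )
    return loss, dE


# ---------------------------------------------------------------------------
# warm-up training
# ---------------------------------------------------------------------------

class _SGD:
    """SGD with classical momentum (v = m v + g; p -= lr v)."""

    def __init__(self, lr: float, momentum: float):
        self.lr = lr
        self.momentum = momentum
        self._v: dict[str, np.ndarray] = {}

    def step(self, params_obj, grads: dict[str, np.ndarray], prefix: str = ""):
        for name, g in grads.items():
            key = prefix + name
            v = self._v.get(key)
            if v is None:
                v = np.zeros_like(g)
            v = self.momentum * v + g
            self._v[key] = v
            arr = getattr(params_obj, name)
            arr -= self.lr * v


def fit_warmup(ds: MSIDataset, cfg) -> tuple[EncoderParams, Embedding]:
    """Train the encoder on the UMAP loss alone (curriculum warm-up).

    Returns the trained parameters and the evaluation-mode embedding of
    the training data.  Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    params = EncoderParams.init(ds.n_ions, cfg.hidden_dim, cfg.latent_dim, rng)
    memberships = compute_fuzzy_memberships(ds, cfg.n_neighbors)
    a, b = find_ab_params(min_dist=cfg.min_dist)
    _run_warmup_epochs(ds, params, memberships, a, b, cfg, rng,
                       cfg.warmup_epochs)
    emb = encode(ds, params)
    return params, emb


def _run_warmup_epochs(ds, params, memberships, a, b, cfg, rng, epochs,
                       opt: Optional[_SGD] = None) -> list[float]:
    coo = sp.triu(memberships.matrix, k=1).tocoo()
    rows, cols, pvals = coo.row, coo.col, coo.data
    batch = cfg.edge_batch if cfg.edge_batch else rows.size
    n_pairs = max(min(batch, rows.size) * (1 + cfg.negative_ratio), 1)
    opt = opt or _SGD(cfg.learning_rate, cfg.momentum)
    history: list[float] = []
    for _ in range(epochs):
        E, cache = _encoder_forward(ds.intensities, params, training=True,
                                    bn_momentum=cfg.bn_momentum)
        loss, dE = _sampled_umap_loss_grad(
            E, rows, cols, pvals, a, b, cfg.negative_ratio, rng,
            edge_batch=cfg.edge_batch,
        )
        loss /= n_pairs
        if not np.isfinite(loss):
            raise RuntimeError(f"warm-up diverged (loss={loss}); lower the learning rate")
        grads = _encoder_backward(dE / n_pairs, params, cache)
        opt.step(params, grads)
        history.append(loss)
    return history
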