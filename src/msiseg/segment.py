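"""GCN-based spatial segmentation with a multi-task self-training loss.

The embedding of each spot feeds a two-layer graph convolutional network
over the 8-neighbor spatial graph:

    H1 = ReLU(A_hat E W0),     H2 = A_hat H1 W1,

followed by per-channel batch normalization and an argmax classifier
that turns the k-channel response map into region labels.  Training is
unsupervised self-training: the model's own argmax labels serve as
targets for a cross-entropy term, regularized by a total-variation term
pulling spatial neighbors together, an entropy penalty preventing the
trivial one-region solution, and (jointly) the UMAP loss that keeps the
embedding faithful to the spectra.  Two optional modes extend the base
model: scribble fine-tuning adds a partial-annotation cross-entropy, and
knowledge transfer applies the frozen model to an unseen adjacent slice.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
import yaml

from .config import TrainConfig
from .core import MSIDataset
from .embed import (
    Embedding,
    EncoderParams,
    FuzzyMemberships,
    _BN_EPS,
    _SGD,
    _encoder_backward,
    _encoder_forward,
    _sampled_umap_loss_grad,
    compute_fuzzy_memberships,
    encode,
    find_ab_params,
    project,
)
from .graph import (
    NormalizedAdjacency,
    SpatialGraph,
    build_adjacency,
    normalize_adjacency,
    suggest_cutoff,
)
from .phantom import UNLABELED

__all__ = [
    "GCNParams",
    "ResponseMap",
    "SegmentationMap",
    "LossBreakdown",
    "TrainedModel",
    "gcn_forward",
    "classify",
    "loss_sim",
    "loss_tv",
    "loss_ent",
    "loss_scr",
    "train_unsupervised",
    "finetune_with_scribble",
    "transfer_predict",
    "save_checkpoint",
    "load_checkpoint",
]

_CLIP = 1e-7  # probability clip inside logs


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GCNParams:
    """Weights of the two GCN layers plus output batch-norm statistics."""

    W0: np.ndarray  # (latent, k)
    W1: np.ndarray  # (k, k)
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.W0.shape[1]

    @classmethod
    def init(cls, latent: int, k: int, rng: np.random.Generator) -> "GCNParams":
        if k < 2:
            raise ValueError("need at least 2 output channels")
        W0 = rng.normal(0, np.sqrt(2.0 / latent), size=(latent, k))
        W1 = rng.normal(0, np.sqrt(2.0 / k), size=(k, k))
        return cls(W0=W0, W1=W1, gamma=np.ones(k), beta=np.zeros(k),
                   running_mean=np.zeros(k), running_var=np.ones(k))

    @classmethod
    def identity(cls, k: int) -> "GCNParams":
        """Identity weights with unit normalization statistics (for analysis)."""
        return cls(W0=np.eye(k), W1=np.eye(k), gamma=np.ones(k),
                   beta=np.zeros(k), running_mean=np.zeros(k),
                   running_var=np.ones(k))

    def copy(self) -> "GCNParams":
        return GCNParams(**{k: v.copy() for k, v in vars(self).items()})


@dataclass
class ResponseMap:
    """Per-spot k-channel response (post batch-norm) on the grid.

    ``probs`` is the softmax-normalized companion used by the
    probabilistic loss terms; its rows sum to one.  The argmax label is
    the same whether taken on ``response`` or ``probs``.
    """

    response: np.ndarray  # (n_spots, k)
    grid_shape: tuple[int, int]
    pixel_index: np.ndarray

    _probs: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def n_spots(self) -> int:
        return self.response.shape[0]

    @property
    def n_channels(self) -> int:
        return self.response.shape[1]

    @property
    def probs(self) -> np.ndarray:
        if self._probs is None:
            self._probs = _softmax(self.response)
        return self._probs


@dataclass
class SegmentationMap:
    """Integer region label (1..k) per on-tissue spot."""

    labels: np.ndarray  # (n_spots,)
    grid_shape: tuple[int, int]
    pixel_index: np.ndarray

    def to_grid(self, fill: int = 0) -> np.ndarray:
        grid = np.full(self.grid_shape, fill, dtype=np.int64)
        grid[self.pixel_index[:, 0], self.pixel_index[:, 1]] = self.labels
        return grid

    @property
    def n_labels(self) -> int:
        return int(np.unique(self.labels).size) if self.labels.size else 0


@dataclass
class LossBreakdown:
    """Per-epoch values of the multi-task loss terms."""

    dr: float = 0.0
    sim: float = 0.0
    tv: float = 0.0
    ent: float = 0.0
    scr: float = 0.0
    total: float = 0.0


@dataclass
class TrainedModel:
    """A trained segmentation model and the context needed to reuse it.

    ``dataset``/``graph``/``memberships`` reference the training slice
    and are needed for scribble fine-tuning; a model restored from a
    checkpoint carries only parameters until :meth:`attach_dataset` is
    called with the training data.
    """

    encoder: EncoderParams
    gcn: GCNParams
    cutoff: float
    config: TrainConfig
    mz: np.ndarray
    ab: tuple[float, float]
    dataset: Optional[MSIDataset] = None
    memberships: Optional[FuzzyMemberships] = None
    graph: Optional[SpatialGraph] = None
    norm_adj: Optional[NormalizedAdjacency] = None
    segmentation: Optional[SegmentationMap] = None
    history: list[LossBreakdown] = field(default_factory=list)
    scribble_state: Optional[np.ndarray] = None  # accumulated annotations

    def copy(self) -> "TrainedModel":
        out = copy.copy(self)
        out.encoder = self.encoder.copy()
        out.gcn = self.gcn.copy()
        out.history = list(self.history)
        return out

    def attach_dataset(self, ds: MSIDataset) -> None:
        """Recompute the training-side context from the training dataset."""
        if ds.n_ions != len(self.mz) or not np.allclose(ds.mz, self.mz):
            raise ValueError("dataset m/z axis does not match the checkpoint")
        self.dataset = ds
        self.memberships = compute_fuzzy_memberships(ds, self.config.n_neighbors)
        emb = encode(ds, self.encoder)
        self.graph = build_adjacency(emb, self.cutoff)
        self.norm_adj = normalize_adjacency(self.graph)


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _softmax(R: np.ndarray) -> np.ndarray:
    Z = R - R.max(axis=1, keepdims=True)
    e = np.exp(Z)
    return e / e.sum(axis=1, keepdims=True)


def gcn_forward(
    norm_adj: NormalizedAdjacency,
    emb: Embedding,
    params: GCNParams,
    training: bool = False,
    bn_momentum: float = 0.1,
):
    """Two graph convolutions followed by output batch normalization.

    Returns ``(ResponseMap, cache)``; the cache (training mode only)
    carries the intermediates needed by :func:`_gcn_backward`.
    """
    E = emb.values
    if E.shape[1] != params.W0.shape[0]:
        raise ValueError(
            f"embedding dim {E.shape[1]} does not match W0 rows {params.W0.shape[0]}"
        )
    A = norm_adj.matrix
    if A.shape[0] != E.shape[0]:
        raise ValueError("graph and embedding cover different spot counts")
    S = A @ (E @ params.W0)
    H1 = np.maximum(S, 0.0)
    H2 = A @ (H1 @ params.W1)
    if training and H2.shape[0] > 1:
        mu = H2.mean(axis=0)
        var = H2.var(axis=0)
        params.running_mean = (1 - bn_momentum) * params.running_mean + bn_momentum * mu
        params.running_var = (1 - bn_momentum) * params.running_var + bn_momentum * var
    else:
        mu, var = params.running_mean, params.running_var
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (H2 - mu) * inv_std
    R = params.gamma * xhat + params.beta
    resp = ResponseMap(R, emb.grid_shape, emb.pixel_index)
    cache = (A, E, S, H1, xhat, inv_std) if training else None
    return resp, cache


def _gcn_backward(dR: np.ndarray, params: GCNParams, cache):
    """Gradients of GCN parameters and the input embedding given dLoss/dR."""
    A, E, S, H1, xhat, inv_std = cache
    n = E.shape[0]
    dgamma = (dR * xhat).sum(axis=0)
    dbeta = dR.sum(axis=0)
    dxhat = dR * params.gamma
    dH2 = (inv_std / n) * (
        n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
    )
    dM1 = A @ dH2  # A symmetric
    dW1 = H1.T @ dM1
    dH1 = dM1 @ params.W1.T
    dS = dH1 * (S > 0)
    dM0 = A @ dS
    dW0 = E.T @ dM0
    dE = dM0 @ params.W0.T
    grads = {"W0": dW0, "W1": dW1, "gamma": dgamma, "beta": dbeta}
    return grads, dE


def classify(r: ResponseMap) -> SegmentationMap:
    """Argmax classifier; ties break toward the smallest channel index."""
    labels = np.argmax(r.response, axis=1) + 1
    return SegmentationMap(labels, r.grid_shape, r.pixel_index)


# ---------------------------------------------------------------------------
# loss terms
# ---------------------------------------------------------------------------

def _spot_labels(seg) -> np.ndarray:
    return seg.labels if isinstance(seg, SegmentationMap) else np.asarray(seg)


def loss_sim(r: ResponseMap, pseudo) -> float:
    """Self-training cross-entropy against the (detached) argmax labels.

    Mean over spots of the negative log softmax probability assigned to
    each spot's pseudo-label.
    """
    labels = _spot_labels(pseudo)
    p = np.clip(r.probs[np.arange(r.n_spots), labels - 1], _CLIP, None)
    return float(-np.log(p).mean())


def _tv_pairs(grid_shape, pixel_index):
    """Index pairs (u, v) for on-tissue right and down neighbors."""
    nr, nc = grid_shape
    grid = np.full((nr, nc), -1, dtype=np.int64)
    grid[pixel_index[:, 0], pixel_index[:, 1]] = np.arange(len(pixel_index))
    pairs = []
    for dr, dc in ((1, 0), (0, 1)):
        a = grid[: nr - dr, : nc - dc]
        b = grid[dr:, dc:]
        ok = (a >= 0) & (b >= 0)
        pairs.append((a[ok], b[ok]))
    u = np.concatenate([p[0] for p in pairs])
    v = np.concatenate([p[1] for p in pairs])
    return u, v


def loss_tv(r: ResponseMap, reduction: str = "sum") -> float:
    """Total-variation term: L1 difference to the right and down neighbor.

    Operates on the raw (batch-normalized) response values; a spatially
    constant map scores 0.  ``reduction='mean'`` divides by the number
    of spots (used during training so the term is scale-comparable with
    the per-spot cross-entropies).
    """
    u, v = _tv_pairs(r.grid_shape, r.pixel_index)
    total = float(np.abs(r.response[v] - r.response[u]).sum())
    if reduction == "mean":
        return total / max(r.n_spots, 1)
    return total


def _tv_grad(values: np.ndarray, grid_shape, pixel_index, reduction="mean"):
    from .embed import _scatter_add_rows

    u, v = _tv_pairs(grid_shape, pixel_index)
    g = np.zeros_like(values)
    s = np.sign(values[v] - values[u])
    _scatter_add_rows(g, np.concatenate([v, u]), np.concatenate([s, -s]))
    loss = float(np.abs(values[v] - values[u]).sum())
    if reduction == "mean":
        n = max(values.shape[0], 1)
        return loss / n, g / n
    return loss, g


def loss_ent(r: ResponseMap, form: str = "marginal") -> float:
    """Entropy penalty against the trivial single-region solution.

    ``per_pixel`` is the literal average of -1/k * sum_i p_i log p_i per
    spot.  ``marginal`` (the default used in training) is
    ``log k - H(mean softmax row)``: zero when the predicted class
    marginal is uniform and maximal (log k) when every spot collapses
    onto one class, which is what makes it an anti-collapse penalty.
    """
    P = r.probs
    k = r.n_channels
    # 0 * log 0 = 0 convention, exact on one-hot rows
    plogp = np.where(P > 0, P * np.log(np.clip(P, _CLIP, None)), 0.0)
    if form == "per_pixel":
        return float(-plogp.sum(axis=1).mean() / k)
    if form == "marginal":
        m = P.mean(axis=0)
        mlogm = np.where(m > 0, m * np.log(np.clip(m, _CLIP, None)), 0.0)
        return float(np.log(k) + mlogm.sum())
    raise ValueError("form must be 'marginal' or 'per_pixel'")


def loss_scr(r: ResponseMap, scribble: np.ndarray) -> float:
    """Scribble cross-entropy over the labeled grid cells only.

    ``scribble`` is an integer grid with 0 as the unlabeled sentinel.
    """
    idx, lab = _scribble_spots(scribble, r.grid_shape, r.pixel_index,
                               r.n_channels)
    if idx.size == 0:
        raise ValueError("scribble mask contains no labeled on-tissue cell")
    p = np.clip(r.probs[idx, lab - 1], _CLIP, None)
    return float(-np.log(p).mean())


def _scribble_spots(scribble, grid_shape, pixel_index, k):
    scribble = np.asarray(scribble)
    if scribble.shape != tuple(grid_shape):
        raise ValueError("scribble mask shape must equal the grid shape")
    spot_labels = scribble[pixel_index[:, 0], pixel_index[:, 1]]
    idx = np.nonzero(spot_labels != UNLABELED)[0]
    lab = spot_labels[idx]
    if lab.size and (lab.max() > k or lab.min() < 1):
        raise ValueError(f"scribble labels must lie in 1..{k}")
    return idx, lab


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _joint_phase(
    ds: MSIDataset,
    encoder: EncoderParams,
    gcn: GCNParams,
    memberships: FuzzyMemberships,
    norm_adj: NormalizedAdjacency,
    ab: tuple[float, float],
    cfg: TrainConfig,
    rng: np.random.Generator,
    epochs: int,
    cutoff: Optional[float] = None,
    scribble: Optional[np.ndarray] = None,
    enc_opt: Optional[_SGD] = None,
    gcn_opt: Optional[_SGD] = None,
) -> list[LossBreakdown]:
    """Shared optimization loop for base training and scribble fine-tuning."""
    a, b = ab
    X = ds.intensities
    n = ds.n_spots
    coo = sp.triu(memberships.matrix, k=1).tocoo()
    erows, ecols, pvals = coo.row, coo.col, coo.data
    ebatch = cfg.edge_batch if cfg.edge_batch else erows.size
    n_pairs = max(min(ebatch, erows.size) * (1 + cfg.negative_ratio), 1)
    enc_opt = enc_opt or _SGD(cfg.learning_rate, cfg.momentum)
    gcn_opt = gcn_opt or _SGD(cfg.learning_rate, cfg.momentum)
    if scribble is not None:
        scr_idx, scr_lab = _scribble_spots(
            scribble, ds.grid_shape, ds.pixel_index, cfg.k_max
        )
        if scr_idx.size == 0:
            raise ValueError("scribble mask contains no labeled on-tissue cell")
    history: list[LossBreakdown] = []
    for epoch in range(epochs):
        train_enc = not cfg.freeze_encoder
        E, enc_cache = _encoder_forward(X, encoder, training=train_enc,
                                        bn_momentum=cfg.bn_momentum)
        emb = Embedding(E, ds.grid_shape, ds.pixel_index)
        if (cfg.graph_refresh > 0 and cutoff is not None and epoch > 0
                and cfg.graph_space == "embedding"
                and epoch % cfg.graph_refresh == 0):
            norm_adj = normalize_adjacency(
                build_adjacency(encode(ds, encoder), cutoff)
            )
        resp, gcn_cache = gcn_forward(norm_adj, emb, gcn, training=True,
                                      bn_momentum=cfg.bn_momentum)
        P = resp.probs
        pseudo = np.argmax(resp.response, axis=1)  # detached self-training target

        # fused softmax + cross-entropy gradients on the response
        onehot = np.zeros_like(P)
        onehot[np.arange(n), pseudo] = 1.0
        dR = cfg.w_sim * (P - onehot) / n
        l_sim = loss_sim(resp, pseudo + 1)

        l_scr = 0.0
        if scribble is not None:
            onehot_s = np.zeros_like(P)
            onehot_s[scr_idx, scr_lab - 1] = 1.0
            mask = np.zeros((n, 1))
            mask[scr_idx] = 1.0
            dR += cfg.scribble_weight * mask * (P - onehot_s) / scr_idx.size
            l_scr = loss_scr(resp, scribble)

        # losses expressed through the softmax probabilities
        dP = np.zeros_like(P)
        if cfg.ent_form == "marginal":
            m = np.clip(P.mean(axis=0), _CLIP, None)
            dP += cfg.w_ent * (np.log(m) + 1.0)[None, :] / n
            l_ent = float(np.log(P.shape[1]) + (m * np.log(m)).sum())
        else:
            logP = np.log(np.clip(P, _CLIP, None))
            k = P.shape[1]
            dP += -cfg.w_ent * (logP + 1.0) / (k * n)
            l_ent = loss_ent(resp, form="per_pixel")
        l_tv, g_tv = _tv_grad(P, ds.grid_shape, ds.pixel_index, reduction="mean")
        dP += cfg.w_tv * g_tv
        # softmax backward: dR_ij = P_ij (dP_ij - sum_k dP_ik P_ik)
        dR += P * (dP - (dP * P).sum(axis=1, keepdims=True))

        gcn_grads, dE = _gcn_backward(dR, gcn, gcn_cache)

        l_dr = 0.0
        if train_enc:
            if cfg.w_dr != 0.0:
                l_dr, dE_umap = _sampled_umap_loss_grad(
                    E, erows, ecols, pvals, a, b, cfg.negative_ratio, rng,
                    edge_batch=cfg.edge_batch,
                )
                l_dr /= n_pairs
                dE = dE + cfg.w_dr * dE_umap / n_pairs
            enc_grads = _encoder_backward(dE, encoder, enc_cache)
            enc_opt.step(encoder, enc_grads)
        gcn_opt.step(gcn, gcn_grads)

        total = (cfg.w_dr * l_dr + cfg.w_sim * l_sim + cfg.w_tv * l_tv
                 + cfg.w_ent * l_ent + cfg.scribble_weight * l_scr)
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged at epoch {epoch}; last finite breakdown: "
                f"{history[-1] if history else None}"
            )
        history.append(LossBreakdown(l_dr, l_sim, l_tv, l_ent, l_scr, total))
        if np.unique(pseudo).size <= cfg.min_label_count:
            break
    return history


def _graph_features(ds: MSIDataset, encoder: EncoderParams,
                    cfg: TrainConfig) -> Embedding:
    """Vectors whose distances gate the lattice edges (embedding or raw)."""
    if cfg.graph_space == "raw":
        return Embedding(ds.intensities, ds.grid_shape, ds.pixel_index)
    return encode(ds, encoder)


def train_unsupervised(
    ds: MSIDataset, cfg: Optional[TrainConfig] = None
) -> TrainedModel:
    """Two-phase curriculum training of the full model.

    Phase 1 warms up the encoder on the UMAP loss alone; phase 2 builds
    the spatial graph from the warm-up embedding (held fixed unless
    ``graph_refresh`` is set) and jointly optimizes encoder and GCN on
    the multi-task loss.  Training stops at ``fc_epochs`` or as soon as
    the number of distinct predicted labels reaches ``min_label_count``.
    Deterministic given ``cfg.seed``.
    """
    cfg = cfg or TrainConfig()
    if ds.n_spots <= cfg.n_neighbors:
        raise ValueError("dataset too small for the configured n_neighbors")
    rng = np.random.default_rng(cfg.seed)
    encoder = EncoderParams.init(ds.n_ions, cfg.hidden_dim, cfg.latent_dim, rng)
    memberships = compute_fuzzy_memberships(ds, cfg.n_neighbors)
    ab = find_ab_params(min_dist=cfg.min_dist)
    enc_opt = _SGD(cfg.learning_rate, cfg.momentum)
    from .embed import _run_warmup_epochs

    _run_warmup_epochs(ds, encoder, memberships, ab[0], ab[1], cfg, rng,
                       cfg.warmup_epochs, opt=enc_opt)
    gfeat = _graph_features(ds, encoder, cfg)
    cutoff = cfg.cutoff if cfg.cutoff is not None else suggest_cutoff(
        gfeat, cfg.cutoff_quantile
    )
    graph = build_adjacency(gfeat, cutoff)
    norm_adj = normalize_adjacency(graph)
    gcn = GCNParams.init(cfg.latent_dim, cfg.k_max, rng)
    history = _joint_phase(ds, encoder, gcn, memberships, norm_adj, ab, cfg,
                           rng, cfg.fc_epochs, cutoff=float(cutoff),
                           enc_opt=enc_opt)
    model = TrainedModel(
        encoder=encoder, gcn=gcn, cutoff=float(cutoff), config=cfg,
        mz=ds.mz.copy(), ab=ab, dataset=ds, memberships=memberships,
        history=history,
    )
    # prediction always builds the graph from the current (final) features,
    # so transferring to the training slice reproduces this segmentation
    model.graph = build_adjacency(_graph_features(ds, encoder, cfg),
                                  model.cutoff)
    model.norm_adj = normalize_adjacency(model.graph)
    model.segmentation = _predict(model, ds)
    return model


def _predict(model: TrainedModel, ds: MSIDataset,
             norm_adj: Optional[NormalizedAdjacency] = None) -> SegmentationMap:
    emb = encode(ds, model.encoder)
    if norm_adj is None:
        norm_adj = model.norm_adj
    resp, _ = gcn_forward(norm_adj, emb, model.gcn, training=False)
    return classify(resp)


def finetune_with_scribble(
    model: TrainedModel,
    scribble: np.ndarray,
    cfg: Optional[TrainConfig] = None,
) -> tuple[TrainedModel, SegmentationMap]:
    """Scribble-interactive refinement of a trained model.

    Continues joint optimization with the scribble cross-entropy added
    for ``cfg.scribble_epochs`` epochs.  The input model is left intact;
    the returned copy can itself be fine-tuned again with further
    scribbles.  Annotations accumulate across rounds (a newer scribble
    wins on cells labeled twice), so corrections established by earlier
    scribbles keep constraining later rounds instead of being forgotten.
    """
    if model.dataset is None or model.norm_adj is None:
        raise ValueError(
            "model carries no training dataset; call attach_dataset() first"
        )
    cfg = cfg or model.config
    scribble = np.asarray(scribble)
    if not (scribble > UNLABELED).any():
        raise ValueError("scribble mask is empty")
    if scribble.max() > cfg.k_max:
        raise ValueError(f"scribble labels exceed k_max={cfg.k_max}")
    out = model.copy()
    if out.scribble_state is not None:
        scribble = np.where(scribble > UNLABELED, scribble, out.scribble_state)
    out.scribble_state = scribble
    rng = np.random.default_rng((cfg.seed + 1 + len(out.history)) % (2**31))
    history = _joint_phase(
        out.dataset, out.encoder, out.gcn, out.memberships, out.norm_adj,
        out.ab, cfg, rng, cfg.scribble_epochs, scribble=scribble,
    )
    out.history = out.history + history
    # the encoder moved: rebuild the graph it will predict with
    out.graph = build_adjacency(_graph_features(out.dataset, out.encoder, cfg),
                                out.cutoff)
    out.norm_adj = normalize_adjacency(out.graph)
    out.segmentation = _predict(out, out.dataset)
    return out, out.segmentation


def transfer_predict(
    model: TrainedModel,
    ds_new: MSIDataset,
    cutoff_policy: str = "reuse",
) -> SegmentationMap:
    """Segment an unseen slice with the frozen model (knowledge transfer).

    The new slice is projected through the trained encoder, gets its own
    8-neighbor graph (reusing the training cut-off, or re-suggesting one
    with ``cutoff_policy='resuggest'``), and passes once through the GCN
    with frozen parameters and running normalization statistics.
    """
    if cutoff_policy not in ("reuse", "resuggest"):
        raise ValueError("cutoff_policy must be 'reuse' or 'resuggest'")
    emb = project(ds_new, model.encoder, mz_train=model.mz)
    if ds_new.n_spots == 0:
        return SegmentationMap(np.empty(0, dtype=np.int64), ds_new.grid_shape,
                               ds_new.pixel_index)
    gfeat = _graph_features(ds_new, model.encoder, model.config)
    cutoff = model.cutoff
    if cutoff_policy == "resuggest":
        cutoff = suggest_cutoff(gfeat, model.config.cutoff_quantile)
    graph = build_adjacency(gfeat, cutoff)
    norm_adj = normalize_adjacency(graph)
    resp, _ = gcn_forward(norm_adj, emb, model.gcn, training=False)
    return classify(resp)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: TrainedModel, path) -> None:
    """Save model parameters, normalization statistics and config (npz)."""
    enc = {f"enc_{k}": v for k, v in vars(model.encoder).items()}
    gcn = {f"gcn_{k}": v for k, v in vars(model.gcn).items()}
    extra = {}
    if model.scribble_state is not None:
        extra["scribble_state"] = model.scribble_state
    np.savez_compressed(
        Path(path),
        cutoff=np.array(model.cutoff),
        ab=np.array(model.ab),
        mz=model.mz,
        config_yaml=np.array(model.config.to_yaml()),
        **enc, **gcn, **extra,
    )


def load_checkpoint(path) -> TrainedModel:
    """Restore a model from :func:`save_checkpoint` output.

    The result can run :func:`transfer_predict` immediately; scribble
    fine-tuning additionally needs :meth:`TrainedModel.attach_dataset`.
    """
    with np.load(Path(path), allow_pickle=False) as z:
        cfg = TrainConfig(**yaml.safe_load(str(z["config_yaml"])))
        encoder = EncoderParams(
            **{k[4:]: z[k] for k in z.files if k.startswith("enc_")}
        )
        gcn = GCNParams(**{k[4:]: z[k] for k in z.files if k.startswith("gcn_")})
        scr = z["scribble_state"] if "scribble_state" in z.files else None
        return TrainedModel(
            encoder=encoder, gcn=gcn, cutoff=float(z["cutoff"]),
            config=cfg, mz=z["mz"], ab=tuple(z["ab"]),
            scribble_state=scr,
        )
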