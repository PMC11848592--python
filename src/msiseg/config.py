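"""Run configuration for training, fine-tuning and transfer."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

__all__ = ["TrainConfig"]


@dataclass
class TrainConfig:
    """All tunable knobs of the segmentation pipeline.

    The optimizer settings (SGD, learning rate 0.01, momentum 0.9) apply
    to both the warm-up and the joint phase.  Loss weights default to 1
    so the multi-task objective is the plain unweighted sum of its
    terms; the entropy term defaults to the marginal (anti-collapse)
    form, with the literal per-pixel form available via ``ent_form``.
    """

    # architecture
    latent_dim: int = 20
    hidden_dim: int = 256
    k_max: int = 16

    # fuzzy-graph / low-dimensional kernel
    n_neighbors: int = 15
    min_dist: float = 0.1
    negative_ratio: int = 5
    edge_batch: int = 4096  # edges sampled per epoch; 0 = all edges

    # optimizer
    learning_rate: float = 0.01
    momentum: float = 0.9
    bn_momentum: float = 0.1

    # schedule
    warmup_epochs: int = 200
    fc_epochs: int = 500
    scribble_epochs: int = 300
    min_label_count: int = 3

    # loss weights
    w_dr: float = 1.0
    w_sim: float = 1.0
    w_tv: float = 1.0
    w_ent: float = 1.0
    scribble_weight: float = 1.0
    ent_form: str = "marginal"  # marginal | per_pixel

    # spatial graph
    cutoff: float | None = None  # None -> suggest from cutoff_quantile
    cutoff_quantile: float = 0.5
    graph_space: str = "embedding"  # embedding | raw (distance space for edges)
    graph_refresh: int = 0  # rebuild the graph every R epochs; 0 = never
    freeze_encoder: bool = False

    seed: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs < 0 or self.fc_epochs <= 0:
            raise ValueError("epoch counts must be positive")
        if not (self.k_max >= self.min_label_count >= 1):
            raise ValueError("need k_max >= min_label_count >= 1")
        if self.latent_dim < 2:
            raise ValueError("latent_dim must be >= 2")
        if self.ent_form not in ("marginal", "per_pixel"):
            raise ValueError("ent_form must be 'marginal' or 'per_pixel'")
        if self.graph_space not in ("embedding", "raw"):
            raise ValueError("graph_space must be 'embedding' or 'raw'")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text
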