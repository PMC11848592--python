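"""Post-hoc analysis of segmentation results.

Marker screening ranks ions by how well a single-ion logistic classifier
separates one segmented region from the rest (one-vs-rest AUC); the
metabotype similarity network summarizes how alike regions' profiles are
via Euclidean distances between region centers; and evaluation metrics
score a predicted segmentation against known ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform, pdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .core import MSIDataset
from .embed import Embedding
from .phantom import GroundTruth
from .segment import SegmentationMap

__all__ = [
    "MarkerResult",
    "MetabotypeNetwork",
    "Metrics",
    "score_marker_auc",
    "metabotype_network",
    "evaluate_ari",
]


@dataclass
class MarkerResult:
    """AUC of one ion for discriminating one region from the others."""

    mz: float
    region: int
    auc: float
    passes_threshold: bool
    low_confidence: bool = False


def score_marker_auc(
    ds: MSIDataset,
    seg: SegmentationMap,
    region: int,
    auc_floor: float = 0.70,
) -> list[MarkerResult]:
    """Rank ions by one-vs-rest AUC for a segmented region.

    For each ion a logistic regression on that single ion scores every
    spot, and the ROC AUC of those scores against "spot is in the
    region" is reported (in-sample).  Because a single-feature logistic
    model is monotone in its input, the AUC coincides with the
    Mann-Whitney rank statistic when the fitted slope is positive.
    Results are sorted by decreasing AUC.
    """
    labels = seg.labels
    if region not in labels:
        raise ValueError(f"region {region} absent from the segmentation")
    y = (labels == region).astype(int)
    n_pos = int(y.sum())
    low_conf = n_pos < 5
    if low_conf:
        warnings.warn(
            f"region {region} has only {n_pos} spots; AUCs are low-confidence"
        )
    results = []
    for j in range(ds.n_ions):
        x = ds.intensities[:, j : j + 1]
        if np.ptp(x) == 0:
            auc = 0.5
        else:
            clf = LogisticRegression().fit(x, y)
            auc = float(roc_auc_score(y, clf.decision_function(x)))
        results.append(
            MarkerResult(float(ds.mz[j]), int(region), auc,
                         passes_threshold=auc >= auc_floor,
                         low_confidence=low_conf)
        )
    results.sort(key=lambda r: -r.auc)
    return results


@dataclass
class MetabotypeNetwork:
    """Region centers and their pairwise Euclidean distances."""

    regions: np.ndarray  # sorted region labels
    centers: np.ndarray  # (n_regions, dim)
    distances: np.ndarray  # symmetric, zero diagonal


def metabotype_network(
    features, seg: SegmentationMap
) -> MetabotypeNetwork:
    """Build the metabotype similarity network over segmented regions.

    ``features`` supplies the per-spot vectors whose region means become
    the cluster centers: an :class:`Embedding` (default presentation) or
    an :class:`MSIDataset` for raw-spectrum centers.
    """
    if isinstance(features, Embedding):
        V = features.values
    elif isinstance(features, MSIDataset):
        V = features.intensities
    else:
        V = np.asarray(features)
    labels = seg.labels
    regions = np.unique(labels)
    if regions.size < 2:
        raise ValueError("need at least 2 regions for a similarity network")
    centers = np.stack([V[labels == r].mean(axis=0) for r in regions])
    distances = squareform(pdist(centers))
    return MetabotypeNetwork(regions, centers, distances)


@dataclass
class Metrics:
    """Agreement between a predicted segmentation and ground truth."""

    ari: float
    n_labels: int
    precision: dict[int, float]  # per true region, under optimal matching
    recall: dict[int, float]


def evaluate_ari(pred: SegmentationMap, truth: GroundTruth) -> Metrics:
    """Adjusted Rand index plus per-region precision/recall.

    Predicted labels are matched to true regions by maximizing overlap
    (Hungarian assignment on the contingency table); ARI itself is
    label-permutation invariant.
    """
    nr, nc = truth.labels.shape
    if pred.labels.size and (
        pred.pixel_index[:, 0].max() >= nr or pred.pixel_index[:, 1].max() >= nc
    ):
        raise ValueError("prediction and truth cover different spot sets")
    true_labels = truth.spot_labels(pred.pixel_index)
    if true_labels.shape != pred.labels.shape:
        raise ValueError("prediction and truth cover different spot sets")
    ari = float(adjusted_rand_score(true_labels, pred.labels))
    t_vals = np.unique(true_labels)
    p_vals = np.unique(pred.labels)
    cont = np.zeros((t_vals.size, p_vals.size), dtype=np.int64)
    for i, t in enumerate(t_vals):
        for j, p in enumerate(p_vals):
            cont[i, j] = np.sum((true_labels == t) & (pred.labels == p))
    rows, cols = linear_sum_assignment(-cont)
    precision, recall = {}, {}
    for i, j in zip(rows, cols):
        t = int(t_vals[i])
        tp = cont[i, j]
        precision[t] = float(tp / max(cont[:, j].sum(), 1))
        recall[t] = float(tp / max(cont[i, :].sum(), 1))
    for t in t_vals:  # true regions left unmatched score zero
        precision.setdefault(int(t), 0.0)
        recall.setdefault(int(t), 0.0)
    return Metrics(ari, int(p_vals.size), precision, recall)
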