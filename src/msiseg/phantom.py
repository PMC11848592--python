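"""Synthetic MSI phantoms with known region structure.

A phantom emulates a tissue section imaged by MSI: an ``X x Y`` grid of
spectra partitioned into K spatial regions, each region over-expressing a
dedicated set of ions by a multiplicative fold change over a shared
per-ion baseline.  Intensities carry multiplicative log-normal spot noise
with a chosen coefficient of variation; series of adjacent slices add a
per-slice, per-ion log-normal batch factor, emulating the systematic
between-slice intensity shifts that confound 3D MSI.

The generator is the test bed for the whole pipeline: every region label
is known, so segmentation accuracy, scribble rescue and cross-slice
transfer can all be scored against ground truth.

The "subtle split" mode addresses a specific failure mode of unsupervised
segmentation: two sub-regions that differ only in a few weakly enriched
ions are, by design, hard to separate without supervision and serve as
the scenario in which scribble-based refinement must recover the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np

from .core import MSIDataset

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "AdjacentSlices",
    "generate_phantom",
    "generate_adjacent_slices",
    "generate_scribble",
    "UNLABELED",
]

UNLABELED = 0  # sentinel in scribble masks


@dataclass
class PhantomSpec:
    """Parameters of a synthetic MSI phantom.

    ``fold_change`` is the multiplicative enrichment of a region's marker
    ions over baseline; ``spot_noise_cv`` the coefficient of variation of
    the mean-one log-normal spot noise; ``batch_log_sd`` the log-scale sd
    of the per-slice per-ion batch factor used by adjacent-slice series.
    With ``subtle_split`` the last region is halved and the second half
    additionally expresses ``subtle_ions`` reserved ions at the small
    ``subtle_fold`` — a broad-but-modest signature, small enough that
    unsupervised training merges the halves.
    """

    grid_shape: tuple[int, int] = (40, 40)
    n_regions: int = 5
    region_geometry: str = "voronoi"  # concentric | voronoi | stripes
    n_ions: int = 60
    enriched_per_region: int = 5
    fold_change: float = 5.0
    spot_noise_cv: float = 0.1
    batch_log_sd: float = 0.0
    seed: int = 0
    baseline_log_sd: float = 0.3
    subtle_split: bool = False
    subtle_fold: float = 1.3
    subtle_ions: int = 6

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.region_geometry not in ("concentric", "voronoi", "stripes"):
            raise ValueError(f"unknown geometry {self.region_geometry!r}")
        if self.subtle_split and self.subtle_ions < 1:
            raise ValueError("subtle_ions must be >= 1")
        reserved = self.subtle_ions if self.subtle_split else 0
        if self.enriched_per_region * self.n_regions + reserved > self.n_ions:
            raise ValueError("enriched_per_region x n_regions exceeds n_ions")
        if self.fold_change <= 1:
            raise ValueError("fold_change must exceed 1")
        for name in ("spot_noise_cv", "batch_log_sd", "baseline_log_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        nr, nc = self.grid_shape
        if nr * nc < self.n_regions:
            raise ValueError("grid too small for the requested regions")


@dataclass
class GroundTruth:
    """True region label per grid cell, 1..K (no background in phantoms)."""

    labels: np.ndarray  # (n_rows, n_cols) int
    region_names: list[str]

    @property
    def n_regions(self) -> int:
        return len(self.region_names)

    def spot_labels(self, pixel_index: np.ndarray) -> np.ndarray:
        """Labels in spot order for a dataset on the same grid."""
        return self.labels[pixel_index[:, 0], pixel_index[:, 1]]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _region_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    nr, nc = spec.grid_shape
    K = spec.n_regions
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    if spec.region_geometry == "stripes":
        edges = np.linspace(0, nc, K + 1)
        return np.digitize(cols, edges[1:-1]) + 1
    if spec.region_geometry == "concentric":
        d = np.hypot(rows - (nr - 1) / 2, cols - (nc - 1) / 2)
        # equal-area rings via distance quantiles
        qs = np.quantile(d.ravel(), np.linspace(0, 1, K + 1)[1:-1])
        return np.digitize(d, qs) + 1
    # voronoi: nearest of K seed cells; resample until all regions non-empty
    for _ in range(100):
        seeds = np.stack(
            [rng.integers(0, nr, size=K), rng.integers(0, nc, size=K)], axis=1
        )
        d2 = (rows[..., None] - seeds[:, 0]) ** 2 + (cols[..., None] - seeds[:, 1]) ** 2
        lab = np.argmin(d2, axis=-1) + 1
        if np.unique(lab).size == K:
            return lab
    raise RuntimeError("failed to draw a Voronoi layout with all regions present")


def _split_last_region(labels: np.ndarray) -> np.ndarray:
    """Halve the highest-numbered region along its wider axis."""
    K = labels.max()
    rr, cc = np.nonzero(labels == K)
    if rr.size < 2:
        raise ValueError("region too small to split")
    axis = rr if rr.max() - rr.min() >= cc.max() - cc.min() else cc
    cut = np.median(axis)
    half = axis > cut
    if not half.any() or half.all():  # degenerate median; split by rank
        half = np.argsort(np.argsort(axis, kind="stable")) >= axis.size // 2
    out = labels.copy()
    out[rr[half], cc[half]] = K + 1
    return out


# ---------------------------------------------------------------------------
# intensity model
# ---------------------------------------------------------------------------

def _mean_one_lognormal(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with E[x] = 1 and sd/mean = cv."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def _enrichment_matrix(spec: PhantomSpec) -> tuple[np.ndarray, int]:
    """(n_labels, n_ions) fold-change matrix and the number of labels."""
    K = spec.n_regions
    e = spec.enriched_per_region
    n_labels = K + 1 if spec.subtle_split else K
    fold = np.ones((n_labels + 1, spec.n_ions))  # row 0 unused; rows 1..n_labels
    for r in range(1, K + 1):
        fold[r, (r - 1) * e : r * e] = spec.fold_change
    if spec.subtle_split:
        # the split half shares region K's markers plus a few weakly
        # enriched ions -- the broad-but-modest signature real sub-organs show
        fold[K + 1] = fold[K]
        fold[K + 1, spec.n_ions - spec.subtle_ions :] = spec.subtle_fold
    return fold, n_labels


def _intensities(
    spec: PhantomSpec,
    labels: np.ndarray,
    baseline: np.ndarray,
    rng: np.random.Generator,
    batch_factor: Optional[np.ndarray] = None,
) -> np.ndarray:
    fold, _ = _enrichment_matrix(spec)
    flat_labels = labels.ravel()
    signal = baseline[None, :] * fold[flat_labels]
    if batch_factor is not None:
        signal = signal * batch_factor[None, :]
    noise = _mean_one_lognormal(rng, spec.spot_noise_cv, signal.shape)
    return signal * noise


def _dataset(spec: PhantomSpec, intensities: np.ndarray, slice_id=None) -> MSIDataset:
    nr, nc = spec.grid_shape
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    pixel_index = np.stack([rows.ravel(), cols.ravel()], axis=1)
    mz = 100.0 + 10.0 * np.arange(spec.n_ions)  # synthetic m/z axis, Da
    return MSIDataset(intensities, mz, spec.grid_shape, pixel_index,
                      slice_id=slice_id)


def _region_names(n_labels: int, subtle: bool) -> list[str]:
    names = [f"region_{i}" for i in range(1, n_labels + 1)]
    if subtle:
        names[-2] = f"region_{n_labels - 1}a"
        names[-1] = f"region_{n_labels - 1}b"
    return names


def generate_phantom(spec: PhantomSpec) -> tuple[MSIDataset, GroundTruth]:
    """Generate one phantom slice with its ground-truth label map.

    Deterministic given ``spec.seed``.  Within a region, each enriched
    ion's expected intensity is ``fold_change`` times its baseline.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _region_labels(spec, rng)
    if spec.subtle_split:
        labels = _split_last_region(labels)
    baseline = np.exp(rng.normal(0.0, spec.baseline_log_sd, size=spec.n_ions))
    intens = _intensities(spec, labels, baseline, rng)
    truth = GroundTruth(labels, _region_names(labels.max(), spec.subtle_split))
    return _dataset(spec, intens, slice_id="slice_0"), truth


# ---------------------------------------------------------------------------
# adjacent slices
# ---------------------------------------------------------------------------

@dataclass
class AdjacentSlices:
    """A z-series of phantom slices with per-slice batch factors.

    ``batch_factors[t]`` holds the multiplicative per-ion factor applied
    to slice ``t`` (slice 0 has unit factors); kept for tests that verify
    the injected batch effect.
    """

    slices: list[tuple[MSIDataset, GroundTruth]]
    batch_factors: np.ndarray  # (n_slices, n_ions)

    def __iter__(self) -> Iterator[tuple[MSIDataset, GroundTruth]]:
        return iter(self.slices)

    def __getitem__(self, i):
        return self.slices[i]

    def __len__(self) -> int:
        return len(self.slices)


def _morph_labels(labels: np.ndarray, morph_rate: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Flip ``morph_rate`` of boundary cells to a differing 4-neighbor label."""
    if morph_rate == 0:
        return labels.copy()
    nr, nc = labels.shape
    boundary = np.zeros_like(labels, dtype=bool)
    boundary[:-1] |= labels[:-1] != labels[1:]
    boundary[1:] |= labels[1:] != labels[:-1]
    boundary[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    boundary[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    rr, cc = np.nonzero(boundary)
    n_flip = int(round(morph_rate * rr.size))
    if n_flip == 0:
        return labels.copy()
    pick = rng.choice(rr.size, size=n_flip, replace=False)
    out = labels.copy()
    for i in pick:
        r, c = rr[i], cc[i]
        neigh = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < nr and 0 <= c2 < nc and labels[r2, c2] != labels[r, c]:
                neigh.append(labels[r2, c2])
        if neigh:
            out[r, c] = neigh[rng.integers(len(neigh))]
    return out


def generate_adjacent_slices(
    spec: PhantomSpec, n_slices: int, morph_rate: float
) -> AdjacentSlices:
    """Generate a series of adjacent slices with batch effects.

    Slice t+1 inherits slice t's geometry with ``morph_rate`` of its
    boundary cells flipped to a neighboring label, and draws fresh
    per-ion batch factors ``exp(N(0, batch_log_sd))`` plus fresh spot
    noise.  Slice 0 carries unit batch factors so that the series is an
    extension of :func:`generate_phantom` output.
    """
    if n_slices < 2:
        raise ValueError("n_slices must be >= 2")
    if not 0.0 <= morph_rate <= 0.2:
        raise ValueError("morph_rate must lie in [0, 0.2]")
    rng = np.random.default_rng(spec.seed)
    labels = _region_labels(spec, rng)
    if spec.subtle_split:
        labels = _split_last_region(labels)
    baseline = np.exp(rng.normal(0.0, spec.baseline_log_sd, size=spec.n_ions))
    n_labels = labels.max()
    slices: list[tuple[MSIDataset, GroundTruth]] = []
    factors = np.ones((n_slices, spec.n_ions))
    for t in range(n_slices):
        if t > 0:
            labels = _morph_labels(labels, morph_rate, rng)
            factors[t] = np.exp(rng.normal(0.0, spec.batch_log_sd, size=spec.n_ions))
        intens = _intensities(spec, labels, baseline, rng, batch_factor=factors[t])
        truth = GroundTruth(labels.copy(), _region_names(n_labels, spec.subtle_split))
        slices.append((_dataset(spec, intens, slice_id=f"slice_{t}"), truth))
    return AdjacentSlices(slices, factors)


# ---------------------------------------------------------------------------
# scribbles
# ---------------------------------------------------------------------------

def generate_scribble(
    truth: GroundTruth,
    regions: Sequence[int],
    coverage: float,
    seed: int = 0,
) -> np.ndarray:
    """Draw a connected scribble inside each requested region.

    Emulates a user annotating a few pixels of known regions: for each
    region id a connected set of cells covering ~``coverage`` of the
    region is labeled with that id; everything else carries the unlabeled
    sentinel 0.  If a region is spatially disconnected the walk restarts
    in an unvisited component, so the scribble may then split.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = np.full(truth.labels.shape, UNLABELED, dtype=np.int64)
    nr, nc = truth.labels.shape
    for region in regions:
        cells = np.argwhere(truth.labels == region)
        if cells.size == 0:
            raise ValueError(f"region {region} absent from ground truth")
        target = max(1, int(round(coverage * len(cells))))
        in_region = {(r, c) for r, c in cells}
        visited: set[tuple[int, int]] = set()
        frontier: list[tuple[int, int]] = []
        while len(visited) < target:
            if not frontier:
                remaining = [rc for rc in map(tuple, cells) if rc not in visited]
                frontier.append(remaining[rng.integers(len(remaining))])
            r, c = frontier.pop(rng.integers(len(frontier)))
            if (r, c) in visited:
                continue
            visited.add((r, c))
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                nxt = (r + dr, c + dc)
                if nxt in in_region and nxt not in visited:
                    frontier.append(nxt)
        for r, c in visited:
            mask[r, c] = region
    return mask
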