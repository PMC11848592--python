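"""Data model and I/O for mass spectrometry imaging (MSI) matrices.

An MSI experiment measures a full mass spectrum at each pixel of a tissue
section.  After vendor-side peak picking and alignment the data reduce to a
``spots x ions`` intensity matrix with a shared m/z axis and integer pixel
coordinates on an ``X x Y`` grid.  This module provides the in-memory
container for that matrix, readers for centroided imzML and for a plain
CSV matrix dialect, and minimal spectrum-level preprocessing (TIC
normalization and occurrence-based peak filtering).

CSV matrix dialect
------------------
A header row ``row,col,<mz_1>,...,<mz_Z>`` followed by one line per spot.
``row``/``col`` are 0-based grid coordinates; the remaining columns are
intensities for the m/z value given in the header.  Spots are stored in
row-major order.
"""

from __future__ import annotations

import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "MSIDataset",
    "PreprocessConfig",
    "load_dataset",
    "save_matrix_csv",
    "tic_normalize",
    "filter_peaks",
    "write_labels_csv",
    "read_labels_csv",
    "write_labels_png",
]


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class MSIDataset:
    """A preprocessed MSI matrix on a pixel grid.

    Attributes
    ----------
    intensities : ndarray of shape (n_spots, n_ions)
        Non-negative peak intensities, arbitrary units.
    mz : ndarray of shape (n_ions,)
        Strictly increasing m/z axis in Da.
    grid_shape : tuple (n_rows, n_cols)
        Size of the pixel lattice.
    pixel_index : ndarray of shape (n_spots, 2)
        0-based (row, col) coordinate of each spot, row-major ordered.
    tissue_mask : ndarray (n_rows, n_cols) of bool, optional
        True for on-tissue cells.  When present, spots exist exactly for
        the True cells; off-tissue cells carry no spectrum.
    slice_id : str, optional
        Free-form tag identifying the tissue slice (used in 3D series).
    """

    intensities: np.ndarray
    mz: np.ndarray
    grid_shape: tuple[int, int]
    pixel_index: np.ndarray
    tissue_mask: Optional[np.ndarray] = None
    slice_id: Optional[str] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.int64)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D spots x ions matrix")
        n_spots, n_ions = self.intensities.shape
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if n_spots and self.intensities.min() < 0:
            raise ValueError("intensities must be non-negative")
        if self.mz.shape != (n_ions,):
            raise ValueError("m/z axis length must equal the ion dimension")
        if n_ions > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError("m/z axis must be strictly increasing")
        if self.pixel_index.shape != (n_spots, 2):
            raise ValueError("pixel_index must be (n_spots, 2)")
        nr, nc = self.grid_shape
        if nr <= 0 or nc <= 0:
            raise ValueError("grid_shape entries must be positive")
        if n_spots:
            r, c = self.pixel_index[:, 0], self.pixel_index[:, 1]
            if r.min() < 0 or c.min() < 0 or r.max() >= nr or c.max() >= nc:
                raise ValueError("pixel coordinates out of grid bounds")
            flat = r * nc + c
            if np.unique(flat).size != n_spots:
                raise ValueError("pixel coordinates must be unique")
        if self.tissue_mask is not None:
            self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)
            if self.tissue_mask.shape != (nr, nc):
                raise ValueError("tissue_mask shape must equal grid_shape")
            if int(self.tissue_mask.sum()) != n_spots:
                raise ValueError(
                    "number of spots must equal number of on-tissue cells"
                )
            if n_spots and not self.tissue_mask[
                self.pixel_index[:, 0], self.pixel_index[:, 1]
            ].all():
                raise ValueError("every spot must lie on an on-tissue cell")
        elif n_spots != nr * nc:
            raise ValueError("without a tissue mask every grid cell needs a spot")

    # -- convenience -------------------------------------------------------

    @property
    def n_spots(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_ions(self) -> int:
        return self.intensities.shape[1]

    def spot_grid_index(self) -> np.ndarray:
        """(n_rows, n_cols) int grid mapping cells to spot row, -1 off-tissue."""
        idx = np.full(self.grid_shape, -1, dtype=np.int64)
        idx[self.pixel_index[:, 0], self.pixel_index[:, 1]] = np.arange(self.n_spots)
        return idx

    def to_grid(self, values: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-spot vector onto the pixel grid."""
        values = np.asarray(values)
        out = np.full(self.grid_shape, fill, dtype=np.result_type(values, type(fill)))
        out[self.pixel_index[:, 0], self.pixel_index[:, 1]] = values
        return out


@dataclass
class PreprocessConfig:
    """Spectrum-level preprocessing switches.

    ``min_nonzero_fraction`` drops ions observed (strictly above
    ``intensity_floor``) in fewer than that fraction of spots — a simple
    occurrence filter for noise peaks surviving upstream peak picking.
    """

    tic_normalize: bool = True
    log_transform: bool = False
    min_nonzero_fraction: float = 0.0
    intensity_floor: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_nonzero_fraction <= 1.0:
            raise ValueError("min_nonzero_fraction must lie in [0, 1]")
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be non-negative")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _row_major_order(pixel_index: np.ndarray, n_cols: int) -> np.ndarray:
    return np.argsort(pixel_index[:, 0] * n_cols + pixel_index[:, 1], kind="stable")


def load_dataset(path, format: Optional[str] = None, slice_id: Optional[str] = None) -> MSIDataset:
    """Load an MSI dataset from imzML or from the matrix CSV dialect.

    ``format`` is ``"imzml"`` or ``"matrix_csv"``; when omitted it is
    inferred from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "imzml" if path.suffix.lower() == ".imzml" else "matrix_csv"
    if format == "imzml":
        return _load_imzml(path, slice_id=slice_id)
    if format == "matrix_csv":
        return _load_matrix_csv(path, slice_id=slice_id)
    raise ValueError(f"unknown format {format!r}")


def _load_matrix_csv(path: Path, slice_id=None) -> MSIDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "row" or cols[1] != "col":
        raise FormatError(
            f"{path}: expected header 'row,col,<mz...>', got {cols[:3]}..."
        )
    try:
        mz = np.array([float(c) for c in cols[2:]])
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric m/z column header: {exc}") from exc
    if mz.size > 1 and not np.all(np.diff(mz) > 0):
        raise FormatError(f"{path}: m/z header must be strictly increasing")
    pixel_index = df[["row", "col"]].to_numpy(dtype=np.int64)
    intensities = df[cols[2:]].to_numpy(dtype=np.float64)
    order = _row_major_order(pixel_index, int(pixel_index[:, 1].max()) + 1 if len(df) else 1)
    pixel_index = pixel_index[order]
    intensities = intensities[order]
    nr = int(pixel_index[:, 0].max()) + 1
    nc = int(pixel_index[:, 1].max()) + 1
    mask = np.zeros((nr, nc), dtype=bool)
    mask[pixel_index[:, 0], pixel_index[:, 1]] = True
    if mask.all():
        mask = None
    return MSIDataset(intensities, mz, (nr, nc), pixel_index, tissue_mask=mask,
                      slice_id=slice_id)


def save_matrix_csv(ds: MSIDataset, path) -> None:
    """Write a dataset in the matrix CSV dialect (lossless round-trip)."""
    path = Path(path)
    header = ["row", "col"] + [repr(float(v)) for v in ds.mz]
    # Python float repr is shortest-round-trip exact, so intensities and
    # the m/z axis survive write->read bit-exactly
    with open(path, "w") as fh:
        fh.write(",".join(header) + "\n")
        for i in range(ds.n_spots):
            vals = ",".join(repr(float(v)) for v in ds.intensities[i])
            fh.write(f"{ds.pixel_index[i, 0]},{ds.pixel_index[i, 1]},{vals}\n")


_IMS_CONTINUOUS = "IMS:1000030"
_IMS_PROCESSED = "IMS:1000031"


def _imzml_mode(path: Path) -> str:
    """Return 'continuous' or 'processed' from the imzML fileContent block."""
    for _, elem in ET.iterparse(str(path)):
        tag = elem.tag.rsplit("}", 1)[-1]
        if tag == "fileDescription":
            for cv in elem.iter():
                acc = cv.get("accession")
                if acc == _IMS_CONTINUOUS:
                    return "continuous"
                if acc == _IMS_PROCESSED:
                    return "processed"
            break
    raise FormatError(f"{path}: could not determine imzML binary mode")


def _load_imzml(path: Path, slice_id=None) -> MSIDataset:
    from pyimzml.ImzMLParser import ImzMLParser

    mode = _imzml_mode(path)
    if mode == "continuous":
        raise FormatError(
            f"{path}: continuous-mode (profile) imzML is not supported; "
            "provide centroided, peak-aligned data"
        )
    parser = ImzMLParser(str(path))
    coords = np.asarray(parser.coordinates, dtype=np.int64)
    n = len(coords)
    if n == 0:
        raise FormatError(f"{path}: no spectra")
    mz0, ints0 = parser.getspectrum(0)
    mz0 = np.asarray(mz0, dtype=np.float64)
    intensities = np.empty((n, mz0.size), dtype=np.float64)
    intensities[0] = ints0
    for i in range(1, n):
        mz_i, ints_i = parser.getspectrum(i)
        if len(mz_i) != mz0.size or not np.allclose(mz_i, mz0, rtol=0, atol=1e-6):
            raise FormatError(
                f"{path}: spectrum {i} has a different m/z axis; "
                "peak alignment to a common axis is required"
            )
        intensities[i] = ints_i
    # imzML coordinates are 1-based with x = column, y = row
    pixel_index = np.stack([coords[:, 1] - 1, coords[:, 0] - 1], axis=1)
    order = _row_major_order(pixel_index, int(pixel_index[:, 1].max()) + 1)
    pixel_index = pixel_index[order]
    intensities = intensities[order]
    nr = int(pixel_index[:, 0].max()) + 1
    nc = int(pixel_index[:, 1].max()) + 1
    mask = np.zeros((nr, nc), dtype=bool)
    mask[pixel_index[:, 0], pixel_index[:, 1]] = True
    if mask.all():
        mask = None
    return MSIDataset(intensities, mz0, (nr, nc), pixel_index, tissue_mask=mask,
                      slice_id=slice_id)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def tic_normalize(ds: MSIDataset) -> MSIDataset:
    """Scale each spectrum to unit total ion current (TIC).

    Spots with zero TIC are left untouched and reported with a warning;
    the operation is idempotent on already-normalized data in the sense
    that re-normalizing changes nothing.
    """
    tic = ds.intensities.sum(axis=1)
    if ds.n_spots and not np.any(tic > 0):
        raise ValueError("no spot has positive total ion current")
    zero = tic == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} spot(s) have zero TIC and were left at zero")
    scale = np.where(zero, 1.0, tic)
    out = ds.intensities / scale[:, None]
    return replace(ds, intensities=out)


def filter_peaks(ds: MSIDataset, cfg: PreprocessConfig) -> MSIDataset:
    """Drop ions observed in fewer than ``min_nonzero_fraction`` of spots.

    An ion counts as observed in a spot when its intensity is strictly
    above ``cfg.intensity_floor``.  Retained ions keep their order.
    """
    observed = (ds.intensities > cfg.intensity_floor).mean(axis=0)
    keep = observed >= cfg.min_nonzero_fraction
    if not keep.any():
        raise ValueError(
            "all ions filtered out; lower min_nonzero_fraction or intensity_floor"
        )
    if keep.all():
        return ds
    return replace(ds, intensities=ds.intensities[:, keep], mz=ds.mz[keep])


def preprocess(ds: MSIDataset, cfg: PreprocessConfig) -> MSIDataset:
    """Apply the configured preprocessing steps in a fixed order."""
    if cfg.min_nonzero_fraction > 0 or cfg.intensity_floor > 0:
        ds = filter_peaks(ds, cfg)
    if cfg.tic_normalize:
        ds = tic_normalize(ds)
    if cfg.log_transform:
        ds = replace(ds, intensities=np.log1p(ds.intensities))
    return ds


# ---------------------------------------------------------------------------
# label maps
# ---------------------------------------------------------------------------

def write_labels_csv(labels: np.ndarray, pixel_index: np.ndarray, path) -> None:
    """Write per-spot integer labels as a row,col,label CSV."""
    df = pd.DataFrame(
        {"row": pixel_index[:, 0], "col": pixel_index[:, 1], "label": labels}
    )
    df.to_csv(path, index=False)


def read_labels_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a row,col,label CSV; returns (labels, pixel_index)."""
    df = pd.read_csv(path)
    return (
        df["label"].to_numpy(dtype=np.int64),
        df[["row", "col"]].to_numpy(dtype=np.int64),
    )


# a categorical palette (tab20-like) for label images; 0 = background/black
_PALETTE = np.array(
    [
        [0, 0, 0], [31, 119, 180], [255, 127, 14], [44, 160, 44], [214, 39, 40],
        [148, 103, 189], [140, 86, 75], [227, 119, 194], [127, 127, 127],
        [188, 189, 34], [23, 190, 207], [174, 199, 232], [255, 187, 120],
        [152, 223, 138], [255, 152, 150], [197, 176, 213], [196, 156, 148],
        [247, 182, 210], [199, 199, 199], [219, 219, 141], [158, 218, 229],
    ],
    dtype=np.uint8,
)


def write_labels_png(labels: np.ndarray, pixel_index: np.ndarray,
                     grid_shape: tuple[int, int], path) -> None:
    """Render a label map to a color PNG (background cells black)."""
    import imageio.v3 as iio

    grid = np.zeros(grid_shape, dtype=np.int64)
    grid[pixel_index[:, 0], pixel_index[:, 1]] = labels
    rgb = _PALETTE[grid % len(_PALETTE)]
    iio.imwrite(Path(path), rgb)
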