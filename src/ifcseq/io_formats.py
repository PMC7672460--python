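"""Readers, writers and in-memory containers for the pipeline's external formats.

The formats follow the conventions of the public datasets the method was
designed around: gene-by-cell UMI count matrices as (optionally gzipped) CSV
with gene names in the first column and cell barcodes in the header row;
per-cell marker-intensity tables as CSV with cells in rows; and per-cell
32x32-pixel 16-bit single-channel brightfield TIFFs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "CountMatrix",
    "MarkerTable",
    "ExpressionMatrix",
    "ImageStack",
    "read_gene_by_cell_csv",
    "write_gene_by_cell_csv",
    "read_marker_csv",
    "write_marker_csv",
    "read_tiff_stack",
    "write_tiff_stack",
    "read_predictions",
    "write_predictions",
]

IMAGE_SHAPE = (32, 32)
MAX_PIXEL = np.uint16(65535)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(ids) != len(set(ids.tolist())):
        seen, dup = set(), None
        for x in ids.tolist():
            if x in seen:
                dup = x
                break
            seen.add(x)
        raise ValueError(f"duplicate {what} id: {dup!r}")


@dataclass
class CountMatrix:
    """Integer UMI counts, genes in rows and cells in columns."""

    values: np.ndarray  # (n_genes, n_cells) non-negative integers
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("count matrix must be 2-D")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.values, 1), 0)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.size and self.values.min() < 0:
            raise ValueError("counts must be non-negative")
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.cell_ids, "cell")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def select_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[idx], self.gene_ids[idx], self.cell_ids)

    def select_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(self.values[:, idx], self.gene_ids, self.cell_ids[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.cell_ids)


@dataclass
class MarkerTable:
    """Continuous surface-marker intensities, cells in rows.

    ``normalized`` marks tables that went through per-column min-max scaling;
    ``norm_bounds`` then stores each marker's original (min, max) so the
    mapping can be inverted or reapplied to new data.
    """

    values: np.ndarray  # (n_cells, n_markers) float
    cell_ids: np.ndarray
    marker_names: np.ndarray
    normalized: bool = False
    norm_bounds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.marker_names = np.asarray(self.marker_names, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("marker table must be 2-D")
        if self.values.shape != (len(self.cell_ids), len(self.marker_names)):
            raise ValueError("marker table shape inconsistent with id lists")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.marker_names, "marker")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def column(self, marker: str) -> np.ndarray:
        idx = np.flatnonzero(self.marker_names == marker)
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in table")
        return self.values[:, idx[0]]

    def select_cells(self, mask_or_idx) -> "MarkerTable":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return MarkerTable(
            self.values[idx],
            self.cell_ids[idx],
            self.marker_names,
            self.normalized,
            dict(self.norm_bounds),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.marker_names)


@dataclass
class ExpressionMatrix:
    """Real-valued expression (cells x targets), typically ln(1+x) scale.

    Targets are genes, optionally extended with surface-protein channels
    (e.g. CD4) that are predicted alongside gene expression.
    """

    values: np.ndarray  # (n_cells, n_targets) float
    cell_ids: np.ndarray
    target_names: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.target_names = np.asarray(self.target_names, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D")
        if self.values.shape != (len(self.cell_ids), len(self.target_names)):
            raise ValueError("expression matrix shape inconsistent with id lists")
        _check_unique(self.cell_ids, "cell")
        _check_unique(self.target_names, "target")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def subset_targets(self, names) -> "ExpressionMatrix":
        names = list(names)
        pos = {t: i for i, t in enumerate(self.target_names.tolist())}
        missing = [t for t in names if t not in pos]
        if missing:
            raise KeyError(f"targets not present: {missing[:5]}")
        idx = np.array([pos[t] for t in names])
        return ExpressionMatrix(self.values[:, idx], self.cell_ids, np.array(names, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.target_names)


@dataclass
class ImageStack:
    """n x 32 x 32 single-channel 16-bit brightfield images with cell ids."""

    pixels: np.ndarray  # (n, 32, 32) uint16
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.pixels.ndim != 3 or self.pixels.shape[1:] != IMAGE_SHAPE:
            raise ValueError(f"image stack must be n x {IMAGE_SHAPE[0]} x {IMAGE_SHAPE[1]}")
        if self.pixels.shape[0] != len(self.cell_ids):
            raise ValueError("number of images != number of cell ids")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValueError("pixels must be integers")
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > int(MAX_PIXEL)):
            raise ValueError("pixel values must lie in [0, 65535]")
        self.pixels = self.pixels.astype(np.uint16)
        _check_unique(self.cell_ids, "cell")

    @property
    def n_images(self) -> int:
        return self.pixels.shape[0]


# ---------------------------------------------------------------------------
# CSV count matrices (GEO supplementary-file dialect)
# ---------------------------------------------------------------------------

def read_gene_by_cell_csv(path, transpose: bool = False) -> CountMatrix:
    """Read a gene-by-cell count CSV (first column gene names, header barcodes).

    Gzip is handled transparently from the ``.gz`` suffix. ``transpose=True``
    reads files stored cell-by-gene; gene/cell roles in the returned
    :class:`CountMatrix` are preserved either way.
    """
    df = pd.read_csv(path, index_col=0)
    if transpose:
        df = df.T
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no cells (header only)")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no genes")
    bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
    if len(bad):
        col = bad[0]
        row = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
        raise ValueError(f"{path}: non-numeric count at gene {row!r}, cell {col!r}")
    return CountMatrix(
        df.to_numpy(),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )


def write_gene_by_cell_csv(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path)


# ---------------------------------------------------------------------------
# Marker tables (cells in rows)
# ---------------------------------------------------------------------------

def read_marker_csv(path, normalized: bool = False) -> MarkerTable:
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no cells")
    return MarkerTable(
        df.to_numpy(dtype=float),
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        normalized=normalized,
    )


def write_marker_csv(markers: MarkerTable, path) -> None:
    markers.to_frame().to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# TIFF image stacks
# ---------------------------------------------------------------------------

def read_tiff_stack(paths, cell_ids=None) -> ImageStack:
    """Read single-channel 16-bit 32x32 TIFFs, one per cell, in path order.

    Cell ids default to the file basenames without extension; an explicit
    ``cell_ids`` list overrides (a manifest may supply it).
    """
    paths = list(paths)
    images = []
    for p in paths:
        img = tifffile.imread(p)
        if img.ndim != 2 or img.shape != IMAGE_SHAPE:
            raise ValueError(f"{p}: expected shape {IMAGE_SHAPE}, got {img.shape}")
        if img.dtype != np.uint16:
            raise ValueError(f"{p}: expected 16-bit pixels, got dtype {img.dtype}")
        images.append(img)
    if cell_ids is None:
        cell_ids = [os.path.splitext(os.path.basename(str(p)))[0] for p in paths]
    return ImageStack(np.stack(images) if images else np.zeros((0, *IMAGE_SHAPE), np.uint16),
                      np.asarray(cell_ids, dtype=object))


def write_tiff_stack(stack: ImageStack, directory) -> list:
    """Write one ``<cell_id>.tif`` per image; returns the paths written."""
    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, cid in enumerate(stack.cell_ids.tolist()):
        p = os.path.join(str(directory), f"{cid}.tif")
        tifffile.imwrite(p, stack.pixels[i])
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Prediction matrices (CSV + lossless binary sidecar)
# ---------------------------------------------------------------------------

def _sidecar(path) -> str:
    return str(path) + ".npy"


def write_predictions(pred: ExpressionMatrix, path) -> None:
    """Write predictions as CSV plus a ``.npy`` sidecar for lossless values.

    NaNs are rejected: a prediction that is undefined should be absent, not
    silently propagated downstream.
    """
    if np.isnan(pred.values).any():
        i, j = np.argwhere(np.isnan(pred.values))[0]
        raise ValueError(
            f"NaN prediction for cell {pred.cell_ids[i]!r}, target {pred.target_names[j]!r}"
        )
    pred.to_frame().to_csv(path, float_format="%.17g")
    np.save(_sidecar(path), pred.values)


def read_predictions(path) -> ExpressionMatrix:
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] and len(df.columns) != len(set(df.columns)):
        raise ValueError(f"{path}: mismatched/duplicated header")
    values = df.to_numpy(dtype=float) if df.size else np.zeros(df.shape)
    side = _sidecar(path)
    if os.path.exists(side):
        arr = np.load(side)
        if arr.shape != df.shape:
            raise ValueError(f"{path}: sidecar shape {arr.shape} != CSV shape {df.shape}")
        values = arr
    return ExpressionMatrix(
        values,
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
    )
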