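"""Volume I/O and the dataset-level preprocessing operators.

The preprocessing chain for training Gaussian-visible models mirrors the
standard pipeline for task fMRI: mask voxels whose across-dataset mean is
below the global mean, remove the mean image, then z-score every surviving
voxel.  The full normalization record is kept so the transform can be
inverted and so learned features can be mapped back onto the original grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:
    import nibabel as nib
except ImportError:  # pragma: no cover - nibabel is a hard dependency
    nib = None


@dataclass(frozen=True)
class DataMatrix:
    """Samples x voxels matrix with its mask and normalization record.

    ``values`` holds only in-mask voxels.  ``mean_image`` and ``voxel_sd``
    record the per-voxel statistics removed by :func:`normalize_dataset`
    (both are None before normalization).  ``geometry`` is the original
    volume shape; voxel ordering is C order (x fastest within a row).
    """

    values: np.ndarray                     # (n_samples, n_kept_voxels)
    mask: np.ndarray                       # (n_voxels_original,) bool
    geometry: tuple[int, ...]
    mean_image: np.ndarray | None = None   # (n_kept_voxels,)
    voxel_sd: np.ndarray | None = None     # (n_kept_voxels,)
    constant_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValueError("values column count must equal mask true count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def unmask(self, rows: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel rows (e.g. feature maps) back to the full grid."""
        rows = np.atleast_2d(rows)
        out = np.full((rows.shape[0], self.mask.size), fill)
        out[:, self.mask] = rows
        return out

    def inverse_transform(self, values: np.ndarray | None = None) -> np.ndarray:
        """Undo normalization (z-scoring and mean-image removal)."""
        x = self.values if values is None else values
        if self.voxel_sd is not None:
            x = x * self.voxel_sd
        if self.mean_image is not None:
            x = x + self.mean_image
        return x


def as_data_matrix(raw: np.ndarray, geometry: tuple[int, ...] | None = None) -> DataMatrix:
    """Wrap a raw samples x voxels array with a trivial (all-true) mask."""
    raw = np.asarray(raw, float)
    if geometry is None:
        geometry = (raw.shape[1],)
    return DataMatrix(values=raw, mask=np.ones(raw.shape[1], bool), geometry=geometry)


# ---------------------------------------------------------------------------
# NIfTI I/O


def load_volumes(paths) -> tuple[np.ndarray, tuple[int, ...]]:
    """Load NIfTI volumes into one row per volume.

    ``paths`` is a single 4D file or a sequence of 3D files with identical
    shapes.  Returns ``(matrix, geometry)`` with C-order flattening.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    rows, geometry = [], None
    for path in paths:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 4:
            shape = arr.shape[:3]
            vols = np.moveaxis(arr, 3, 0).reshape(arr.shape[3], -1)
        elif arr.ndim == 3:
            shape = arr.shape
            vols = arr.reshape(1, -1)
        else:
            raise ValueError(f"{path}: expected a 3D or 4D NIfTI volume")
        if geometry is None:
            geometry = shape
        elif shape != geometry:
            raise ValueError(f"{path}: shape {shape} != {geometry}")
        rows.append(vols)
    return np.vstack(rows), geometry


def save_volumes(matrix: np.ndarray, geometry: tuple[int, ...], path) -> None:
    """Write a samples x voxels matrix as a float32 4D NIfTI file."""
    matrix = np.asarray(matrix)
    arr = matrix.reshape(matrix.shape[0], *geometry)
    arr = np.moveaxis(arr, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))


def grid_geometry(grid_side: int) -> tuple[int, int, int]:
    """Volume shape for the simulator's 2D grids (one-slice volumes)."""
    return (grid_side, grid_side, 1)


# ---------------------------------------------------------------------------
# preprocessing operators


def mask_below_mean(raw: np.ndarray, geometry: tuple[int, ...] | None = None) -> DataMatrix:
    """Keep only voxels whose across-samples mean is at or above the global
    mean of all voxel means (ties kept)."""
    raw = np.asarray(raw, float)
    if raw.size == 0:
        raise ValueError("empty data")
    voxel_means = raw.mean(axis=0)
    mask = voxel_means >= voxel_means.mean()
    if geometry is None:
        geometry = (raw.shape[1],)
    return DataMatrix(values=raw[:, mask], mask=mask, geometry=geometry)


def normalize_dataset(masked: DataMatrix) -> DataMatrix:
    """Remove the mean image, then z-score every voxel.

    Constant voxels cannot be scaled; they are set to zero and recorded in
    ``constant_voxels`` (their sd is stored as 1 so the inverse transform
    stays exact).
    """
    if masked.n_samples < 2:
        raise ValueError("need at least 2 samples to normalize")
    x = masked.values
    mean_image = x.mean(axis=0)
    centered = x - mean_image
    sd = centered.std(axis=0)
    constant = sd < 1e-12
    safe_sd = np.where(constant, 1.0, sd)
    values = centered / safe_sd
    values[:, constant] = 0.0
    return DataMatrix(values=values, mask=masked.mask, geometry=masked.geometry,
                      mean_image=mean_image, voxel_sd=safe_sd,
                      constant_voxels=constant)


def preprocess(raw: np.ndarray, geometry: tuple[int, ...] | None = None) -> DataMatrix:
    """The full chain: mask below mean, remove mean image, z-score."""
    return normalize_dataset(mask_below_mean(raw, geometry))


# ---------------------------------------------------------------------------
# model archives


def save_archive(path, arrays: dict, meta: dict) -> None:
    """Single-file .npz archive with a plain-text JSON sidecar."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **arrays)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))


def load_archive(path) -> tuple[dict, dict]:
    path = Path(path)
    with np.load(path.with_suffix(".npz")) as npz:
        arrays = {k: npz[k] for k in npz.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    return arrays, meta
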