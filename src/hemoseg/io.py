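"""Reading, masking and reshaping of 4D DSC-MRI perfusion series.

A perfusion series is a 4D stack of T2*-weighted echo-planar images acquired
while a gadolinium bolus transits the brain.  The analysis pipeline works on
an ``M x N`` matrix whose columns are the voxel time courses inside a brain
mask; this module owns the conversion between the two representations and the
NIfTI round trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


@dataclass
class PerfusionSeries:
    """4D signal-intensity series indexed ``(time, x, y, z)``.

    Parameters
    ----------
    signal : ndarray
        Nonnegative intensities, shape ``(n_frames, nx, ny, nz)``.
    tr_seconds : float
        Sampling interval between frames (the TR of the dynamic scan).
    te_seconds : float
        Echo time; enters the signal-to-concentration conversion.
    """

    signal: np.ndarray
    tr_seconds: float
    te_seconds: float

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("not a time series: expected 4D (time, x, y, z) data")
        if self.n_frames < 2:
            raise ValueError("not a time series: fewer than 2 time frames")
        if not (self.tr_seconds > 0 and self.te_seconds > 0):
            raise ValueError("tr_seconds and te_seconds must be positive")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("non-finite voxel intensities")
        if np.any(self.signal < 0):
            raise ValueError("negative voxel intensities")

    @property
    def n_frames(self) -> int:
        return self.signal.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.signal.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.tr_seconds


@dataclass
class BrainMask:
    """Boolean brain mask on the spatial grid of a series."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if self.n_voxels < 1:
            raise ValueError("empty brain mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class DataMatrix:
    """``M x N`` observation matrix; column ``n`` is the time course of voxel ``n``.

    ``voxel_index`` maps columns back to grid coordinates so that labels and
    parameter maps computed on columns can be scattered into volumes.
    """

    values: np.ndarray
    voxel_index: np.ndarray = field(default=None)  # (N, 3) int coords, or None
    spatial_shape: tuple[int, int, int] | None = None
    tr_seconds: float = 1.0
    te_seconds: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DataMatrix values must be 2D (time x voxels)")
        if self.voxel_index is not None:
            self.voxel_index = np.asarray(self.voxel_index, dtype=int)
            if self.voxel_index.shape != (self.n_voxels, 3):
                raise ValueError("voxel_index must be (N, 3)")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]

    def scatter(self, column_values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter one value per column into a 3D volume (inverse of masking)."""
        if self.voxel_index is None or self.spatial_shape is None:
            raise ValueError("matrix has no voxel geometry attached")
        column_values = np.asarray(column_values)
        out = np.full(self.spatial_shape, fill, dtype=column_values.dtype)
        i, j, k = self.voxel_index.T
        out[i, j, k] = column_values
        return out


def load_series(path, tr_seconds: float | None = None,
                te_seconds: float | None = None) -> PerfusionSeries:
    """Load a 4D NIfTI perfusion series.

    TR/TE are taken from the arguments if given, otherwise from a JSON sidecar
    ``<stem>.json`` with keys ``tr_seconds``/``te_seconds``, otherwise TR from
    the NIfTI header pixdim if present.  A missing TE (or TR) raises.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim < 4:
        raise ValueError(f"not a time series: {path} has {data.ndim} dimensions")
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if tr_seconds is None:
        tr_seconds = meta.get("tr_seconds")
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        if len(zooms) >= 4 and zooms[3] > 0:
            tr_seconds = float(zooms[3])
    if te_seconds is None:
        te_seconds = meta.get("te_seconds")
    if tr_seconds is None:
        raise ValueError("TR not found: pass tr_seconds or provide the "
                         "'tr_seconds' field in the JSON sidecar")
    if te_seconds is None:
        raise ValueError("TE not found: pass te_seconds or provide the "
                         "'te_seconds' field in the JSON sidecar")
    # NIfTI stores (x, y, z, t); analysis code indexes (t, x, y, z)
    signal = np.moveaxis(data.astype(float), 3, 0)
    return PerfusionSeries(signal, float(tr_seconds), float(te_seconds))


def save_series(series: PerfusionSeries, path) -> None:
    """Write a series as 4D NIfTI plus a timing JSON sidecar."""
    path = Path(path)
    data = np.moveaxis(series.signal, 0, 3)
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_seconds))
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps(
        {"tr_seconds": series.tr_seconds, "te_seconds": series.te_seconds}))


def save_volume(volume: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume), np.eye(4)), str(path))


def load_volume(path) -> np.ndarray:
    return np.asanyarray(nib.load(str(path)).dataobj)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu threshold: maximizes between-class variance on an ``nbins`` histogram."""
    values = np.asarray(values, dtype=float).ravel()
    if np.unique(values).size < 2:
        raise ValueError("degenerate histogram: constant input")
    return float(threshold_otsu(values, nbins=nbins))


def extract_brain_mask(series: PerfusionSeries, erosion_radius: int = 2,
                       dilation_radius: int = 2,
                       keep_largest_component: bool = False) -> BrainMask:
    """Extract the brain region from the temporal-mean image, slice by slice.

    Each axial slice of the temporal mean is Otsu-thresholded; the
    supra-threshold mask is then binary-eroded and dilated with disk
    structuring elements of the given radii, which removes small bright
    speckles outside the head.  Optionally only the largest connected
    component per slice is kept.
    """
    mean_img = series.signal.mean(axis=0)
    mask = np.zeros(mean_img.shape, dtype=bool)
    for z in range(mean_img.shape[2]):
        sl = mean_img[:, :, z]
        if np.unique(sl).size < 2:
            continue
        m = sl > otsu_threshold(sl)
        if erosion_radius > 0:
            m = ndimage.binary_erosion(m, structure=_disk(erosion_radius))
        if dilation_radius > 0:
            m = ndimage.binary_dilation(m, structure=_disk(dilation_radius))
        if keep_largest_component and m.any():
            labels = cc_label(m)
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            m = labels == counts.argmax()
        mask[:, :, z] = m
    if not mask.any():
        raise ValueError("empty mask after thresholding/morphology")
    return BrainMask(mask)


def _disk(radius: int) -> np.ndarray:
    xx, yy = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (xx ** 2 + yy ** 2) <= radius ** 2


def to_matrix(series: PerfusionSeries, mask: BrainMask,
              frame_window: tuple[int, int] | None = None) -> DataMatrix:
    """Reshape the masked series into the ``M x N`` analysis matrix.

    ``frame_window`` is a 1-based inclusive ``(first, last)`` frame range.
    By default up to 65 frames are analysed: series longer than 65 frames
    drop their leading pre-bolus frames so that the last 65 are kept, shorter
    series are used in full.
    """
    if mask.mask.shape != series.spatial_shape:
        raise ValueError("mask shape does not match series grid")
    n = series.n_frames
    if frame_window is None:
        first = max(1, n - 65 + 1)
        frame_window = (first, n)
    first, last = frame_window
    if not (1 <= first <= last <= n):
        raise ValueError(f"frame window {frame_window} out of range 1..{n}")
    idx = np.argwhere(mask.mask)
    values = series.signal[first - 1:last, mask.mask]
    return DataMatrix(values=values, voxel_index=idx,
                      spatial_shape=series.spatial_shape,
                      tr_seconds=series.tr_seconds,
                      te_seconds=series.te_seconds)
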