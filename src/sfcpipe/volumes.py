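"""NIfTI I/O and shared voxel-grid utilities.

All volumes in the package live on a regular grid with isotropic voxels;
voxel indices are 0-based and distances are measured between voxel centers
in millimetres.  4D data are indexed ``(x, y, z, t)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeSeries",
    "VolumeMap",
    "read_volume",
    "write_volume",
    "gaussian_smooth",
    "make_gm_mask",
    "FWHM_TO_SIGMA",
]

# FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class VolumeSeries:
    """One subject's 4D resting-state series on a regular voxel grid."""

    data: np.ndarray  # (x, y, z, t)
    voxel_size_mm: float
    tr_seconds: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries requires 4D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("VolumeSeries contains non-finite values")
        if self.voxel_size_mm <= 0 or self.tr_seconds <= 0:
            raise ValueError("voxel_size_mm and tr_seconds must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class VolumeMap:
    """A single 3D map (statistic, probability, SBR ...) on a regular grid."""

    data: np.ndarray  # (x, y, z)
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeMap requires 3D data, got {self.data.ndim}D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


def read_volume(path, tr_seconds: float | None = None):
    """Read a NIfTI-1 file as a :class:`VolumeSeries` (4D) or :class:`VolumeMap` (3D).

    The repetition time for 4D series is taken from the header pixdim unless
    overridden.  Non-finite voxels and dimensionalities other than 3/4 are
    rejected with the offending file named.
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    zooms = img.header.get_zooms()
    voxel_size = float(zooms[0])
    if data.ndim == 3:
        return VolumeMap(data=data, voxel_size_mm=voxel_size)
    if data.ndim == 4:
        tr = tr_seconds if tr_seconds is not None else float(zooms[3]) if len(zooms) > 3 else 0.0
        if tr <= 0:
            raise ValueError(f"{path}: repetition time missing from header; pass tr_seconds")
        return VolumeSeries(data=data, voxel_size_mm=voxel_size, tr_seconds=tr)
    raise ValueError(f"{path}: expected 3D or 4D NIfTI, got {data.ndim}D")


def write_volume(obj, path) -> None:
    """Write a VolumeSeries/VolumeMap as NIfTI-1 (float64, diagonal affine)."""
    path = Path(path)
    affine = np.diag([obj.voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(obj.data, dtype=np.float64), affine)
    if isinstance(obj, VolumeSeries):
        img.header.set_zooms((obj.voxel_size_mm,) * 3 + (obj.tr_seconds,))
    else:
        img.header.set_zooms((obj.voxel_size_mm,) * 3)
    nib.save(img, str(path))


def gaussian_smooth(obj, fwhm_mm: float):
    """Spatial Gaussian smoothing with a kernel given in mm FWHM.

    sigma = fwhm / (2*sqrt(2 ln 2)) per axis, converted to voxel units.
    Series are smoothed per timepoint.  Edges use replicate-nearest
    handling so constant images stay constant.  fwhm 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    if fwhm_mm == 0:
        return obj
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / obj.voxel_size_mm
    if isinstance(obj, VolumeSeries):
        out = ndimage.gaussian_filter(
            obj.data.astype(np.float64), sigma=(sigma_vox,) * 3 + (0.0,), mode="nearest"
        )
        return VolumeSeries(out, obj.voxel_size_mm, obj.tr_seconds)
    out = ndimage.gaussian_filter(obj.data.astype(np.float64), sigma=sigma_vox, mode="nearest")
    return VolumeMap(out, obj.voxel_size_mm)


def make_gm_mask(prob_map: VolumeMap, threshold: float = 0.2) -> np.ndarray:
    """Binary gray-matter mask from a tissue-probability map.

    Inclusion is by strict inequality: a voxel enters the mask only when its
    gray-matter probability exceeds ``threshold`` (default 0.2).
    """
    data = np.asarray(prob_map.data)
    if np.nanmin(data) < 0 or np.nanmax(data) > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return data > threshold
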