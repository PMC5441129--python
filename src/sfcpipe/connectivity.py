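"""Per-subject seed-based functional connectivity.

Implements the standard resting-state chain for a spherical striatal seed:
24-parameter motion regression (6 motion parameters, their backward-difference
accelerations, and the squares of both), linear detrending, an ideal bandpass
restricted to 0.01-0.08 Hz, and Fisher z-transformed Pearson correlation of
every voxel with the mean seed time course.

Processing order is fixed as motion regression -> detrend -> bandpass ->
correlation; the chain is invariant to adding any linear combination of
nuisance columns to the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .volumes import VolumeSeries

__all__ = [
    "SeedSpec",
    "NuisanceDesign",
    "SFCMap",
    "build_nuisance_matrix",
    "regress_out",
    "detrend_linear",
    "bandpass",
    "resolve_seed",
    "sfc_map",
    "motion_qc",
    "preprocess_series",
    "fisher_z",
]

logger = logging.getLogger(__name__)

# |r| clamp before atanh keeps connectivity maps finite (z caps near 13.9)
_R_CLAMP = 1.0 - 1e-12


def fisher_z(r):
    """Fisher's variance-stabilizing transform z = atanh(r) for |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1")
    return np.arctanh(r)


@dataclass
class SeedSpec:
    """Spherical seed: center voxel index plus a radius in mm (default 5)."""

    center_voxel: tuple[int, int, int]
    radius_mm: float = 5.0

    def __post_init__(self) -> None:
        self.center_voxel = tuple(int(c) for c in self.center_voxel)
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


@dataclass
class NuisanceDesign:
    """T x 24 nuisance matrix: [motion | accel | motion^2 | accel^2]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 24:
            raise ValueError("NuisanceDesign requires exactly 24 columns")


@dataclass
class SFCMap:
    """Fisher-z seed connectivity map for one subject."""

    data: np.ndarray  # 3D z values
    seed: SeedSpec
    voxel_size_mm: float = 1.0
    n_zero_variance: int = 0
    mask: np.ndarray | None = field(default=None, repr=False)


def build_nuisance_matrix(motion: np.ndarray) -> NuisanceDesign:
    """Expand a T x 6 motion trace into the 24-parameter nuisance design.

    Acceleration is the backward difference of each motion parameter with a
    leading zero; the squared terms of both blocks complete the design.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    if motion.shape[0] < 3:
        raise ValueError("motion trace needs at least 3 timepoints")
    accel = np.vstack([np.zeros((1, 6)), np.diff(motion, axis=0)])
    return NuisanceDesign(np.hstack([motion, accel, motion**2, accel**2]))


def _prune_rank_deficient(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns, keeping the earliest independent set."""
    keep: list[int] = []
    basis = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j : j + 1]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > 1e-10 * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.hstack([basis, col])
    if len(keep) < X.shape[1]:
        logger.warning("dropping %d rank-deficient design column(s)", X.shape[1] - len(keep))
    return X[:, keep]


def regress_out(series: VolumeSeries, design: NuisanceDesign | np.ndarray) -> VolumeSeries:
    """Per-voxel OLS residuals after regressing on the nuisance design.

    An intercept is always included, so the output is demeaned and orthogonal
    to every design column.  Rank-deficient designs have dependent columns
    dropped with a logged warning.
    """
    X = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design, dtype=float)
    T = series.n_timepoints
    if X.shape[0] != T:
        raise ValueError(f"design has {X.shape[0]} rows but series has {T} timepoints")
    X = np.hstack([np.ones((T, 1)), X])
    X = _prune_rank_deficient(X)
    Y = series.data.reshape(-1, T).T  # T x V
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = resid.T.reshape(series.data.shape)
    return VolumeSeries(out, series.voxel_size_mm, series.tr_seconds)


def detrend_linear(series: VolumeSeries) -> VolumeSeries:
    """Remove the per-voxel best-fit line (and mean) along time."""
    out = sps.detrend(series.data, axis=3, type="linear")
    return VolumeSeries(out, series.voxel_size_mm, series.tr_seconds)


def bandpass(series: VolumeSeries, low_hz: float = 0.01, high_hz: float = 0.08) -> VolumeSeries:
    """Ideal (rectangular) frequency-domain bandpass.

    Keeps DFT bins with low_hz <= f <= high_hz; the DC bin is always removed.
    """
    if high_hz <= low_hz:
        raise ValueError("high_hz must exceed low_hz")
    nyquist = 0.5 / series.tr_seconds
    if high_hz >= nyquist:
        raise ValueError(f"high_hz={high_hz} must be below Nyquist {nyquist:.4f} Hz")
    T = series.n_timepoints
    freqs = np.fft.rfftfreq(T, d=series.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    keep[0] = False
    spec = np.fft.rfft(series.data, axis=3)
    spec[..., ~keep] = 0.0
    out = np.fft.irfft(spec, n=T, axis=3)
    return VolumeSeries(out, series.voxel_size_mm, series.tr_seconds)


def resolve_seed(seed: SeedSpec, grid_dims: tuple[int, int, int], voxel_size_mm: float) -> np.ndarray:
    """Binary membership mask of the seed sphere.

    A voxel belongs to the seed when the Euclidean distance between its
    center and the seed-center voxel's center is <= radius_mm; the center
    voxel is always a member.
    """
    dims = tuple(int(d) for d in grid_dims)
    cx, cy, cz = seed.center_voxel
    if not (0 <= cx < dims[0] and 0 <= cy < dims[1] and 0 <= cz < dims[2]):
        raise ValueError(f"seed center {seed.center_voxel} outside grid {dims}")
    ax = [np.arange(d, dtype=float) * voxel_size_mm for d in dims]
    dx = ax[0] - cx * voxel_size_mm
    dy = ax[1] - cy * voxel_size_mm
    dz = ax[2] - cz * voxel_size_mm
    dist2 = dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
    return dist2 <= seed.radius_mm**2 + 1e-9


def sfc_map(series: VolumeSeries, seed: SeedSpec, mask: np.ndarray | None = None) -> SFCMap:
    """Fisher-z map of Pearson correlations with the mean seed time course.

    The seed time course is the unweighted mean over the resolved seed
    voxels.  Zero-variance voxels get z = 0 (count logged); |r| is clamped
    just below 1 before atanh so the map stays finite.
    """
    dims = series.data.shape[:3]
    seed_mask = resolve_seed(seed, dims, series.voxel_size_mm)
    if mask is None:
        mask = np.ones(dims, dtype=bool)
    if not np.any(seed_mask & mask):
        raise ValueError("seed sphere lies entirely outside the analysis mask")
    T = series.n_timepoints
    seed_tc = series.data[seed_mask & mask].mean(axis=0)
    seed_tc = seed_tc - seed_tc.mean()
    seed_norm = np.linalg.norm(seed_tc)
    if seed_norm == 0:
        raise ValueError("seed time course has zero variance")

    Y = series.data.reshape(-1, T)
    Y = Y - Y.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Y, axis=1)
    zero_var = norms == 0
    norms[zero_var] = 1.0
    r = (Y @ seed_tc) / (norms * seed_norm)
    r[zero_var] = 0.0
    n_zero = int(np.count_nonzero(zero_var & mask.ravel()))
    if n_zero:
        logger.info("sfc_map: %d zero-variance voxel(s) set to z=0", n_zero)
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP)).reshape(dims)
    z[~mask] = 0.0
    return SFCMap(z, seed, series.voxel_size_mm, n_zero, mask=mask)


def motion_qc(motion: np.ndarray, voxel_size_mm: float) -> dict:
    """Optional quality check: flag subjects whose head motion exceeds one voxel.

    Computes the maximum absolute translation (columns 0-2, mm) over the
    run; ``exceeds`` is True when it is above ``voxel_size_mm``.  Rotations
    are reported (max |radians|) but not thresholded.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
    max_trans = float(np.abs(motion[:, :3]).max())
    max_rot = float(np.abs(motion[:, 3:]).max())
    return {
        "max_translation_mm": max_trans,
        "max_rotation_rad": max_rot,
        "exceeds": max_trans > voxel_size_mm,
    }


def preprocess_series(
    series: VolumeSeries,
    motion: np.ndarray,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> VolumeSeries:
    """Full nuisance chain: 24-parameter regression, detrend, bandpass."""
    design = build_nuisance_matrix(motion)
    out = regress_out(series, design)
    out = detrend_linear(out)
    return bandpass(out, low_hz=low_hz, high_hz=high_hz)
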