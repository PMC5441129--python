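"""Voxel-wise regression of connectivity maps on clinical scores with
permutation cluster-extent inference adjusted for non-stationary smoothness.

The model is a per-voxel OLS of Fisher-z connectivity values on one or more
clinical regressors of interest (tested one-sided for negative association)
plus nuisance covariates.  Supra-threshold voxels at a cluster-forming
threshold (default p < 0.01) are labeled into connected components and each
cluster's extent is normalized by locally estimated smoothness (resel
extent), so extent-based inference stays valid when smoothness varies over
the volume.  Family-wise error over clusters is controlled by a permutation
null of the maximum normalized extent: the clinical regressors of interest
are randomly reassigned to scans (covariates stay attached to the imaging
rows), the model is refit, and the null distribution of the max resel
extent across all tested regressors is accumulated.  Exact cluster
p-values are reported from the same null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .groupglm import StatMap

__all__ = [
    "RegressionDesign",
    "ClusterTable",
    "PermutationNull",
    "LocalSmoothness",
    "SFCRegression",
    "SFCRegressionResults",
    "fit_voxelwise_regression",
    "form_clusters",
    "local_smoothness",
    "cluster_fwe",
    "validity_check",
    "binomial_ci",
]

logger = logging.getLogger(__name__)

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class RegressionDesign:
    """Regressors of interest (tested) plus covariates of no interest.

    ``interest`` may hold several jointly modeled clinical scores (each gets
    its own contrast) or a single score; the design matrix is
    [intercept | interest | covariates].  Rows with missing values are
    dropped listwise with their ids logged.
    """

    interest: pd.DataFrame
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.interest = pd.DataFrame(self.interest)
        if self.covariates is not None:
            self.covariates = pd.DataFrame(self.covariates)
            if len(self.covariates) != len(self.interest):
                raise ValueError("interest and covariates must have equal row counts")

    @property
    def names(self) -> list[str]:
        return [str(c) for c in self.interest.columns]

    def complete_rows(self) -> np.ndarray:
        ok = ~self.interest.isna().any(axis=1).to_numpy()
        if self.covariates is not None:
            ok &= ~self.covariates.isna().any(axis=1).to_numpy()
        if not ok.all():
            dropped = np.flatnonzero(~ok)
            logger.warning("listwise deletion of %d subject(s): rows %s", len(dropped), dropped.tolist())
        return ok

    def matrix(self) -> np.ndarray:
        rows = self.complete_rows()
        n = int(rows.sum())
        Z = self.interest.to_numpy(float)[rows]
        cols = [np.ones(n), *Z.T]
        if self.covariates is not None:
            cols.extend(self.covariates.to_numpy(float)[rows].T)
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("design matrix is rank deficient after column assembly")
        return X


@dataclass
class ClusterTable:
    """Supra-threshold clusters of one contrast.

    ``table`` columns: cluster_id, extent_voxels, extent_resels, peak_t,
    peak_x/y/z, p_fwe (permutation-FWE corrected = exact permutation p).
    ``labels`` is the 3D cluster-id image (0 = background).
    """

    table: pd.DataFrame
    labels: np.ndarray
    regressor: str = ""
    t_threshold: float = np.nan

    def __len__(self) -> int:
        return len(self.table)

    def voxels(self, cluster_id: int) -> np.ndarray:
        """Boolean mask of one cluster."""
        return self.labels == cluster_id

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        if "p_fwe" not in self.table.columns:
            raise ValueError("cluster table carries no permutation p-values yet")
        return self.table[self.table["p_fwe"] <= alpha]


@dataclass
class PermutationNull:
    """Null distribution of the maximum normalized (resel) cluster extent."""

    max_extents: np.ndarray
    t_threshold: float
    alpha: float = 0.05

    @property
    def n_perm(self) -> int:
        return len(self.max_extents)

    def critical_extent(self) -> float:
        """(1-alpha) quantile: the FWE cluster-extent threshold in resels."""
        k = int(np.ceil((1 - self.alpha) * (self.n_perm + 1))) - 1
        return float(np.sort(self.max_extents)[min(k, self.n_perm - 1)])

    def exact_p(self, extent_resels) -> np.ndarray:
        e = np.atleast_1d(np.asarray(extent_resels, float))
        p = (1 + np.sum(self.max_extents[None, :] >= e[:, None], axis=1)) / (1 + self.n_perm)
        return p


@dataclass
class LocalSmoothness:
    """Per-voxel FWHM (mm, one per axis) and resels-per-voxel map."""

    fwhm: np.ndarray  # (x, y, z, 3)
    rpv: np.ndarray  # (x, y, z)
    n_excluded: int = 0

    def median_fwhm(self, mask: np.ndarray | None = None) -> float:
        f = self.fwhm if mask is None else self.fwhm[mask]
        return float(np.nanmedian(f))


def _stack_maps(maps) -> np.ndarray:
    if isinstance(maps, (list, tuple)):
        maps = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in maps])
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("maps must stack to (n_subjects, x, y, z)")
    return maps


def _tmaps_interest(X: np.ndarray, Y: np.ndarray, n_interest: int) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sided (negative-direction) t per interest regressor.

    Returns (t_neg: n_interest x V, residuals: n x V, dof).  t_neg is the t
    statistic for the *negative* association, i.e. positive values indicate
    connectivity decreasing with the score.
    """
    n, p = X.shape
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    idx = np.arange(1, 1 + n_interest)
    var_c = np.diag(XtX_inv)[idx]
    se = np.sqrt(np.maximum(sigma2[None, :] * var_c[:, None], 1e-300))
    t_neg = -beta[idx] / se
    return t_neg, resid, dof


def fit_voxelwise_regression(maps, design: RegressionDesign, mask: np.ndarray | None = None) -> dict[str, StatMap]:
    """Per-voxel OLS over subjects; one negative-direction StatMap per regressor."""
    return SFCRegression(maps, design, mask=mask).fit().statmaps


def form_clusters(
    statmap: StatMap,
    voxel_p: float = 0.01,
    connectivity: int = 18,
    t_threshold: float | None = None,
    rpv: np.ndarray | None = None,
) -> ClusterTable:
    """Label supra-threshold voxels into connected components.

    The cluster-forming threshold is the one-sided t value at ``voxel_p``
    for the map's dof (or an explicit ``t_threshold``).  Connectivity is
    18 by default (6/26 available).  If a resels-per-voxel map is given the
    table carries smoothness-normalized (resel) extents.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    if t_threshold is None:
        if not 0 < voxel_p < 1:
            raise ValueError("voxel_p must be in (0, 1)")
        t_threshold = float(stats.t.ppf(1 - voxel_p, statmap.dof))
    supra = (statmap.t > t_threshold) & statmap.mask
    labels, n_clusters = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    rows = []
    for cid in range(1, n_clusters + 1):
        vox = labels == cid
        extent = int(vox.sum())
        tvals = np.where(vox, statmap.t, -np.inf)
        peak = np.unravel_index(int(np.argmax(tvals)), tvals.shape)
        resels = float(rpv[vox].sum()) if rpv is not None else np.nan
        rows.append(
            {
                "cluster_id": cid,
                "extent_voxels": extent,
                "extent_resels": resels,
                "peak_t": float(statmap.t[peak]),
                "peak_x": peak[0],
                "peak_y": peak[1],
                "peak_z": peak[2],
            }
        )
    table = pd.DataFrame(rows, columns=["cluster_id", "extent_voxels", "extent_resels", "peak_t", "peak_x", "peak_y", "peak_z"])
    return ClusterTable(table=table, labels=labels, t_threshold=t_threshold)


def _max_resel_extent(t_flat: np.ndarray, mask: np.ndarray, t_threshold: float, rpv: np.ndarray, structure) -> float:
    """Maximum normalized cluster extent of one flat t map (0 if none supra)."""
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = t_flat > t_threshold
    if not supra.any():
        return 0.0
    labels, n = ndimage.label(supra, structure=structure)
    sums = ndimage.sum_labels(rpv, labels, index=np.arange(1, n + 1))
    return float(np.max(sums))


def local_smoothness(residual_maps, mask: np.ndarray, voxel_size_mm: float) -> LocalSmoothness:
    """Per-voxel smoothness (FWHM) from spatial derivatives of standardized residuals.

    Residual images are variance-normalized per voxel; for each axis the mean
    squared forward difference (per mm) estimates the second spectral moment
    Lambda, and FWHM = sqrt(4 ln 2 / Lambda).  The resels-per-voxel map is
    voxel volume / product of the per-axis FWHMs.  Zero-variance voxels are
    excluded (RPV 0, FWHM NaN) and counted.
    """
    R = _stack_maps(residual_maps)
    if R.shape[0] < 10:
        raise ValueError("need at least 10 residual maps to estimate smoothness")
    mask = np.asarray(mask, dtype=bool)
    norms = np.sqrt(np.einsum("i...,i...->...", R, R))
    zero = (norms == 0) | ~mask
    n_excluded = int(np.count_nonzero(zero & mask))
    if n_excluded:
        logger.warning("local_smoothness: %d zero-variance voxel(s) excluded", n_excluded)
    safe = np.where(norms == 0, 1.0, norms)
    U = R / safe[None]

    dims = mask.shape
    lam = np.full(dims + (3,), np.nan)
    for ax in range(3):
        d = np.diff(U, axis=ax + 1) / voxel_size_mm
        ss = np.einsum("i...,i...->...", d, d)
        # valid where both voxels of the difference are usable
        valid_pair = (~zero) & np.roll(~zero, -1, axis=ax)
        sl = [slice(None)] * 3
        sl[ax] = slice(0, dims[ax] - 1)
        valid_pair = valid_pair[tuple(sl)]
        lam_ax = np.full(dims, np.nan)
        lam_ax[tuple(sl)] = np.where(valid_pair, ss, np.nan)
        # replicate the last valid plane so edge voxels keep an estimate
        sl_last, sl_prev = [slice(None)] * 3, [slice(None)] * 3
        sl_last[ax] = slice(dims[ax] - 1, dims[ax])
        sl_prev[ax] = slice(dims[ax] - 2, dims[ax] - 1)
        lam_ax[tuple(sl_last)] = np.where(
            np.isnan(lam_ax[tuple(sl_last)]), lam_ax[tuple(sl_prev)], lam_ax[tuple(sl_last)]
        )
        lam[..., ax] = lam_ax

    with np.errstate(divide="ignore", invalid="ignore"):
        fwhm = np.sqrt(4 * np.log(2) / lam)
    # fill voxels lacking a usable derivative with the in-mask median
    for ax in range(3):
        f = fwhm[..., ax]
        med = np.nanmedian(f[mask & ~zero]) if np.any(mask & ~zero) else voxel_size_mm
        f[np.isnan(f) & mask & ~zero] = med
    voxel_vol = voxel_size_mm**3
    with np.errstate(divide="ignore", invalid="ignore"):
        rpv = voxel_vol / np.prod(fwhm, axis=-1)
    rpv[~mask | zero] = 0.0
    rpv[~np.isfinite(rpv)] = 0.0
    fwhm[~mask | zero] = np.nan
    return LocalSmoothness(fwhm=fwhm, rpv=rpv, n_excluded=n_excluded)


class SFCRegression:
    """Voxel-wise multiple regression of connectivity maps on clinical scores.

    Parameters
    ----------
    maps : (n, x, y, z) array or list of SFCMap/VolumeMap
    design : RegressionDesign
        Regressors of interest (each tested one-sided for negative
        association) plus covariates.
    mask : 3D bool, optional
    voxel_size_mm : float
        Needed for smoothness normalization; taken from the first map when
        available.
    """

    def __init__(self, maps, design: RegressionDesign, mask: np.ndarray | None = None, voxel_size_mm: float | None = None):
        if voxel_size_mm is None and isinstance(maps, (list, tuple)) and maps:
            voxel_size_mm = getattr(maps[0], "voxel_size_mm", None)
        self.maps = _stack_maps(maps)
        self.voxel_size_mm = float(voxel_size_mm) if voxel_size_mm else 1.0
        self.design = design
        self.mask = np.ones(self.maps.shape[1:], dtype=bool) if mask is None else np.asarray(mask, bool)
        rows = design.complete_rows()
        if len(rows) != self.maps.shape[0]:
            raise ValueError("maps and design are not row-aligned")
        self._rows = rows
        self._X = design.matrix()
        n, p = self._X.shape
        if n <= p + 2:
            raise ValueError(f"need n > p + 2 (n={n}, p={p})")

    def fit(self) -> "SFCRegressionResults":
        Y = self.maps[self._rows].reshape(int(self._rows.sum()), -1)[:, self.mask.ravel()]
        t_neg, resid, dof = _tmaps_interest(self._X, Y, len(self.design.names))
        statmaps = {}
        for j, name in enumerate(self.design.names):
            t = np.zeros(self.mask.shape)
            t[self.mask] = t_neg[j]
            statmaps[name] = StatMap(t, dof, self.mask)
        return SFCRegressionResults(self, statmaps, resid, Y)


class SFCRegressionResults:
    """Fitted voxel-wise regression: per-regressor t maps, clustering, permutation FWE."""

    def __init__(self, model: SFCRegression, statmaps: dict[str, StatMap], residuals: np.ndarray, _Y: np.ndarray):
        self.model = model
        self.statmaps = statmaps
        self._resid_flat = residuals  # n x V(mask)
        self._Y = _Y
        self._smoothness: LocalSmoothness | None = None

    @property
    def dof(self) -> int:
        return next(iter(self.statmaps.values())).dof

    def smoothness(self) -> LocalSmoothness:
        """Local smoothness of the model residuals (cached)."""
        if self._smoothness is None:
            n = self._resid_flat.shape[0]
            R = np.zeros((n,) + self.model.mask.shape)
            R[:, self.model.mask] = self._resid_flat
            self._smoothness = local_smoothness(R, self.model.mask, self.model.voxel_size_mm)
        return self._smoothness

    def clusters(self, voxel_p: float = 0.01, connectivity: int = 18) -> dict[str, ClusterTable]:
        """Pre-inference cluster tables (with resel extents) per regressor."""
        rpv = self.smoothness().rpv
        out = {}
        for name, sm in self.statmaps.items():
            ct = form_clusters(sm, voxel_p=voxel_p, connectivity=connectivity, rpv=rpv)
            ct.regressor = name
            out[name] = ct
        return out

    def cluster_fwe(
        self,
        voxel_p: float = 0.01,
        cluster_alpha: float = 0.05,
        n_perm: int = 1000,
        connectivity: int = 18,
        rng=None,
    ) -> tuple[dict[str, ClusterTable], PermutationNull]:
        """Permutation FWE over normalized cluster extents.

        The rows of the regressor-of-interest block are permuted jointly
        (preserving inter-score correlation; covariates stay attached to the
        imaging rows); each permutation contributes the maximum resel extent
        over all tested regressors.  Observed clusters get
        p_fwe = (1 + #{null max >= extent}) / (1 + n_perm).
        """
        if n_perm < 20:
            raise ValueError("n_perm must be >= 20 (p resolution too coarse below)")
        rng = np.random.default_rng(rng)
        tables = self.clusters(voxel_p=voxel_p, connectivity=connectivity)
        t_thresh = float(stats.t.ppf(1 - voxel_p, self.dof))
        rpv = self.smoothness().rpv
        structure = _STRUCTURES[connectivity]
        mask = self.model.mask
        X = self.model._X
        m = len(self.model.design.names)
        n = X.shape[0]
        Y = self._Y
        null_max = np.empty(n_perm)
        for b in range(n_perm):
            Xp = X.copy()
            perm = rng.permutation(n)
            Xp[:, 1 : 1 + m] = X[perm, 1 : 1 + m]
            t_neg, _, _ = _tmaps_interest(Xp, Y, m)
            null_max[b] = max(
                _max_resel_extent(t_neg[j], mask, t_thresh, rpv, structure) for j in range(m)
            )
        null = PermutationNull(max_extents=null_max, t_threshold=t_thresh, alpha=cluster_alpha)
        for ct in tables.values():
            if len(ct):
                ct.table["p_fwe"] = null.exact_p(ct.table["extent_resels"].to_numpy())
            else:
                ct.table["p_fwe"] = pd.Series(dtype=float)
        return tables, null

    def summary(self) -> str:
        lines = [
            "Voxel-wise SFC regression (one-sided, negative direction)",
            f"  subjects: {self._resid_flat.shape[0]}   voxels: {int(self.model.mask.sum())}   dof: {self.dof}",
        ]
        for name, sm in self.statmaps.items():
            lines.append(f"  {name}: max t = {sm.t[sm.mask].max():.3f}")
        return "\n".join(lines)


def cluster_fwe(
    maps,
    design: RegressionDesign,
    voxel_p: float = 0.01,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    mask: np.ndarray | None = None,
    voxel_size_mm: float | None = None,
    connectivity: int = 18,
    rng=None,
):
    """Functional wrapper around SFCRegression(...).fit().cluster_fwe(...)."""
    res = SFCRegression(maps, design, mask=mask, voxel_size_mm=voxel_size_mm).fit()
    return res.cluster_fwe(voxel_p=voxel_p, cluster_alpha=cluster_alpha, n_perm=n_perm, connectivity=connectivity, rng=rng)


def binomial_ci(k: int, n: int, conf: float = 0.99) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for a proportion."""
    alpha = 1 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def validity_check(
    maps,
    design: RegressionDesign,
    voxel_p: float = 0.01,
    cluster_alpha: float = 0.05,
    n_perm: int = 500,
    n_eval: int | None = None,
    mask: np.ndarray | None = None,
    voxel_size_mm: float | None = None,
    connectivity: int = 18,
    rng=None,
) -> dict:
    """Empirical false-positive rate of the cluster inference under permutation.

    Builds the max-resel-extent null from ``n_perm`` permutations, then
    scores ``n_eval`` (default n_perm) *fresh* random reassignments of the
    clinical scores against it: a reassignment counts as positive when its
    exact cluster p = (1 + #{null >= max extent}) / (1 + n_perm) is <=
    ``cluster_alpha``.  Returns the positive proportion with an exact
    (Clopper-Pearson) 99% binomial confidence interval.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    res = SFCRegression(maps, design, mask=mask, voxel_size_mm=voxel_size_mm).fit()
    _, null = res.cluster_fwe(
        voxel_p=voxel_p, cluster_alpha=cluster_alpha, n_perm=n_perm, connectivity=connectivity, rng=rng
    )
    n_eval = n_perm if n_eval is None else n_eval
    t_thresh = null.t_threshold
    rpv = res.smoothness().rpv
    structure = _STRUCTURES[connectivity]
    X = res.model._X
    m = len(res.model.design.names)
    n = X.shape[0]
    positives = 0
    eval_max = np.empty(n_eval)
    for b in range(n_eval):
        Xp = X.copy()
        perm = rng.permutation(n)
        Xp[:, 1 : 1 + m] = X[perm, 1 : 1 + m]
        t_neg, _, _ = _tmaps_interest(Xp, res._Y, m)
        mx = max(_max_resel_extent(t_neg[j], res.model.mask, t_thresh, rpv, structure) for j in range(m))
        eval_max[b] = mx
        if null.exact_p(mx)[0] <= cluster_alpha:
            positives += 1
    prop = positives / n_eval
    lo, hi = binomial_ci(positives, n_eval, conf=0.99)
    return {
        "proportion": prop,
        "ci99": (lo, hi),
        "n_eval": n_eval,
        "n_positive": positives,
        "null": null,
        "eval_max_extents": eval_max,
    }
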