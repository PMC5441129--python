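"""Cluster eigenvariate extraction.

A cluster's eigenvariate is the subject-side first singular component of the
subjects x voxels matrix of connectivity values inside the cluster — a
one-number-per-subject summary of the cluster's signal.  Before the
decomposition, covariates of no interest are regressed out of every voxel
column (intercept included), matching inference models that adjust for the
same covariates.  Because singular vectors are sign-ambiguous, the score is
sign-fixed to correlate positively with the cluster's mean (adjusted)
signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Eigenvariate", "extract_eigenvariate", "loo_r2"]


@dataclass
class Eigenvariate:
    """Per-subject cluster score with its voxel weight vector."""

    scores: np.ndarray  # (n_subjects,)
    weights: np.ndarray  # (n_voxels,), unit norm
    cluster_id: int = 0
    sign_fixed: bool = True
    singular_value: float = np.nan

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.scores, dtype=dtype)


def _residualize(M: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = M.shape[0]
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if C.shape[0] != n:
            raise ValueError("covariate rows must match subject count")
        X = np.hstack([X, C])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


def extract_eigenvariate(
    maps,
    cluster_mask: np.ndarray,
    covariates=None,
    adjust: bool = True,
    cluster_id: int = 0,
) -> Eigenvariate:
    """First singular component of the (covariate-adjusted) cluster matrix.

    Parameters
    ----------
    maps : (n, x, y, z) array or list of maps
    cluster_mask : 3D bool mask of the cluster (non-empty)
    covariates : optional n x k array/DataFrame regressed out per voxel
        (with an intercept) before the decomposition; ``adjust=False`` (or no
        covariates) decomposes the raw cluster matrix.

    A single-voxel cluster degenerates to the adjusted voxel values
    themselves (unit weight).
    """
    if isinstance(maps, (list, tuple)):
        maps = np.stack([np.asarray(getattr(m, "data", m), dtype=float) for m in maps])
    maps = np.asarray(maps, dtype=float)
    cluster_mask = np.asarray(cluster_mask, dtype=bool)
    if not cluster_mask.any():
        raise ValueError("cluster is empty")
    M = maps[:, cluster_mask]  # n x K
    if adjust and covariates is not None:
        M = _residualize(M, np.asarray(covariates, dtype=float))
    mean_signal = M.mean(axis=1)
    if M.shape[1] == 1:
        w = np.ones(1)
        scores = M[:, 0]
        s1 = float(np.linalg.norm(scores))
        return Eigenvariate(scores=scores, weights=w, cluster_id=cluster_id, singular_value=s1)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    scores = U[:, 0] * S[0]
    w = Vt[0]
    if np.dot(scores - scores.mean(), mean_signal - mean_signal.mean()) < 0:
        scores = -scores
        w = -w
    return Eigenvariate(scores=scores, weights=w, cluster_id=cluster_id, singular_value=float(S[0]))


def loo_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Leave-one-out predicted r^2 of a simple linear regression of y on x.

    Utility for quantifying how much variance a cluster score predicts in a
    clinical scale out-of-sample: each subject's prediction comes from the
    model fitted without them; returns the squared correlation between
    predictions and observations.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need aligned vectors of length >= 4")
    X = np.column_stack([np.ones(n), x])
    # closed-form LOO predictions via hat-matrix diagonal
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    fitted = X @ beta
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    loo_pred = y - (y - fitted) / (1 - h)
    r = np.corrcoef(loo_pred, y)[0, 1]
    return float(r**2)
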