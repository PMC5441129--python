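"""Cross-modal scalar statistics: partial correlations, a significance-based
mediation rule, and Steiger's z-test for dependent overlapping correlations.

These operate on per-subject scalars (cluster eigenvariates, DAT
striatal-binding ratios, UPDRS subscales) merged into one table.  Missing
values are handled by listwise deletion, so effective n may differ between
analyses.  p-values are reported uncorrected, mirroring common practice for
small families of planned comparisons; a Holm correction helper is provided
for users who want one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .connectivity import fisher_z

__all__ = [
    "PartialCorrResult",
    "MediationResult",
    "SteigerResult",
    "partial_correlation",
    "mediation_test",
    "steiger_z",
    "fisher_z",
    "partial_correlation_from_marginals",
    "shared_variance_percent",
    "holm_correction",
]


@dataclass
class PartialCorrResult:
    """Partial correlation with its t-based two-sided p-value.

    p is computed from t = r*sqrt((n-2-k)/(1-r^2)) on n-2-k degrees of
    freedom, k the number of controls.  ``marginal`` flags the
    0.05 <= p < 0.10 band ("marginally significant").
    """

    r: float
    p: float
    n: int
    controls: list[str] = field(default_factory=list)

    @property
    def marginal(self) -> bool:
        return 0.05 <= self.p < 0.10

    @property
    def significant(self) -> bool:
        return self.p < 0.05


@dataclass
class MediationResult:
    """Outcome of the significance-based mediation rule at alpha = 0.05."""

    verdict: str  # mediated | independent | no_initial_association
    r_before: float
    p_before: float
    r_after: float
    p_after: float
    mediator: str = ""


@dataclass
class SteigerResult:
    Z: float
    p: float


def _listwise(*arrays):
    cols = [np.asarray(a, dtype=float).reshape(len(np.asarray(a)), -1) for a in arrays]
    X = np.hstack(cols)
    ok = np.all(np.isfinite(X), axis=1)
    return [c[ok] for c in cols], int(ok.sum())


def partial_correlation(x, y, controls=None, control_names=None) -> PartialCorrResult:
    """Correlation of x and y after removing linear effects of the controls.

    Both variables are residualized on [intercept | controls] by OLS and the
    Pearson correlation of the residuals is returned; with no controls this
    is the plain Pearson correlation.  Complete cases only.
    """
    arrays = [x, y] + ([controls] if controls is not None else [])
    (xc, yc, *rest), n = _listwise(*arrays)
    C = rest[0] if rest else None
    k = 0 if C is None else C.shape[1]
    if n <= k + 3:
        raise ValueError(f"need n > #controls + 3 (n={n}, k={k})")
    X = np.ones((n, 1)) if C is None else np.hstack([np.ones((n, 1)), C])
    rx = xc - X @ np.linalg.lstsq(X, xc, rcond=None)[0]
    ry = yc - X @ np.linalg.lstsq(X, yc, rcond=None)[0]
    sx, sy = np.linalg.norm(rx), np.linalg.norm(ry)
    if sx <= 1e-10 * max(1.0, np.linalg.norm(xc)) or sy <= 1e-10 * max(1.0, np.linalg.norm(yc)):
        raise ValueError("zero residual variance: partial correlation undefined")
    r = float((rx.T @ ry).item() / (sx * sy))
    r = min(1.0, max(-1.0, r))
    dof = n - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), dof))
    names = list(control_names) if control_names is not None else ([f"c{i}" for i in range(k)] if k else [])
    return PartialCorrResult(r=r, p=p, n=n, controls=names)


def mediation_test(x, y, mediator, covariates=None, alpha: float = 0.05) -> MediationResult:
    """Significance-based mediation rule.

    r_before = partial(x, y | covariates); r_after = partial(x, y |
    covariates + mediator).  Verdict: ``no_initial_association`` if the
    initial correlation is not significant; ``mediated`` if it is and the
    controlled one is not; ``independent`` if both are significant.
    """
    med = np.asarray(mediator, dtype=float).reshape(-1, 1)
    if np.nanstd(med) == 0:
        raise ValueError("mediator is constant")
    before = partial_correlation(x, y, covariates)
    C_after = med if covariates is None else np.hstack([np.asarray(covariates, float).reshape(len(med), -1), med])
    after = partial_correlation(x, y, C_after)
    if before.p >= alpha:
        verdict = "no_initial_association"
    elif after.p >= alpha:
        verdict = "mediated"
    else:
        verdict = "independent"
    return MediationResult(
        verdict=verdict,
        r_before=before.r,
        p_before=before.p,
        r_after=after.r,
        p_after=after.p,
    )


def steiger_z(r_xy1: float, r_xy2: float, r_12: float, n: int) -> SteigerResult:
    """Steiger's test for two dependent correlations sharing one variable.

    Compares r(x, y1) with r(x, y2) given r(y1, y2) at sample size n:
    both correlations are Fisher-z transformed and their covariance is taken
    from the Dunn-Clark formula evaluated at the pooled mean correlation,
    giving an asymptotically standard-normal Z with a two-sided p.
    """
    for r in (r_xy1, r_xy2, r_12):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise ValueError("n must exceed 3")
    R = np.array([[1.0, r_xy1, r_xy2], [r_xy1, 1.0, r_12], [r_xy2, r_12, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-12:
        raise ValueError("the three correlations do not form a valid correlation matrix")
    z1, z2 = np.arctanh(r_xy1), np.arctanh(r_xy2)
    rbar = 0.5 * (r_xy1 + r_xy2)
    rb2 = rbar**2
    # Dunn & Clark covariance of the two z's, at the pooled correlation
    cov = (r_12 * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_12**2)) / (1 - rb2) ** 2
    Z = (z1 - z2) * np.sqrt((n - 3) / (2 * (1 - cov)))
    p = float(2 * stats.norm.sf(abs(Z)))
    return SteigerResult(Z=float(Z), p=p)


def partial_correlation_from_marginals(r_xy: float, r_xz: float, r_yz: float) -> float:
    """First-order partial correlation r(x,y | z) from the three marginals.

    r_xy.z = (r_xy - r_xz*r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); agrees with
    the residualization route on any trivariate sample whose correlations
    match the inputs.
    """
    for r in (r_xy, r_xz, r_yz):
        if not -1 < r < 1:
            raise ValueError("marginal correlations must lie strictly inside (-1, 1)")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


def shared_variance_percent(r: float) -> float:
    """Percent of variance shared by two variables correlating at r (100*r^2)."""
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    return 100.0 * r**2


def holm_correction(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
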