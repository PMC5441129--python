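"""Synthetic PPMI-style cohort simulator.

Generates, without any download, cohorts carrying the statistical structure
the downstream analysis assumes:

* integer UPDRS subscale scores with a prescribed inter-subscale correlation
  matrix (latent-Gaussian copula mapped through truncated-normal marginals),
* per-subject 4D resting-state series in which a band-limited seed signal is
  injected into a striatal seed sphere and, scaled by a subject-specific
  coupling strength, into one or more disjoint network templates,
* a motion-correlated artifact that the 24-parameter nuisance regression
  removes exactly,
* DAT-SPECT striatal-binding-ratio maps and region values with a group-level
  reduction at the seed-containing region, statistically independent of the
  connectivity coupling by default,
* gray-matter volume maps with no group difference (a planted null).

Subject-level coupling for network k is an affine function of the designated
UPDRS subscale, calibrated against the population moments of the *integer*
scores so that corr(coupling_k, subscale_k) equals ``coupling_effects[k]``
in the population.

Every subject draws from an RNG stream derived from ``rng_seed`` by fixed
offsets, so cohorts are reproducible under subsetting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import SeedSpec, resolve_seed
from .volumes import VolumeMap, VolumeSeries, write_volume

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_clinical",
    "generate_imaging",
    "generate_cohort",
    "default_network_templates",
    "score_population_moments",
    "UPDRS_MARGINALS",
]

# UPDRS subscale marginals: (mean, sd, min, max) for parts I, II, III.
UPDRS_MARGINALS = {
    "updrs1": (6.9, 5.1, 0, 23),
    "updrs2": (6.8, 4.7, 1, 23),
    "updrs3": (19.8, 10.0, 6, 47),
}

_DEFAULT_UPDRS_CORR = np.array(
    [
        [1.00, 0.56, 0.33],
        [0.56, 1.00, 0.46],
        [0.33, 0.46, 1.00],
    ]
)


def default_network_templates(
    grid_dims: tuple[int, int, int]
) -> list[np.ndarray]:
    """Two disjoint rectangular network templates in opposite grid corners.

    Template extents scale with the grid so each network occupies roughly
    5% of the volume — the proportion cortico-cerebellar connectivity
    networks occupy relative to a whole gray-matter mask.  The first box
    ("SFC II"-like, coupled by default to UPDRS II) sits at the origin
    corner, the second ("SFC III"-like, coupled to UPDRS III) at the far
    corner; both stay clear of a 5 mm mid-grid seed sphere for grids of 12
    voxels per axis and up.
    """
    gx, gy, gz = (int(d) for d in grid_dims)
    ax, ay, az = (max(3, 2 * d // 5) for d in (gx, gy, gz))
    az = max(3, az - 2)  # flatter in z, like cerebellar/occipital sheets
    t1 = np.zeros(grid_dims, dtype=bool)
    t1[1 : 1 + ax, 1 : 1 + ay, 1 : 1 + az] = True
    t2 = np.zeros(grid_dims, dtype=bool)
    t2[gx - 1 - ax : gx - 1, gy - 1 - ay : gy - 1, gz - 1 - az : gz - 1] = True
    return [t1, t2]


@dataclass
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror the de novo PD resting-state cohort the pipeline is
    designed around: 87 patients, inter-subscale correlations
    (I,II)=0.56, (I,III)=0.33, (II,III)=0.46, network couplings of -0.46
    (UPDRS II) and -0.42 (UPDRS III), a DAT reduction at the seed region and
    a DAT signal independent of connectivity coupling.  The grid is kept at
    20 voxels per axis (3 mm isotropic, 150 timepoints at TR 2.4 s) so that
    permutation suites run at desk scale.
    """

    n_subjects: int = 87
    grid_dims: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 150
    tr_seconds: float = 2.4
    seed_center: tuple[int, int, int] | None = None
    seed_radius_mm: float = 5.0
    network_templates: list[np.ndarray] | None = None
    # per-network (population corr with its subscale, subscale index 0/1/2)
    coupling_effects: tuple[float, ...] = (-0.46, -0.42)
    coupling_subscales: tuple[int, ...] = (1, 2)
    updrs_corr: np.ndarray = field(default_factory=lambda: _DEFAULT_UPDRS_CORR.copy())
    dat_effect: float = -0.8
    dat_sfc_corr: float = 0.0
    noise_sd: float = 1.0
    # absolute injection amplitudes (signal units; noise_sd=1 by default):
    # the seed signal is strong (high within-seed SNR); network coupling sits
    # in the r ~ 0.3-0.6 pre-smoothing regime typical of strong seed maps,
    # varying across subjects via coupling_sd
    seed_amp: float = 3.0
    coupling_base: float = 0.45
    coupling_sd: float = 0.12
    motion_step_mm: float = 0.02
    artifact_sd: float = 1.0
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    n_controls: int = 60
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.updrs_corr = np.asarray(self.updrs_corr, dtype=float)
        if self.updrs_corr.shape != (3, 3) or not np.allclose(self.updrs_corr, self.updrs_corr.T):
            raise ValueError("updrs_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(self.updrs_corr), 1.0):
            raise ValueError("updrs_corr must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.updrs_corr)
        if eigvals.min() < -1e-10:
            raise ValueError(
                f"updrs_corr is not positive semi-definite (smallest eigenvalue {eigvals.min():.3g})"
            )
        if self.n_timepoints < 64:
            raise ValueError("n_timepoints must be >= 64 for adequate bandpass resolution")
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.seed_center is None:
            self.seed_center = tuple(int(d) // 2 for d in self.grid_dims)
        self.seed_center = tuple(int(c) for c in self.seed_center)
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        if self.network_templates is None:
            self.network_templates = default_network_templates(self.grid_dims)
        self.network_templates = [np.asarray(t, dtype=bool) for t in self.network_templates]
        if len(self.coupling_effects) != len(self.network_templates):
            raise ValueError("coupling_effects must have one entry per network template")
        if len(self.coupling_subscales) != len(self.network_templates):
            raise ValueError("coupling_subscales must have one entry per network template")
        seed_mask = self.seed_mask
        for k, tmpl in enumerate(self.network_templates):
            if tmpl.shape != self.grid_dims:
                raise ValueError(f"network template {k} shape {tmpl.shape} != grid {self.grid_dims}")
            if np.any(tmpl & seed_mask):
                raise ValueError(f"network template {k} overlaps the seed sphere")

    @property
    def seed(self) -> SeedSpec:
        return SeedSpec(self.seed_center, self.seed_radius_mm)

    @property
    def seed_mask(self) -> np.ndarray:
        return resolve_seed(self.seed, self.grid_dims, self.voxel_size_mm)


def _truncnorm_map(z: np.ndarray, mean: float, sd: float, lo: int, hi: int) -> np.ndarray:
    """Monotone map from standard-normal latents to integer scores in [lo, hi].

    Quantile-maps through a normal truncated to [lo-0.5, hi+0.5] and rounds;
    strictly monotone before rounding, so rank correlations are preserved and
    there is no point mass at the range bounds.
    """
    a = (lo - 0.5 - mean) / sd
    b = (hi + 0.5 - mean) / sd
    x = stats.truncnorm.ppf(stats.norm.cdf(z), a, b, loc=mean, scale=sd)
    return np.clip(np.rint(x), lo, hi).astype(int)


def score_population_moments(mean: float, sd: float, lo: int, hi: int) -> tuple[float, float]:
    """Population mean/SD of the mapped integer score, by quadrature over the latent."""
    z = np.linspace(-8.0, 8.0, 8001)
    w = stats.norm.pdf(z)
    w /= w.sum()
    s = _truncnorm_map(z, mean, sd, lo, hi).astype(float)
    mu = float(np.sum(w * s))
    var = float(np.sum(w * (s - mu) ** 2))
    return mu, np.sqrt(var)


def generate_clinical(spec: CohortSpec) -> pd.DataFrame:
    """Clinical table for the patient group.

    Subscales are drawn from a latent Gaussian with the requested
    correlation matrix and monotonically mapped to integers within the
    per-subscale ranges; total = I + II + III by construction.  Age, sex,
    dominant side and three binary medication flags follow the cohort's
    marginal frequencies and are independent of the UPDRS scores.
    """
    rng = np.random.default_rng([spec.rng_seed, 0])
    n = spec.n_subjects
    L = np.linalg.cholesky(spec.updrs_corr + 1e-12 * np.eye(3))
    z = rng.standard_normal((n, 3)) @ L.T
    cols = {}
    for j, (name, (mu, sd, lo, hi)) in enumerate(UPDRS_MARGINALS.items()):
        cols[name] = _truncnorm_map(z[:, j], mu, sd, lo, hi)
    df = pd.DataFrame(cols)
    df["updrs_total"] = df["updrs1"] + df["updrs2"] + df["updrs3"]
    df["age"] = np.clip(np.rint(rng.normal(61.0, 10.5, n)), 38, 78).astype(int)
    df["sex"] = (rng.random(n) < 28 / 87).astype(int)  # 1 = female
    df["dominant_side"] = rng.choice([-1, 0, 1], size=n, p=[33 / 87, 2 / 87, 52 / 87])
    df["on_levodopa"] = (rng.random(n) < 32 / 87).astype(int)
    df["on_agonist"] = (rng.random(n) < 19 / 87).astype(int)
    df["on_other"] = (rng.random(n) < 19 / 87).astype(int)
    df["tiv_ml"] = rng.normal(1500.0, 120.0, n)
    df.insert(0, "subject", [f"PD{i:04d}" for i in range(n)])
    df.attrs["latent"] = z
    return df


def _bandlimited_signal(rng: np.random.Generator, T: int, tr: float, low: float, high: float) -> np.ndarray:
    """Unit-variance Gaussian signal restricted to the analysis band."""
    white = rng.standard_normal(T)
    freqs = np.fft.rfftfreq(T, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False
    spec = np.fft.rfft(white)
    spec[~keep] = 0.0
    s = np.fft.irfft(spec, n=T)
    return s / s.std()


def _simulate_motion(rng: np.random.Generator, T: int, step_mm: float) -> np.ndarray:
    """T x 6 random-walk motion trace (3 translations mm, 3 rotations rad)."""
    steps = rng.normal(0.0, 1.0, (T, 6)) * np.array([step_mm] * 3 + [step_mm / 50] * 3)
    return np.cumsum(steps, axis=0)


# DAT-SPECT striatal binding ratios: region base means/SD (healthy levels)
_DAT_REGIONS = ("dat_putamen_ipsi", "dat_putamen_contra", "dat_caudate_ipsi", "dat_caudate_contra")
_DAT_BASE = {"dat_putamen_ipsi": 2.0, "dat_putamen_contra": 2.1, "dat_caudate_ipsi": 2.8, "dat_caudate_contra": 2.9}
_DAT_SD = 0.35
# fraction of the seed-region effect applied to the other striatal regions
_DAT_SPREAD = 0.6
SEED_DAT_REGION = "dat_putamen_ipsi"


@dataclass
class SyntheticCohort:
    """A generated cohort: clinical table, motion, lazy volumes, DAT and GMV data.

    4D series are regenerated on demand from per-subject RNG streams
    (``series(i)``), so arbitrarily large cohorts can be streamed through the
    connectivity stage without holding every volume in memory.
    """

    spec: CohortSpec
    clinical: pd.DataFrame
    motion: list[np.ndarray]
    dat_regions: pd.DataFrame
    dat_maps: np.ndarray  # (n_pd, x, y, z) float32
    dat_maps_control: np.ndarray  # (n_hc, x, y, z) float32
    gmv_maps: np.ndarray
    gmv_maps_control: np.ndarray
    control_covariates: pd.DataFrame
    truth: dict

    def series(self, i: int) -> VolumeSeries:
        """Regenerate subject i's 4D resting-state series."""
        spec = self.spec
        rng = np.random.default_rng([spec.rng_seed, 3, i])
        dims = spec.grid_dims
        T = spec.n_timepoints
        data = rng.standard_normal(dims + (T,)) * spec.noise_sd
        s = _bandlimited_signal(rng, T, spec.tr_seconds, spec.band_low_hz, spec.band_high_hz)
        data[self.truth["seed_mask"]] += spec.seed_amp * s
        for k, tmpl in enumerate(spec.network_templates):
            data[tmpl] += self.truth["coupling"][i, k] * s
        # motion artifact: a linear mixture of the 6 motion traces added to a
        # random 10% of voxels; lies exactly in the span of the nuisance design
        flat = data.reshape(-1, T)
        n_vox = flat.shape[0]
        idx = rng.choice(n_vox, max(1, n_vox // 10), replace=False)
        w = rng.standard_normal(6)
        art = self.motion[i] @ w
        scale = art.std()
        if scale > 0:
            art = art / scale * spec.artifact_sd
        flat[idx] += art
        return VolumeSeries(data, spec.voxel_size_mm, spec.tr_seconds)

    @property
    def volumes(self) -> list[VolumeSeries]:
        """Materialize every subject's series (small cohorts only)."""
        return [self.series(i) for i in range(self.spec.n_subjects)]

    @property
    def n_subjects(self) -> int:
        return self.spec.n_subjects


def generate_imaging(spec: CohortSpec, clinical: pd.DataFrame) -> SyntheticCohort:
    """Imaging arm of the cohort, consistent with a previously generated clinical table.

    Network-k coupling for subject i is ``coupling_base + coupling_sd * w_ik``
    where ``w_ik = r_k * s~_ik + sqrt(1-r_k^2) * eta_ik``, s~ the designated
    subscale standardized by its population moments and eta an independent
    standard normal, so corr(w, subscale) = r_k in population.  DAT region
    values carry the group effect ``dat_effect`` at the seed-containing
    region (ipsilateral putamen) and correlate with the mean standardized
    coupling at ``dat_sfc_corr`` (default 0: DAT independent of SFC).
    """
    if len(clinical) != spec.n_subjects:
        raise ValueError(
            f"clinical table has {len(clinical)} rows but spec.n_subjects={spec.n_subjects}"
        )
    n = spec.n_subjects
    K = len(spec.network_templates)
    seed_mask = spec.seed_mask

    # population-standardized subscales
    names = list(UPDRS_MARGINALS)
    std_scores = np.empty((n, 3))
    for j, name in enumerate(names):
        mu, sd = score_population_moments(*UPDRS_MARGINALS[name])
        std_scores[:, j] = (clinical[name].to_numpy(float) - mu) / sd

    coupling_w = np.empty((n, K))
    for i in range(n):
        rng_i = np.random.default_rng([spec.rng_seed, 4, i])
        eta = rng_i.standard_normal(K)
        for k in range(K):
            r = spec.coupling_effects[k]
            coupling_w[i, k] = r * std_scores[i, spec.coupling_subscales[k]] + np.sqrt(1 - r**2) * eta[k]
    coupling = spec.coupling_base + spec.coupling_sd * coupling_w

    motion = [
        _simulate_motion(np.random.default_rng([spec.rng_seed, 2, i]), spec.n_timepoints, spec.motion_step_mm)
        for i in range(n)
    ]

    # DAT region SBR values (patients)
    mean_w = coupling_w.mean(axis=1) if K else np.zeros(n)
    rho = spec.dat_sfc_corr
    dat_cols = {}
    rng_dat = np.random.default_rng([spec.rng_seed, 5])
    for region in _DAT_REGIONS:
        eff = spec.dat_effect if region == SEED_DAT_REGION else _DAT_SPREAD * spec.dat_effect
        xi = rng_dat.standard_normal(n)
        e = rho * mean_w + np.sqrt(max(0.0, 1 - rho**2)) * xi
        dat_cols[region] = _DAT_BASE[region] + eff + _DAT_SD * e
    dat_regions = pd.DataFrame(dat_cols)
    dat_regions.insert(0, "subject", clinical["subject"].to_numpy())

    # 3D DAT maps: anatomical base + striatal box, PD reduction peaking at the seed
    dims = spec.grid_dims
    cx, cy, cz = spec.seed_center
    box = np.zeros(dims, dtype=bool)
    box[
        max(cx - 2, 0) : cx + 3,
        max(cy - 2, 0) : cy + 3,
        max(cz - 2, 0) : cz + 3,
    ] = True
    base = np.full(dims, 0.8)
    base[box] += 1.2
    effect_map = np.zeros(dims)
    effect_map[box] = 0.5 * spec.dat_effect
    effect_map[seed_mask] = spec.dat_effect

    rng_maps = np.random.default_rng([spec.rng_seed, 6])
    dat_maps = (base + effect_map)[None] + rng_maps.normal(0.0, 0.15, (n,) + dims)
    dat_maps = dat_maps.astype(np.float32)
    n_hc = spec.n_controls
    dat_maps_control = base[None] + rng_maps.normal(0.0, 0.15, (n_hc,) + dims)
    dat_maps_control = dat_maps_control.astype(np.float32)

    # GMV maps: planted null (no group difference)
    gmv_base = np.full(dims, 0.6)
    gmv_maps = (gmv_base[None] + rng_maps.normal(0.0, 0.08, (n,) + dims)).astype(np.float32)
    gmv_maps_control = (gmv_base[None] + rng_maps.normal(0.0, 0.08, (n_hc,) + dims)).astype(np.float32)

    rng_hc = np.random.default_rng([spec.rng_seed, 7])
    control_covariates = pd.DataFrame(
        {
            "subject": [f"HC{i:04d}" for i in range(n_hc)],
            "age": np.clip(np.rint(rng_hc.normal(61.0, 10.5, n_hc)), 38, 85).astype(int),
            "sex": (rng_hc.random(n_hc) < 63 / 198).astype(int),
            "tiv_ml": rng_hc.normal(1500.0, 120.0, n_hc),
        }
    )

    truth = {
        "striatal_mask": box,
        "coupling": coupling,
        "coupling_w": coupling_w,
        "coupling_effects": np.asarray(spec.coupling_effects, float),
        "coupling_subscales": np.asarray(spec.coupling_subscales, int),
        "templates": spec.network_templates,
        "seed_mask": seed_mask,
        "std_scores": std_scores,
    }
    return SyntheticCohort(
        spec=spec,
        clinical=clinical,
        motion=motion,
        dat_regions=dat_regions,
        dat_maps=dat_maps,
        dat_maps_control=dat_maps_control,
        gmv_maps=gmv_maps,
        gmv_maps_control=gmv_maps_control,
        control_covariates=control_covariates,
        truth=truth,
    )


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Clinical + imaging arms in one call."""
    return generate_imaging(spec, generate_clinical(spec))


def write_cohort(cohort: SyntheticCohort, out_dir, write_series: bool = False) -> None:
    """Persist a cohort: TSV tables, whitespace motion files, NIfTI maps.

    4D series are written only on request (they can be regenerated from the
    spec and are large).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    cohort.dat_regions.to_csv(out / "dat_regions.tsv", sep="\t", index=False)
    cohort.control_covariates.to_csv(out / "control_covariates.tsv", sep="\t", index=False)
    mdir = out / "motion"
    mdir.mkdir(exist_ok=True)
    for i, m in enumerate(cohort.motion):
        np.savetxt(mdir / f"{cohort.clinical['subject'].iloc[i]}_motion.txt", m, fmt="%.6f")
    vox = cohort.spec.voxel_size_mm
    ddir = out / "dat"
    ddir.mkdir(exist_ok=True)
    for i in range(cohort.n_subjects):
        write_volume(VolumeMap(cohort.dat_maps[i].astype(np.float64), vox), ddir / f"PD{i:04d}_dat.nii.gz")
    if write_series:
        sdir = out / "rest"
        sdir.mkdir(exist_ok=True)
        for i in range(cohort.n_subjects):
            write_volume(cohort.series(i), sdir / f"PD{i:04d}_rest.nii.gz")
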