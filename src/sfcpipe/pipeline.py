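"""End-to-end driver: simulate -> seed selection -> connectivity -> cluster
inference -> eigenvariates -> cross-modal statistics -> Bayesian network.

Each stage writes its outputs into the run directory (TSV tables with
documented headers, NIfTI label maps, a DOT graph) and a machine-readable
``summary.json`` records every threshold and seed, so any stage can be
re-run or audited in isolation.  Runs are deterministic given ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusterstats, eigen, groupglm, simulate, xmstats
from .bayesnet import TPDA
from .connectivity import preprocess_series, sfc_map
from .volumes import VolumeMap, gaussian_smooth, write_volume

__all__ = ["RunConfig", "run_full", "compute_sfc_maps"]

logger = logging.getLogger(__name__)

COVARIATE_COLS = ["age", "sex", "dominant_side", "on_levodopa", "on_agonist", "on_other"]
DEMOGRAPHIC_CONTROLS = ["age", "sex", "on_levodopa", "on_agonist", "on_other"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run; every field has a default.

    ``cohort`` collects overrides for the synthetic-cohort spec (field names
    of :class:`sfcpipe.simulate.CohortSpec`).
    """

    out_dir: str = "sfc_run"
    rng_seed: int = 0
    cohort: dict = field(default_factory=dict)
    smooth_fwhm_mm: float = 8.0
    voxel_p: float = 0.01
    cluster_alpha: float = 0.05
    fwe_alpha: float = 0.05
    n_perm: int = 1000
    seed_from_group_glm: bool = True
    group_glm_n_perm: int = 200
    mode: str = "joint"  # 'joint' (all subscales in one model) or 'single'
    bn_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("voxel_p", "cluster_alpha", "fwe_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100 for reported runs")
        if self.mode not in ("joint", "single"):
            raise ValueError("mode must be 'joint' or 'single'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def cohort_spec(self) -> simulate.CohortSpec:
        kwargs = dict(self.cohort)
        kwargs.setdefault("rng_seed", self.rng_seed)
        return simulate.CohortSpec(**kwargs)


def compute_sfc_maps(cohort: simulate.SyntheticCohort, seed, smooth_fwhm_mm: float = 8.0) -> np.ndarray:
    """Stream every subject through smoothing + nuisance chain + seed correlation.

    Returns the stacked Fisher-z maps (n_subjects, x, y, z); series are
    regenerated per subject and discarded, so memory stays flat in n.
    """
    spec = cohort.spec
    maps = np.empty((cohort.n_subjects,) + spec.grid_dims)
    for i in range(cohort.n_subjects):
        series = cohort.series(i)
        if smooth_fwhm_mm > 0:
            series = gaussian_smooth(series, smooth_fwhm_mm)
        series = preprocess_series(series, cohort.motion[i], spec.band_low_hz, spec.band_high_hz)
        maps[i] = sfc_map(series, seed).data
    return maps


def _stage(summary: dict, name: str):
    summary["stages"].append(name)
    logger.info("stage: %s", name)


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the summary dict (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": config.to_dict(), "stages": [], "errors": None}
    try:
        rng = np.random.default_rng(config.rng_seed)

        _stage(summary, "simulate")
        spec = config.cohort_spec()
        cohort = simulate.generate_cohort(spec)
        simulate.write_cohort(cohort, out / "cohort")
        summary["n_subjects"] = spec.n_subjects

        _stage(summary, "seed")
        if config.seed_from_group_glm:
            diag = np.concatenate([np.ones(spec.n_subjects), np.zeros(spec.n_controls)])
            age = np.concatenate(
                [cohort.clinical["age"].to_numpy(float), cohort.control_covariates["age"].to_numpy(float)]
            )
            sex = np.concatenate(
                [cohort.clinical["sex"].to_numpy(float), cohort.control_covariates["sex"].to_numpy(float)]
            )
            dat_stack = np.concatenate([cohort.dat_maps, cohort.dat_maps_control]).astype(float)
            design = groupglm.GroupDesign(diagnosis=diag, covariates=np.column_stack([age, sex]))
            res = groupglm.GroupGLM(dat_stack, design).fit()
            seed = res.seed_peak(cohort.truth["striatal_mask"])
            sig_dat, _ = res.voxel_fwe(alpha=config.fwe_alpha, n_perm=config.group_glm_n_perm, rng=rng)
            # GMV comparison with total intracranial volume controlled: a null in
            # the synthetic cohorts (no atrophy is planted)
            tiv = np.concatenate(
                [cohort.clinical["tiv_ml"].to_numpy(float), cohort.control_covariates["tiv_ml"].to_numpy(float)]
            )
            gmv_stack = np.concatenate([cohort.gmv_maps, cohort.gmv_maps_control]).astype(float)
            gmv_design = groupglm.GroupDesign(diagnosis=diag, covariates=np.column_stack([age, sex, tiv]))
            gmv_res = groupglm.GroupGLM(gmv_stack, gmv_design).fit()
            sig_gmv, _ = gmv_res.voxel_fwe(alpha=config.fwe_alpha, n_perm=config.group_glm_n_perm, rng=rng)
            summary["group_glm"] = {
                "dof": int(res.statmap.dof),
                "peak": list(map(int, seed.center_voxel)),
                "n_fwe_voxels_dat": int(sig_dat.sum()),
                "n_fwe_voxels_gmv": int(sig_gmv.sum()),
            }
        else:
            seed = spec.seed
        summary["seed"] = {"center_voxel": list(map(int, seed.center_voxel)), "radius_mm": seed.radius_mm}

        _stage(summary, "connectivity")
        maps = compute_sfc_maps(cohort, seed, config.smooth_fwhm_mm)

        _stage(summary, "clusters")
        covars = cohort.clinical[COVARIATE_COLS]
        if config.mode == "joint":
            designs = {"joint": clusterstats.RegressionDesign(cohort.clinical[["updrs1", "updrs2", "updrs3"]], covars)}
        else:
            designs = {
                name: clusterstats.RegressionDesign(cohort.clinical[[name]], covars)
                for name in ("updrs1", "updrs2", "updrs3", "updrs_total")
            }
        cluster_rows = []
        eigens: dict[str, np.ndarray] = {}
        for dname, design in designs.items():
            res = clusterstats.SFCRegression(maps, design, voxel_size_mm=spec.voxel_size_mm).fit()
            tables, null = res.cluster_fwe(
                voxel_p=config.voxel_p,
                cluster_alpha=config.cluster_alpha,
                n_perm=config.n_perm,
                rng=rng,
            )
            for reg, ct in tables.items():
                labels_img = VolumeMap(ct.labels.astype(np.float64), spec.voxel_size_mm)
                write_volume(labels_img, out / f"clusters_{dname}_{reg}.nii.gz")
                for _, row in ct.table.iterrows():
                    cluster_rows.append({"model": dname, "regressor": reg, **row.to_dict()})
                sig = ct.significant(config.cluster_alpha)
                if len(sig):
                    _stage(summary, f"eigen[{dname}/{reg}]")
                for cid in sig["cluster_id"]:
                    ev = eigen.extract_eigenvariate(
                        maps, ct.voxels(int(cid)), covariates=covars.to_numpy(float), cluster_id=int(cid)
                    )
                    eigens[f"sfc_{reg}_c{int(cid)}"] = ev.scores
        cluster_df = pd.DataFrame(cluster_rows)
        cluster_df.to_csv(out / "clusters.tsv", sep="\t", index=False)
        summary["n_significant_clusters"] = int(
            (cluster_df["p_fwe"] <= config.cluster_alpha).sum() if len(cluster_df) else 0
        )
        eig_df = pd.DataFrame(eigens)
        eig_df.insert(0, "subject", cohort.clinical["subject"].to_numpy())
        eig_df.to_csv(out / "eigenvariates.tsv", sep="\t", index=False)

        _stage(summary, "crossmodal")
        merged = cohort.clinical.merge(cohort.dat_regions, on="subject").merge(eig_df, on="subject")
        controls = merged[DEMOGRAPHIC_CONTROLS].to_numpy(float)
        xm_rows = []
        dat_cols = [c for c in merged.columns if c.startswith("dat_")]
        sfc_cols = [c for c in merged.columns if c.startswith("sfc_")]
        for target in ("updrs1", "updrs2", "updrs3"):
            for other in dat_cols + sfc_cols:
                pr = xmstats.partial_correlation(
                    merged[target], merged[other], controls, control_names=DEMOGRAPHIC_CONTROLS
                )
                xm_rows.append(
                    {"x": target, "y": other, "r": pr.r, "p": pr.p, "n": pr.n, "controls": "demographics"}
                )
        xm_df = pd.DataFrame(xm_rows)
        xm_df.to_csv(out / "partial_correlations.tsv", sep="\t", index=False)
        summary["crossmodal_pairs"] = len(xm_df)

        _stage(summary, "bayes_net")
        bn_cols = ["updrs1", "updrs2", "updrs3"] + dat_cols + sfc_cols
        if len(bn_cols) >= 3 and len(merged) >= 30:
            bn = TPDA(merged[bn_cols]).fit(alpha=config.bn_alpha)
            bn.graph.edge_table().to_csv(out / "bn_edges.tsv", sep="\t", index=False)
            (out / "bn_graph.dot").write_text(bn.graph.to_dot())
            summary["bn_edges"] = len(bn.graph.edges)
        else:
            summary["bn_edges"] = None

        summary["ok"] = True
    except Exception as exc:  # persist partial outputs, name the failing stage
        summary["ok"] = False
        stage = summary["stages"][-1] if summary["stages"] else "init"
        summary["errors"] = f"stage {stage}: {exc}"
        (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(summary["errors"]) from exc
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
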