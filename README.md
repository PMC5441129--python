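# sfcpipe

Striatal functional connectivity (SFC) analysis for Parkinson's disease
cohorts: seed-based resting-state connectivity mapping, permutation
cluster-extent inference adjusted for non-stationary smoothness, cluster
eigenvariate extraction, cross-modal partial-correlation / mediation /
Steiger statistics, and Bayesian-network structure learning — together with
a synthetic cohort simulator that makes the whole chain runnable and
testable without access to patient data.

## Who it is for

Researchers analysing resting-state fMRI of de novo Parkinson's disease
alongside DAT-SPECT striatal binding ratios (SBR) and MDS-UPDRS clinical
scores, and methodologists who want a permutation-based, assumption-light
re-implementation of the classic SPM-style analysis chain on which such
studies rest.

## The model

Per subject, the pipeline computes a Fisher-z seed connectivity map

  z(v) = atanh( corr( x_v , s̄ ) ),

where s̄ is the mean time course of a 5 mm spherical striatal seed and x_v
each voxel's series after 24-parameter motion regression (6 motion
parameters, their backward-difference accelerations, the squares of both),
linear detrending, and an ideal 0.01–0.08 Hz bandpass.

At the group level, z maps are regressed voxel-wise on UPDRS subscales
(controlling age, sex, dominant side and medication flags), thresholded at
voxel p < 0.01 one-sided (negative direction), and clusters are tested by a
permutation null of the maximum *smoothness-normalized* cluster extent: a
cluster's extent is its resel count, Σ_v voxel-volume / Π_axis FWHM_axis(v),
with local FWHM estimated from spatial derivatives of standardized
residuals. Exact cluster p-values are (1 + #{null ≥ extent})/(1 + n_perm).
Significant clusters are summarized per subject by their covariate-adjusted
first singular component (eigenvariate), which then enters partial
correlations against clinical scores and SBR values, a significance-based
mediation rule, Steiger's z-test for dependent correlations, and TPDA
(three-phase dependency) Bayesian-network structure learning with Gaussian
conditional mutual information.

The synthetic cohort generator plants this exact structure — integer UPDRS
scores with inter-subscale correlations 0.56/0.33/0.46, network couplings
of −0.46 (UPDRS II) and −0.42 (UPDRS III), a DAT reduction at the seed
region independent of connectivity — so every stage has a ground truth.
See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
from sfcpipe import (CohortSpec, generate_cohort, compute_sfc_maps,
                     RegressionDesign, SFCRegression, extract_eigenvariate,
                     partial_correlation)

spec = CohortSpec(n_subjects=87, grid_dims=(12, 12, 12), rng_seed=7)
cohort = generate_cohort(spec)
maps = compute_sfc_maps(cohort, spec.seed)          # (87, 12, 12, 12) Fisher-z

covars = cohort.clinical[["age", "sex", "dominant_side",
                          "on_levodopa", "on_agonist", "on_other"]]
design = RegressionDesign(cohort.clinical[["updrs2"]], covars)
res = SFCRegression(maps, design, voxel_size_mm=3.0).fit()
tables, null = res.cluster_fwe(n_perm=500, rng=np.random.default_rng(0))
print(tables["updrs2"].table[["extent_voxels", "extent_resels", "peak_t", "p_fwe"]])

ct = tables["updrs2"]
cid = int(ct.significant()["cluster_id"].iloc[0])
ev = extract_eigenvariate(maps, ct.voxels(cid), covariates=covars.to_numpy(float))
pr = partial_correlation(ev.scores, cohort.clinical["updrs2"], covars.to_numpy(float))
print(f"eigenvariate vs UPDRS II: r = {pr.r:.2f}, p = {pr.p:.2g}, n = {pr.n}")
```

Output:

```
   extent_voxels  extent_resels    peak_t     p_fwe
0            129       4.910781  4.654907  0.003992
1              3       0.182739  2.614139  0.824351
2              4       0.377875  3.106588  0.556886
3              5       0.711217  2.584616  0.261477
4              2       0.232258  2.542004  0.748503
5              3       0.107390  2.651963  0.912176
eigenvariate vs UPDRS II: r = -0.44, p = 4.2e-05, n = 87
```

The 129-voxel cluster (4.9 resels, exact permutation p ≈ 0.004) sits on the
planted UPDRS II network template; the remaining small clusters are noise
and stay non-significant. Its eigenvariate correlates with UPDRS II at
r = −0.44, close to the planted population coupling of −0.46.

An end-to-end driver (simulate → seed selection via the DAT group GLM →
connectivity → cluster inference → eigenvariates → cross-modal statistics →
Bayesian network) is available as `sfcpipe.run_full(RunConfig(...))` or from
the shell:

```
ppmi-sfc full --out run1 --seed 0
ppmi-sfc validity --n-subjects 60 --n-perm 500
```

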