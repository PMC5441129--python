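# Methods

This note describes the models and procedures `sfcpipe` implements, the
choices made where a design question was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## Scientific setting

In de novo Parkinson's disease, loss of dopaminergic projections into the
striatum (measured by DAT-SPECT striatal binding ratios, SBR) and
desynchronization of striato-cortical resting-state coupling (striatal
functional connectivity, SFC) are candidate substrates of clinical symptom
severity as scored by the MDS-UPDRS subscales (part I: non-motor
experiences; part II: motor aspects of daily living; part III: clinician
motor exam). The pipeline asks three questions: which brain networks'
coupling to a striatal seed tracks each subscale; whether SFC explains
symptom variance beyond dopaminergic loss (partial correlation and a
significance-based mediation rule); and what directed dependence structure
links the imaging and clinical variables (Bayesian-network structure
learning).

## Connectivity model

Per subject, the 4D series is smoothed (8 mm FWHM Gaussian, replicate-edge
handling), then passed through a fixed nuisance chain:

1. **24-parameter motion regression** — OLS residualization on the 6 motion
   parameters, their backward-difference accelerations (leading element 0),
   and the squares of both, plus an intercept.
2. **Linear detrend** per voxel.
3. **Ideal bandpass** keeping DFT bins with 0.01 Hz ≤ f ≤ 0.08 Hz (DC
   always removed).

The order (motion → detrend → bandpass → correlation) is fixed; the chain
is invariant to adding any linear combination of nuisance columns to the
input. Whether to smooth the series before correlation (rather than only
the statistical maps) is exposed as a flag; the default smooths the series.

The seed is a 5 mm-radius sphere around a striatal peak voxel; membership
is by center-to-center Euclidean distance (19 voxels on a 3 mm grid). The
SFC map is the Fisher z = atanh(r) of each voxel's Pearson correlation with
the unweighted mean seed time course; |r| is clamped at 1 − 1e−12 (z caps
near 13.9) and zero-variance voxels get z = 0 with a logged count.

## Seed selection

The seed peak is the voxel maximizing the control-minus-patient t
statistic of a voxel-wise GLM on DAT-SPECT maps (diagnosis + age + sex),
restricted to a striatal mask; ties break lexicographically. Voxel-wise
family-wise error uses a permutation max-T procedure (group labels
permuted, null of the maximum t over the mask) rather than parametric
random-field correction — distribution-free and exact under
exchangeability. The same GLM machinery serves the gray-matter-volume
comparison, where the synthetic cohorts plant a true null.

## Cluster inference with non-stationarity adjustment

SFC maps are regressed voxel-wise on UPDRS scores (parts I, II, III jointly,
or single subscales/total), controlling age, sex, dominant side and three
binary medication flags, tested one-sided for negative association. Voxels
with p < 0.01 (t threshold at the model dof) form clusters under
18-connectivity (6/26 available).

Cluster extent is normalized by locally estimated smoothness so inference
stays valid when smoothness varies across the volume: residual images are
variance-normalized per voxel; for each axis, the mean squared forward
difference (per mm) of the normalized residuals estimates the second
spectral moment Λ, and FWHM = sqrt(4 ln 2 / Λ). The resels-per-voxel (RPV)
map is voxel volume divided by the product of per-axis FWHMs, and a
cluster's normalized extent is the sum of RPV over its voxels (its resel
count). Edge voxels inherit the last interior derivative; voxels without a
usable derivative take the in-mask median FWHM; zero-variance voxels are
excluded (RPV 0).

Family-wise error over clusters is controlled by permutation: the clinical
regressors of interest are reassigned to scans jointly (preserving
inter-subscale correlation; covariates stay attached to the imaging rows),
the model is refit, and each permutation contributes the maximum resel
extent across all tested contrasts. Observed clusters get exact
p = (1 + #{null max ≥ extent}) / (1 + n_perm). The RPV map is estimated
once from the observed-model residuals and reused across permutations:
residual smoothness does not depend on the regressor labels to first
order, and re-estimating it per permutation would only add Monte-Carlo
noise. This permutation construction replaces the parametric
non-stationary cluster correction of standard packages; it targets the
same quantity (smoothness-normalized extent) without distributional
assumptions, and is the central methodological substitution in the
package.

**Validity check.** The empirical false-positive rate of the whole
procedure is measured by building the null from `n_perm` permutations and
scoring `n_eval` fresh reassignments against it (positive when exact
p ≤ 0.05), reported with an exact Clopper–Pearson 99% binomial CI. Fresh
reassignments (rather than re-ranking the null within itself) keep the
estimate honest — self-ranking gives ≈5% by construction.

## Eigenvariates

A cluster's per-subject summary is the subject-side first singular
component of its subjects × voxels matrix. Covariates of no interest are
residualized out of every voxel column (with intercept) before the
decomposition; with no covariates the raw matrix is decomposed. Because
singular vectors are sign-ambiguous, scores are sign-fixed to correlate
positively with the cluster's mean signal. A single-voxel cluster
degenerates to the (adjusted) voxel values. A leave-one-out predicted-r²
utility (closed form via the hat matrix) quantifies out-of-sample
prediction of clinical scores.

## Cross-modal statistics

*Partial correlation*: Pearson correlation of OLS residuals of both
variables on [intercept | controls]; p from t = r·sqrt((n−2−k)/(1−r²)).
Listwise deletion mirrors cohorts whose modalities overlap incompletely.
*Mediation rule* (significance-based, α = 0.05): an initially significant
association that loses significance after adding the candidate mediator to
the controls is declared mediated; if it stays significant the association
is independent of the mediator; no effect decomposition is attempted.
*Steiger's z* compares two dependent correlations sharing one variable:
both are Fisher-z transformed and their covariance is taken from the
Dunn–Clark formula at the pooled mean correlation. p-values are reported
uncorrected (small families of planned comparisons); a Holm helper is
provided, and the 0.05 ≤ p < 0.10 band is flagged as marginal.

## Bayesian-network structure learning (TPDA)

Dependency strength between continuous variables is Gaussian conditional
mutual information, CMI = −0.5·ln(1 − ρ²) with ρ the partial correlation
given the conditioning set; significance comes from the Fisher-z test of ρ,
replacing the absolute CMI threshold of the original discrete formulation
with a sample-size-aware test. The three phases: draft (rank marginally
dependent pairs by MI; add an edge when no open path already connects the
pair), thicken (add deferred pairs that no cut set separates), thin
(retest every edge whose endpoints stay connected without it). The
cut-set search conditions on path-adjacent neighbours, searched
exhaustively in deterministic (size, lexicographic) order — exact for the
≤ 10-variable problems this package addresses, where the original greedy
heuristic would only save negligible time. Orientation: collider detection
from recorded cut sets, then Meek propagation; unresolved or conflicting
directions are reported as bidirected. Edge strength is the determination
coefficient R² of the joined variables. Monotone faithfulness is assumed,
as in TPDA generally. Note the false-edge rate over independent variables
is governed by α: with m testable pairs the empty-graph probability is
≈ (1−α)^m, so exact nulls should be tested at small α.

## Synthetic cohorts: what they emulate

The generator produces the statistical structure the analysis assumes,
with defaults fixed at the study conditions the pipeline is designed
around:

* **Clinical scores** — a latent Gaussian with inter-subscale correlations
  (I,II) = 0.56, (I,III) = 0.33, (II,III) = 0.46 is quantile-mapped
  through truncated normals (part I: 6.9 ± 5.1 on [0,23]; II: 6.8 ± 4.7 on
  [1,23]; III: 19.8 ± 10.0 on [6,47]) and rounded. The map is strictly
  monotone before rounding, so rank correlations survive and Pearson
  attenuation is below 0.01. Totals are sums of parts by construction.
  Age, sex, dominant side and three medication flags follow the cohort
  frequencies and are independent of the scores.
* **Imaging** — 20×20×20 voxels at 3 mm, 150 timepoints at TR 2.4 s, unit
  Gaussian noise. A band-limited unit-variance seed signal enters a 5 mm
  seed sphere at amplitude 3 and each disjoint network template at the
  subject's coupling strength (0.45 ± 0.12 across subjects), putting
  per-voxel seed correlations in the 0.3–0.6 range typical of strong seed
  maps before smoothing. Default templates scale with the grid to occupy
  roughly 5% of the volume (384 voxels at 20³), matching the proportion
  cortico-cerebellar SFC networks occupy relative to a gray-matter mask;
  the recovered eigenvariate–score correlation then runs about 5% below
  the planted population coupling, a floor set by per-subject SNR
  fluctuation over the ~50 within-band degrees of freedom at 150
  timepoints rather than by template size. Coupling for network k is affine in the
  designated subscale, standardized by its population moments (computed by
  quadrature over the latent), so the population correlation equals the
  configured effect exactly: −0.46 for the UPDRS II network and −0.42 for
  the UPDRS III network by default. A linear mixture of the six simulated
  motion traces is added to a random 10% of voxels; it lies exactly in the
  span of the 24-parameter design, so the nuisance regression removes it
  completely — a positive control for the motion model.
* **DAT-SPECT** — four region SBR values (ipsi/contralateral putamen and
  caudate at healthy means 2.0–2.9, SD 0.35) with a group reduction of 0.8
  at the seed-containing region (ipsilateral putamen, 60% of it
  elsewhere), and 3D maps with the reduction peaking in the seed sphere.
  The DAT signal is independent of the connectivity coupling by default
  (`dat_sfc_corr = 0`), encoding the dissociation hypothesis as ground
  truth.
* **GMV** — maps with no group difference: a planted null for the
  atrophy comparison.

Per-subject RNG streams derive from the cohort seed by fixed offsets, so
any subject's series can be regenerated on demand (cohorts stream through
the connectivity stage with flat memory) and cohorts are reproducible
under subsetting.

**What passing tests do not show.** The simulator has no scanner drift,
physiological noise spectra, multi-site effects, spatial anatomy, or
registration error; smoothness is spatially homogeneous except where
smoothing interacts with the mask edge. Calibration results (e.g. the ~5%
cluster false-positive rate) therefore validate the inference machinery
under exchangeability, not robustness to the full noise structure of real
resting-state data.

## Numerical choices

* Smoothing sigma = FWHM / (2√(2 ln 2)) per axis, replicate-nearest edges.
* Gray-matter mask threshold is strict (> 0.2).
* |r| clamp 1 − 1e−12 before atanh; acceleration = backward difference
  with leading 0; rank-deficient designs drop dependent columns with a
  logged warning (intercept and diagnosis protected in group GLMs).
* Cluster connectivity default 18; one-sided (negative) inference only.
* Exact permutation p-values use the (1 + count)/(1 + n) estimator and are
  bounded below by 1/(n_perm + 1).
* Seed-peak and drafting-phase ties break lexicographically.
* Problem sizes for the shipped calibration suites: null-cohort validity
  runs 60 subjects on a 20³ grid with 500–2000 permutations; coupling
  recovery runs 1000 subjects on the default grid; structure-learning
  quality uses 6-node linear-Gaussian graphs at n = 2000.

## Known limitations

* The permutation cluster null assumes exchangeability of subjects under
  the regressor reassignment; covariate effects are retained in the
  imaging rows rather than re-estimated per permutation (no
  Freedman–Lane refinement).
* The smoothness estimator is biased upward by a few percent at kernel
  widths near the voxel size (forward differences under-resolve the
  autocorrelation); this cancels in the cluster inference because observed
  and null extents share the same RPV map.
* The mediation rule is purely significance-based and inherits its
  dichotomies; it is not an effect decomposition.
* TPDA orientation can return bidirected edges wherever colliders and
  propagation leave direction unresolved; with few variables and strong
  correlations this is common and expected.
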