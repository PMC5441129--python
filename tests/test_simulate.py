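import numpy as np
import pandas as pd
import pytest

from sfcpipe import CohortSpec, generate_clinical, generate_cohort, generate_imaging
from sfcpipe.simulate import UPDRS_MARGINALS, score_population_moments


class TestCohortSpec:
    def test_non_psd_correlation_rejected_with_eigenvalue(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            CohortSpec(updrs_corr=bad)

    def test_template_overlapping_seed_rejected(self):
        tmpl = np.zeros((12, 12, 12), dtype=bool)
        tmpl[5:8, 5:8, 5:8] = True  # contains the mid-grid seed
        with pytest.raises(ValueError, match="overlaps the seed"):
            CohortSpec(grid_dims=(12, 12, 12), network_templates=[tmpl], coupling_effects=(-0.4,), coupling_subscales=(1,))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="n_timepoints"):
            CohortSpec(n_timepoints=32)


class TestClinicalGenerator:
    def test_total_is_sum_of_parts(self):
        clin = generate_clinical(CohortSpec(n_subjects=200, rng_seed=3))
        np.testing.assert_array_equal(
            clin["updrs_total"], clin["updrs1"] + clin["updrs2"] + clin["updrs3"]
        )

    def test_scores_respect_ranges(self):
        clin = generate_clinical(CohortSpec(n_subjects=500, rng_seed=4))
        for name, (_, _, lo, hi) in UPDRS_MARGINALS.items():
            assert clin[name].between(lo, hi).all()

    def test_independence_under_identity_correlation(self):
        spec = CohortSpec(n_subjects=2000, updrs_corr=np.eye(3), rng_seed=5)
        clin = generate_clinical(spec)
        r = clin[["updrs1", "updrs2", "updrs3"]].corr().to_numpy()
        off = r[~np.eye(3, dtype=bool)]
        assert np.all(np.abs(off) < 0.08)

    def test_planted_correlations_recovered_within_3_se(self):
        spec = CohortSpec(n_subjects=5000, rng_seed=6)
        clin = generate_clinical(spec)
        r = clin[["updrs1", "updrs2", "updrs3"]].corr().to_numpy()
        n = 5000
        for (i, j) in [(0, 1), (0, 2), (1, 2)]:
            target = spec.updrs_corr[i, j]
            se = (1 - target**2) / np.sqrt(n)
            assert abs(r[i, j] - target) < 3 * se + 0.01  # small copula attenuation allowance

    def test_marginal_moments_near_table_values(self):
        clin = generate_clinical(CohortSpec(n_subjects=5000, rng_seed=8))
        for name, (mu, sd, lo, hi) in UPDRS_MARGINALS.items():
            pop_mu, pop_sd = score_population_moments(mu, sd, lo, hi)
            assert clin[name].mean() == pytest.approx(pop_mu, abs=4 * pop_sd / np.sqrt(5000))
            assert clin[name].std() == pytest.approx(pop_sd, rel=0.05)

    def test_reproducible_under_seed(self):
        a = generate_clinical(CohortSpec(n_subjects=50, rng_seed=9))
        b = generate_clinical(CohortSpec(n_subjects=50, rng_seed=9))
        pd.testing.assert_frame_equal(a, b)


class TestImagingGenerator:
    def test_clinical_row_count_checked(self):
        spec = CohortSpec(n_subjects=10, grid_dims=(12, 12, 12), rng_seed=1)
        clin = generate_clinical(spec).iloc[:5]
        with pytest.raises(ValueError, match="rows"):
            generate_imaging(spec, clin)

    def test_subject_streams_stable_under_subsetting(self):
        kw = dict(grid_dims=(12, 12, 12), n_timepoints=64, n_controls=4, rng_seed=11)
        small = generate_cohort(CohortSpec(n_subjects=4, **kw))
        large = generate_cohort(CohortSpec(n_subjects=8, **kw))
        np.testing.assert_array_equal(small.motion[2], large.motion[2])
        np.testing.assert_allclose(
            small.truth["coupling"][2], large.truth["coupling"][2], atol=1e-12
        )
        np.testing.assert_allclose(small.series(2).data, large.series(2).data, atol=1e-12)

    def test_noiseless_limit_seed_template_correlation(self):
        spec = CohortSpec(
            n_subjects=4, grid_dims=(12, 12, 12), n_timepoints=64,
            noise_sd=1e-8, artifact_sd=0.0, coupling_base=1.0, coupling_sd=0.0,
            n_controls=4, rng_seed=12,
        )
        cohort = generate_cohort(spec)
        series = cohort.series(0)
        seed_tc = series.data[spec.seed_mask].mean(axis=0)
        tmpl_voxel = series.data[spec.network_templates[0]][0]
        r = np.corrcoef(seed_tc, tmpl_voxel)[0, 1]
        assert abs(r) > 0.999

    def test_dat_independent_of_coupling_by_default(self):
        spec = CohortSpec(n_subjects=1000, grid_dims=(12, 12, 12), n_timepoints=64, n_controls=4, rng_seed=13)
        cohort = generate_cohort(spec)
        assert spec.dat_sfc_corr == 0.0
        r = np.corrcoef(
            cohort.dat_regions["dat_putamen_ipsi"], cohort.truth["coupling"][:, 0]
        )[0, 1]
        assert abs(r) < 0.07

    def test_dat_group_effect_at_seed_region(self):
        spec = CohortSpec(n_subjects=200, grid_dims=(12, 12, 12), n_timepoints=64, n_controls=200, rng_seed=14)
        cohort = generate_cohort(spec)
        seed_mask = cohort.truth["seed_mask"]
        pd_mean = cohort.dat_maps[:, seed_mask].mean()
        hc_mean = cohort.dat_maps_control[:, seed_mask].mean()
        assert pd_mean - hc_mean == pytest.approx(spec.dat_effect, abs=0.05)

    def test_null_coupling_uncorrelated_with_subscales(self):
        spec = CohortSpec(
            n_subjects=1000, grid_dims=(12, 12, 12), n_timepoints=64,
            coupling_effects=(0.0, 0.0), n_controls=4, rng_seed=15,
        )
        cohort = generate_cohort(spec)
        for k, sub in enumerate(["updrs2", "updrs3"]):
            r = np.corrcoef(cohort.truth["coupling"][:, k], cohort.clinical[sub])[0, 1]
            assert abs(r) < 0.09

    def test_planted_coupling_correlation_matches_target(self):
        spec = CohortSpec(n_subjects=5000, grid_dims=(12, 12, 12), n_timepoints=64, n_controls=4, rng_seed=16)
        cohort = generate_cohort(spec)
        for k, sub in enumerate(["updrs2", "updrs3"]):
            r = np.corrcoef(cohort.truth["coupling"][:, k], cohort.clinical[sub])[0, 1]
            assert r == pytest.approx(spec.coupling_effects[k], abs=0.04)
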