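import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from sfcpipe import (
    RegressionDesign,
    SFCRegression,
    StatMap,
    binomial_ci,
    fit_voxelwise_regression,
    form_clusters,
    local_smoothness,
)
from sfcpipe.volumes import FWHM_TO_SIGMA


def _maps(rng, n, dims=(6, 6, 6)):
    return rng.standard_normal((n,) + dims)


class TestVoxelwiseRegression:
    def test_single_regressor_matches_closed_form(self, rng):
        n = 30
        maps = _maps(rng, n)
        x = rng.standard_normal(n)
        sm = fit_voxelwise_regression(maps, RegressionDesign(pd.DataFrame({"x": x})))["x"]
        v = (2, 3, 1)
        y = maps[:, v[0], v[1], v[2]]
        r = np.corrcoef(x, y)[0, 1]
        t_simple = r * np.sqrt((n - 2) / (1 - r**2))
        assert sm.t[v] == pytest.approx(-t_simple, abs=1e-10)  # negative-direction convention
        assert sm.dof == n - 2

    def test_orthogonal_covariate_leaves_coefficient(self, rng):
        n = 40
        x = rng.standard_normal(n)
        c = rng.standard_normal(n)
        c -= c.mean() + x @ c / (x @ x) * x  # orthogonalize to x and intercept
        maps = _maps(rng, n, dims=(3, 3, 3))
        t_with = fit_voxelwise_regression(maps, RegressionDesign(pd.DataFrame({"x": x}), pd.DataFrame({"c": c})))["x"]
        t_without = fit_voxelwise_regression(maps, RegressionDesign(pd.DataFrame({"x": x})))["x"]
        # same coefficient => t differs only through dof/sigma; correlation near 1
        assert np.corrcoef(t_with.t.ravel(), t_without.t.ravel())[0, 1] > 0.999

    def test_row_permutation_preserves_t_multiset(self, rng):
        n = 25
        maps = _maps(rng, n, dims=(4, 4, 4))
        x = pd.DataFrame({"x": rng.standard_normal(n)})
        perm = rng.permutation(n)
        a = fit_voxelwise_regression(maps, RegressionDesign(x))["x"].t
        b = fit_voxelwise_regression(maps[perm], RegressionDesign(x.iloc[perm].reset_index(drop=True)))["x"].t
        np.testing.assert_allclose(np.sort(a.ravel()), np.sort(b.ravel()), atol=1e-8)

    def test_missing_rows_dropped_listwise(self, rng):
        n = 20
        maps = _maps(rng, n, dims=(3, 3, 3))
        x = rng.standard_normal(n)
        x_missing = x.copy()
        x_missing[[3, 7]] = np.nan
        sm = fit_voxelwise_regression(maps, RegressionDesign(pd.DataFrame({"x": x_missing})))["x"]
        keep = np.ones(n, bool)
        keep[[3, 7]] = False
        oracle = fit_voxelwise_regression(maps[keep], RegressionDesign(pd.DataFrame({"x": x[keep]})))["x"]
        np.testing.assert_allclose(sm.t, oracle.t, atol=1e-10)


class TestFormClusters:
    def _statmap(self, t):
        return StatMap(t, dof=40, mask=np.ones(t.shape, bool))

    def test_two_separated_blobs(self):
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 5.0
        t[5:7, 5:7, 5:7] = 5.0
        ct = form_clusters(self._statmap(t), voxel_p=0.01)
        assert len(ct) == 2
        assert sorted(ct.table["extent_voxels"]) == [8, 8]

    def test_corner_touch_18_vs_26_connectivity(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = 5.0
        t[1, 1, 1] = 5.0  # shares only a corner
        assert len(form_clusters(self._statmap(t), connectivity=18)) == 2
        assert len(form_clusters(self._statmap(t), connectivity=26)) == 1

    def test_edge_touch_joined_under_18(self):
        t = np.zeros((4, 4, 4))
        t[0, 0, 0] = 5.0
        t[1, 1, 0] = 5.0  # shares an edge
        assert len(form_clusters(self._statmap(t), connectivity=18)) == 1
        assert len(form_clusters(self._statmap(t), connectivity=6)) == 2

    def test_full_suprathreshold_mask_one_cluster(self):
        t = np.full((5, 5, 5), 9.0)
        ct = form_clusters(self._statmap(t))
        assert len(ct) == 1
        assert ct.table["extent_voxels"].iloc[0] == 125

    def test_empty_supra_set_gives_empty_table(self):
        ct = form_clusters(self._statmap(np.zeros((5, 5, 5))))
        assert len(ct) == 0

    def test_threshold_uses_dof(self):
        sm = self._statmap(np.zeros((3, 3, 3)))
        ct = form_clusters(sm, voxel_p=0.01)
        assert ct.t_threshold == pytest.approx(stats.t.ppf(0.99, 40))


class TestLocalSmoothness:
    def test_smoothed_noise_recovers_kernel_fwhm(self, rng):
        n, fwhm_mm, vox = 30, 8.0, 3.0
        sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vox
        R = np.stack(
            [ndimage.gaussian_filter(rng.standard_normal((20, 20, 20)), sigma_vox, mode="wrap") for _ in range(n)]
        )
        mask = np.ones((20, 20, 20), bool)
        sm = local_smoothness(R, mask, vox)
        assert sm.median_fwhm(mask) == pytest.approx(fwhm_mm, rel=0.15)

    def test_unsmoothed_noise_fwhm_near_voxel_size(self, rng):
        R = _maps(rng, 30, dims=(12, 12, 12))
        sm = local_smoothness(R, np.ones((12, 12, 12), bool), 3.0)
        med = sm.median_fwhm()
        assert 0.8 * 3.0 < med < 1.6 * 3.0

    def test_stationary_smoothness_preserves_extent_order(self, rng):
        R = _maps(rng, 40, dims=(10, 10, 10))
        sm = local_smoothness(R, np.ones((10, 10, 10), bool), 3.0)
        rpv = sm.rpv
        a = rpv[1:3, 1:3, 1:3].sum()   # 8 voxels
        b = rpv[5:8, 5:8, 5:8].sum()   # 27 voxels
        assert b > a  # larger voxel extent -> larger resel extent under ~constant smoothness
        assert rpv[rpv > 0].std() / rpv[rpv > 0].mean() < 0.8

    def test_zero_variance_voxel_excluded(self, rng):
        R = _maps(rng, 15, dims=(6, 6, 6))
        R[:, 2, 2, 2] = 0.0
        sm = local_smoothness(R, np.ones((6, 6, 6), bool), 3.0)
        assert sm.n_excluded == 1
        assert sm.rpv[2, 2, 2] == 0.0

    def test_too_few_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="10"):
            local_smoothness(_maps(rng, 5), np.ones((6, 6, 6), bool), 3.0)


class TestClusterFwe:
    def test_exact_p_bounded_below(self, rng):
        n = 30
        maps = _maps(rng, n, dims=(8, 8, 8))
        x = rng.standard_normal(n)
        maps[:, 2:5, 2:5, 2:5] -= 1.2 * x[:, None, None, None]  # strong planted association
        design = RegressionDesign(pd.DataFrame({"x": x}))
        res = SFCRegression(maps, design, voxel_size_mm=3.0).fit()
        tables, null = res.cluster_fwe(n_perm=99, rng=rng)
        ct = tables["x"]
        assert len(ct) >= 1
        assert ct.table["p_fwe"].min() >= 1 / 100
        sig = ct.significant()
        assert len(sig) >= 1

    def test_n_perm_floor_enforced(self, rng):
        maps = _maps(rng, 20, dims=(5, 5, 5))
        design = RegressionDesign(pd.DataFrame({"x": rng.standard_normal(20)}))
        res = SFCRegression(maps, design, voxel_size_mm=3.0).fit()
        with pytest.raises(ValueError):
            res.cluster_fwe(n_perm=10)

    def test_planted_network_detected_and_overlaps_template(self, small_spec, small_cohort, small_maps):
        """A network coupled to UPDRS II at |r| = 0.46 yields a significant cluster on its template."""
        from sfcpipe import pipeline

        design = RegressionDesign(
            small_cohort.clinical[["updrs2"]],
            small_cohort.clinical[pipeline.COVARIATE_COLS],
        )
        res = SFCRegression(small_maps, design, voxel_size_mm=small_spec.voxel_size_mm).fit()
        tables, null = res.cluster_fwe(n_perm=200, rng=np.random.default_rng(1))
        ct = tables["updrs2"]
        sig = ct.significant()
        assert len(sig) >= 1
        best = max(
            (int((ct.voxels(int(c)) & small_spec.network_templates[0]).sum()) for c in sig["cluster_id"])
        )
        assert best >= 0.5 * small_spec.network_templates[0].sum()


class TestValidityCheck:
    def test_binomial_ci_matches_statsmodels_oracle(self):
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = binomial_ci(49, 1000, conf=0.99)
        olo, ohi = proportion_confint(49, 1000, alpha=0.01, method="beta")
        assert lo == pytest.approx(olo, abs=1e-10)
        assert hi == pytest.approx(ohi, abs=1e-10)

    def test_proportion_arithmetic(self):
        assert 49 / 1000 == pytest.approx(0.049)
        lo, hi = binomial_ci(0, 200)
        assert lo == 0.0

    def test_null_false_positive_rate_within_binomial_band(self, small_spec, small_cohort):
        """Cluster-inference type-I error on a null regressor stays near the nominal 5%."""
        from sfcpipe import pipeline
        from sfcpipe.clusterstats import validity_check

        rng = np.random.default_rng(3)
        # replace the clinical scores by pure noise: a genuinely null design
        null_interest = pd.DataFrame(rng.standard_normal((small_spec.n_subjects, 3)), columns=list("abc"))
        from sfcpipe import compute_sfc_maps

        maps = compute_sfc_maps(small_cohort, small_spec.seed)
        out = validity_check(
            maps,
            RegressionDesign(null_interest, small_cohort.clinical[pipeline.COVARIATE_COLS]),
            n_perm=150,
            n_eval=200,
            voxel_size_mm=small_spec.voxel_size_mm,
            rng=rng,
        )
        n_eval = out["n_eval"]
        lo = stats.binom.ppf(0.005, n_eval, 0.05) / n_eval
        hi = stats.binom.ppf(0.995, n_eval, 0.05) / n_eval
        assert lo <= out["proportion"] <= hi

    def test_exact_p_uniform_under_null(self, small_spec, small_cohort, small_maps):
        """Evaluation maxima are exchangeable with the permutation null, so exact
        p-values are uniform on their achievable grid (two-sample KS)."""
        from sfcpipe import pipeline
        from sfcpipe.clusterstats import validity_check

        rng = np.random.default_rng(5)
        null_interest = pd.DataFrame(rng.standard_normal((small_spec.n_subjects, 1)), columns=["x"])
        out = validity_check(
            small_maps,
            RegressionDesign(null_interest, small_cohort.clinical[pipeline.COVARIATE_COLS]),
            n_perm=200,
            n_eval=300,
            voxel_size_mm=small_spec.voxel_size_mm,
            rng=rng,
        )
        ks = stats.ks_2samp(out["eval_max_extents"], out["null"].max_extents)
        assert ks.pvalue > 0.01
        # mean exact p of the evaluation maxima is 1/2 up to Monte-Carlo error
        p_eval = out["null"].exact_p(out["eval_max_extents"])
        assert abs(p_eval.mean() - 0.5) < 0.08
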