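import numpy as np
import pytest

from sfcpipe import (
    SeedSpec,
    motion_qc,
    VolumeSeries,
    bandpass,
    build_nuisance_matrix,
    detrend_linear,
    fisher_z,
    preprocess_series,
    regress_out,
    resolve_seed,
    sfc_map,
)


def _series(data, voxel=3.0, tr=2.0):
    return VolumeSeries(np.asarray(data, float), voxel_size_mm=voxel, tr_seconds=tr)


class TestNuisanceMatrix:
    def test_zero_motion_gives_zero_design(self):
        d = build_nuisance_matrix(np.zeros((10, 6)))
        assert d.matrix.shape == (10, 24)
        assert not d.matrix.any()

    def test_hand_enumerated_column_expansion(self):
        motion = np.zeros((5, 6))
        motion[:, 0] = [0, 1, 2, 3, 4]
        d = build_nuisance_matrix(motion).matrix
        np.testing.assert_array_equal(d[:, 0], [0, 1, 2, 3, 4])       # motion
        np.testing.assert_array_equal(d[:, 6], [0, 1, 1, 1, 1])       # accel (backward diff, leading 0)
        np.testing.assert_array_equal(d[:, 12], [0, 1, 4, 9, 16])     # motion^2
        np.testing.assert_array_equal(d[:, 18], [0, 1, 1, 1, 1])      # accel^2

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="3 timepoints"):
            build_nuisance_matrix(np.zeros((2, 6)))

    def test_wrong_column_count_rejected(self):
        with pytest.raises(ValueError, match="T x 6"):
            build_nuisance_matrix(np.zeros((10, 5)))


class TestRegressOut:
    def test_design_column_fully_removed(self, rng):
        motion = rng.standard_normal((20, 6))
        design = build_nuisance_matrix(motion)
        data = np.tile(design.matrix[:, 3], (2, 2, 2, 1))
        resid = regress_out(_series(data), design)
        np.testing.assert_allclose(resid.data, 0.0, atol=1e-10)

    def test_zero_design_demeans(self, rng):
        data = rng.standard_normal((2, 2, 2, 15))
        resid = regress_out(_series(data), build_nuisance_matrix(np.zeros((15, 6))))
        np.testing.assert_allclose(resid.data, data - data.mean(axis=3, keepdims=True), atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        motion = rng.standard_normal((30, 6))
        design = build_nuisance_matrix(motion)
        data = rng.standard_normal((3, 3, 3, 30))
        resid = regress_out(_series(data), design)
        X = np.hstack([np.ones((30, 1)), design.matrix])
        P = X @ np.linalg.pinv(X.T @ X) @ X.T
        expected = (np.eye(30) - P) @ data.reshape(-1, 30).T
        np.testing.assert_allclose(resid.data.reshape(-1, 30).T, expected, atol=1e-8)
        # residuals orthogonal to every design column
        inner = X.T @ resid.data.reshape(-1, 30).T
        assert np.abs(inner).max() < 1e-8


class TestDetrendBandpass:
    def test_stopband_sinusoid_suppressed(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.15 * t)
        data = np.tile(sig, (2, 2, 2, 1))
        out = bandpass(_series(data, tr=2.0))
        assert np.sqrt((out.data**2).mean()) < 0.01 * np.sqrt((data**2).mean())

    def test_passband_bin_retained(self):
        # 0.04 Hz on an exact DFT bin: T=200, TR=2 s -> bin 16 at 0.04 Hz
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.04 * t)
        data = np.tile(sig, (2, 2, 2, 1))
        out = bandpass(_series(data, tr=2.0))
        assert np.sqrt((out.data**2).mean()) > 0.99 * np.sqrt((data**2).mean())

    def test_constant_zeroed(self):
        out = bandpass(_series(np.full((2, 2, 2, 100), 7.0), tr=2.0))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-10)

    def test_detrend_removes_line(self):
        t = np.arange(50, dtype=float)
        data = np.tile(3.0 + 0.5 * t, (2, 2, 2, 1))
        out = detrend_linear(_series(data))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-8)

    def test_band_order_validated(self):
        with pytest.raises(ValueError):
            bandpass(_series(np.zeros((2, 2, 2, 100))), low_hz=0.08, high_hz=0.01)

    def test_high_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(_series(np.zeros((2, 2, 2, 100)), tr=2.0), high_hz=0.3)


class TestResolveSeed:
    def test_5mm_sphere_on_3mm_grid_has_19_voxels(self):
        mask = resolve_seed(SeedSpec((5, 5, 5), 5.0), (11, 11, 11), 3.0)
        assert mask.sum() == 19  # center + 6 face (3 mm) + 12 edge (4.243 mm)
        assert mask[5, 5, 5]
        assert not mask[6, 6, 6]  # corner at 5.196 mm excluded

    def test_radius_below_voxel_size_single_voxel(self):
        mask = resolve_seed(SeedSpec((3, 3, 3), 1.0), (7, 7, 7), 3.0)
        assert mask.sum() == 1

    def test_matches_brute_force_enumeration_1mm(self):
        center, radius, vox = (7, 7, 7), 5.0, 1.0
        mask = resolve_seed(SeedSpec(center, radius), (15, 15, 15), vox)
        count = 0
        for i in range(15):
            for j in range(15):
                for k in range(15):
                    d = vox * np.sqrt((i - 7) ** 2 + (j - 7) ** 2 + (k - 7) ** 2)
                    count += d <= radius
        assert mask.sum() == count

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            resolve_seed(SeedSpec((20, 5, 5), 5.0), (10, 10, 10), 3.0)


class TestSfcMap:
    def test_voxel_identical_to_seed_mean_capped(self, rng):
        data = rng.standard_normal((9, 9, 9, 80))
        series = _series(data)
        seed = SeedSpec((4, 4, 4), 5.0)
        seed_mask = resolve_seed(seed, (9, 9, 9), 3.0)
        data[0, 0, 0] = data[seed_mask].mean(axis=0)
        z = sfc_map(series, seed)
        assert np.isfinite(z.data[0, 0, 0])
        assert z.data[0, 0, 0] > 13.0  # capped atanh(1 - 1e-12)

    def test_white_noise_voxel_uncorrelated(self, rng):
        data = rng.standard_normal((7, 7, 7, 150))
        z = sfc_map(_series(data), SeedSpec((3, 3, 3), 5.0))
        far = z.data[0, 0, 0]
        assert abs(np.tanh(far)) < 0.3

    def test_zero_variance_voxel_counted_and_zeroed(self, rng):
        data = rng.standard_normal((7, 7, 7, 60))
        data[0, 0, 0] = 5.0
        z = sfc_map(_series(data), SeedSpec((3, 3, 3), 5.0))
        assert z.data[0, 0, 0] == 0.0
        assert z.n_zero_variance == 1

    def test_seed_outside_mask_rejected(self, rng):
        data = rng.standard_normal((7, 7, 7, 60))
        mask = np.ones((7, 7, 7), bool)
        mask[1:6, 1:6, 1:6] = False
        with pytest.raises(ValueError, match="mask"):
            sfc_map(_series(data), SeedSpec((3, 3, 3), 4.0), mask=mask)


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_and_inverse(self, rng):
        r = rng.uniform(-0.99, 0.99, 50)
        np.testing.assert_allclose(fisher_z(-r), -fisher_z(r), atol=1e-12)
        x = rng.uniform(-3, 3, 50)
        np.testing.assert_allclose(np.arctanh(np.tanh(x)), x, atol=1e-12)

    def test_domain_enforced(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)


class TestChainInvariance:
    def test_nuisance_span_invariance(self, rng):
        """Adding any linear combination of nuisance columns leaves the SFC map unchanged."""
        motion = np.cumsum(rng.standard_normal((80, 6)) * 0.02, axis=0)
        data = rng.standard_normal((8, 8, 8, 80))
        series = _series(data, tr=2.4)
        seed = SeedSpec((4, 4, 4), 5.0)
        base = sfc_map(preprocess_series(series, motion), seed).data

        design = build_nuisance_matrix(motion)
        combo = design.matrix @ rng.standard_normal(24)
        perturbed = _series(data + combo[None, None, None, :] * 2.0, tr=2.4)
        pert = sfc_map(preprocess_series(perturbed, motion), seed).data
        np.testing.assert_allclose(pert, base, atol=1e-6)


class TestMotionQc:
    def test_small_motion_passes_and_large_motion_flagged(self, rng):
        calm = np.cumsum(rng.normal(0, 0.01, (50, 6)), axis=0)
        out = motion_qc(calm, voxel_size_mm=3.0)
        assert not out["exceeds"]
        jumpy = calm.copy()
        jumpy[30, 1] = 4.5  # translation beyond one 3 mm voxel
        assert motion_qc(jumpy, voxel_size_mm=3.0)["exceeds"]
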