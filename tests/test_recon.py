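"""Reconstruction: system-matrix structure, truncated-SVD selection against
independent oracles, reconstruction fidelity, smoothing and PSF estimation."""

import numpy as np
import pytest

from fmpi import recon as rc
from fmpi import scanner_sim as ss


class TestBuildSystemMatrix:
    def test_row_count_2d_four_harmonics(self, geometry, spion):
        grid = rc.GridSpec(n_xy=5, voxel_size=3.0)
        sm = rc.build_system_matrix(geometry, spion, grid, [3, 5, 7, 9])
        assert sm.matrix.shape == (27 * 66 * 4, 25)

    def test_row_count_3d_two_harmonics(self, system3d):
        assert system3d.matrix.shape[0] == 27 * 66 * 2 == 3564

    def test_column_equals_acquire_frame(self, geometry, spion, grid17, system17):
        tracer = grid17.to_tracer_map()
        tracer.grid[8, 8, 0] = 1.0
        frame = ss.acquire_frame(tracer, geometry, spion, 0.0, (3, 5, 7, 9))
        col = system17.matrix[:, np.ravel_multi_index((8, 8, 0), (17, 17, 1))]
        assert np.array_equal(col, frame.values.ravel())

    def test_empty_harmonics_rejected(self, geometry, spion):
        with pytest.raises(ValueError, match="empty"):
            rc.build_system_matrix(geometry, spion, rc.GridSpec(5, 3.0), [])

    def test_grid_outside_fov_rejected(self, geometry, spion):
        with pytest.raises(ValueError, match="field of view"):
            rc.build_system_matrix(geometry, spion, rc.GridSpec(33, 1.75), [3])


def _toy_system(seed=0, n_angles=1, n_samples=3, n_xy=2):
    """A tiny random complex system wrapped in the SystemMatrix container."""
    geometry = ss.ScannerGeometry(n_angles=n_angles, n_samples=n_samples)
    grid = rc.GridSpec(n_xy=n_xy, voxel_size=1.0)
    rng = np.random.default_rng(seed)
    m = n_angles * n_samples
    mat = rng.normal(size=(m, grid.n_voxels)) + 1j * rng.normal(size=(m, grid.n_voxels))
    return rc.SystemMatrix(mat, grid, (3,), geometry, ss.SpionModel())


class TestSelectSingularVectors:
    def test_zero_threshold_equals_full_pseudoinverse(self):
        sys = _toy_system()
        inv = rc.select_singular_vectors(sys, energy_threshold=0.0)
        A = np.vstack([sys.matrix.real, sys.matrix.imag])
        assert np.allclose(inv.pseudo_inverse, np.linalg.pinv(A), atol=1e-10)
        assert inv.retained_vectors == np.linalg.matrix_rank(A)

    def test_pure_dc_singular_vector_always_retained(self):
        # rank-1 system whose right singular vector is constant (pure DC)
        geometry = ss.ScannerGeometry(n_angles=1, n_samples=3)
        grid = rc.GridSpec(n_xy=2, voxel_size=1.0)
        u = np.array([1.0, -2.0, 0.5])[:, None]
        mat = (u @ np.ones((1, 4))).astype(complex)
        sys = rc.SystemMatrix(mat, grid, (3,), geometry, ss.SpionModel())
        inv = rc.select_singular_vectors(sys, energy_threshold=0.99)
        assert inv.retained_vectors == 1
        assert inv.low_freq_fractions[0] == pytest.approx(1.0)

    def test_toy_matrix_matches_explicit_svd_oracle(self):
        # independent oracle: brute-force SVD + per-vector spectral rule
        sys = _toy_system(seed=3)
        thr, band = 0.4, 0.5
        inv = rc.select_singular_vectors(sys, thr, band)
        A = np.vstack([sys.matrix.real, sys.matrix.imag])
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        band_mm = band / (2.0 * sys.geometry.sample_spacing)
        keep = []
        for i in range(len(s)):
            img = Vt[i].reshape(2, 2)
            spec = np.abs(np.fft.fft2(img)) ** 2
            fx = np.fft.fftfreq(2, d=1.0)
            r = np.hypot(fx[:, None], fx[None, :])
            frac = spec[r <= band_mm].sum() / spec.sum()
            if frac > thr:
                keep.append(i)
        oracle = (Vt[keep].T / s[keep]) @ U[:, keep].T
        assert inv.retained_vectors == len(keep)
        assert np.allclose(inv.pseudo_inverse, oracle, atol=1e-12)

    def test_retained_count_monotone_in_threshold(self, system17):
        counts = [
            rc.select_singular_vectors(system17, thr).retained_vectors
            for thr in (0.0, 0.05, 0.10, 0.3, 0.6)
        ]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_all_rejected_raises_advice(self):
        sys = _toy_system(seed=1)
        with pytest.raises(ValueError, match="relax"):
            rc.select_singular_vectors(sys, energy_threshold=1.0)

    def test_truncated_pinv_matches_normal_equations_on_small_grid(self, geometry, spion):
        # retained-subspace least squares solved by an independent route
        grid = rc.GridSpec(n_xy=7, voxel_size=3.5)
        sm = rc.build_system_matrix(geometry, spion, grid, [3, 5])
        inv = rc.select_singular_vectors(sm)
        A = np.vstack([sm.matrix.real, sm.matrix.imag])
        U, s, Vt = np.linalg.svd(A, full_matrices=False)
        keep = inv.low_freq_fractions > inv.energy_threshold
        A_r = (U[:, keep] * s[keep]) @ Vt[keep]
        rng = np.random.default_rng(7)
        d = rng.normal(size=A.shape[0])
        x_oracle, *_ = np.linalg.lstsq(A_r, d, rcond=1e-10)
        x_ours_full = (Vt[keep].T / s[keep]) @ (U[:, keep].T @ d)
        assert np.linalg.norm(x_ours_full - x_oracle) < 1e-8 * np.linalg.norm(x_oracle)
        # and the operator's center-slice rows agree with the full solution
        img = inv.pseudo_inverse @ d
        assert np.allclose(img, x_ours_full, atol=1e-10)


class TestReconstructFrame:
    def test_zero_sinogram_gives_zero_image(self, inv17):
        frame = ss.SinogramFrame(np.zeros((27, 66, 4), complex), 0.0, (3, 5, 7, 9))
        assert np.all(rc.reconstruct_frame(frame, inv17) == 0)

    def test_point_source_argmax_at_source_voxel(self, geometry, spion, grid17, inv17):
        tracer = grid17.to_tracer_map()
        tracer.grid[5, 10, 0] = 100.0
        frame = ss.acquire_frame(tracer, geometry, spion, 0.0, (3, 5, 7, 9))
        img = rc.reconstruct_frame(frame, inv17)
        assert np.unravel_index(np.argmax(img), img.shape) == (5, 10)

    def test_two_sources_above_native_fwhm_resolved(self, geometry, spion, grid17, inv17):
        from scipy import ndimage

        tracer = grid17.to_tracer_map()
        tracer.grid[5, 8, 0] = 100.0
        tracer.grid[11, 8, 0] = 100.0  # 10.5 mm apart >> 3 mm FWHM
        frame = ss.acquire_frame(tracer, geometry, spion, 0.0, (3, 5, 7, 9))
        img = rc.reconstruct_frame(frame, inv17)
        maxima = (img == ndimage.maximum_filter(img, 3)) & (img > 0.5 * img.max())
        peaks = set(map(tuple, np.argwhere(maxima)))
        assert peaks == {(5, 8), (11, 8)}

    def test_reconstruction_linearity(self, inv17):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(27, 66, 4)) + 1j * rng.normal(size=(27, 66, 4))
        f1 = ss.SinogramFrame(v, 0.0, (3, 5, 7, 9))
        f3 = ss.SinogramFrame(3.5 * v, 0.0, (3, 5, 7, 9))
        assert np.allclose(
            rc.reconstruct_frame(f3, inv17), 3.5 * rc.reconstruct_frame(f1, inv17), atol=1e-12
        )

    def test_missing_harmonics_rejected(self, inv17):
        frame = ss.SinogramFrame(np.zeros((27, 66, 2), complex), 0.0, (3, 5))
        with pytest.raises(ValueError, match="lacks harmonics"):
            rc.reconstruct_frame(frame, inv17)

    def test_out_of_plane_source_suppressed_in_center_slice(self, geometry, spion, inv3d):
        def peak_for_z(z):
            tracer = ss.TracerMap(np.full((1, 1, 1), 100.0), (1.0, 1.0, 1.0), (0.0, 0.0, z))
            frame = ss.acquire_frame(tracer, geometry, spion, 0.0, (2, 3))
            return float(rc.reconstruct_frame(frame, inv3d).max())

        assert peak_for_z(2.0) < peak_for_z(0.0)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        img = np.random.default_rng(0).normal(size=(9, 9))
        assert np.array_equal(rc.smooth_image(img, 0.0, 1.0), img)

    def test_sum_conserved_for_interior_source(self):
        img = np.zeros((31, 31))
        img[15, 15] = 5.0
        out = rc.smooth_image(img, 3.0, 1.0)
        assert out.sum() == pytest.approx(5.0, rel=1e-6)

    def test_smoothed_delta_has_requested_fwhm(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = rc.smooth_image(img, 3.0, 0.9)
        assert rc.measure_psf_fwhm(out, 0.9) == pytest.approx(3.0, abs=0.45)


class TestMeasurePsfFwhm:
    @pytest.mark.parametrize("fwhm", [3.0, 2.55])
    def test_recovers_known_gaussian_width(self, fwhm):
        truth = np.zeros((41, 41))
        truth[20, 20] = 1.0
        blob = rc.smooth_image(truth, fwhm, 1.0)
        assert rc.measure_psf_fwhm(blob, 1.0) == pytest.approx(fwhm, abs=0.1)

    def test_simulator_point_source_resolution_recorded(
        self, geometry, spion, grid17, inv17
    ):
        # pipeline measurement: value depends on the retained subspace, so it
        # is recorded and sanity-bounded rather than pinned
        tracer = grid17.to_tracer_map()
        tracer.grid[8, 8, 0] = 100.0
        frame = ss.acquire_frame(tracer, geometry, spion, 0.0, (3, 5, 7, 9))
        fwhm = rc.measure_psf_fwhm(rc.reconstruct_frame(frame, inv17), 1.75)
        assert 1.0 < fwhm < 8.0


def test_operator_h5_roundtrip(tmp_path, inv17):
    path = tmp_path / "op.h5"
    rc.save_operator(path, inv17)
    back = rc.load_operator(path)
    assert back.retained_vectors == inv17.retained_vectors
    assert back.energy_threshold == inv17.energy_threshold
    assert back.grid_spec == inv17.grid_spec
    assert np.array_equal(back.pseudo_inverse, inv17.pseudo_inverse)


def test_nifti_roundtrip_preserves_voxel_size(tmp_path):
    frames = np.random.default_rng(2).normal(size=(4, 9, 9))
    path = tmp_path / "series.nii.gz"
    rc.write_image_series_nifti(path, frames, voxel_size=0.9)
    back, vox = rc.read_image_series_nifti(path)
    assert vox == pytest.approx(0.9)
    assert np.allclose(back, frames, atol=1e-6)
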