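"""Hemodynamic GLM: kernel shape, design construction, OLS exactness,
parameter optimization, CNR / percent-change / activation maps."""

import numpy as np
import pytest

from fmpi import glm as gl
from fmpi import preprocess as pre
from fmpi import study_synth as sy


class TestCo2rf:
    def test_zero_at_origin_and_negative_times(self):
        assert gl.co2rf(0.0, 51.0) == 0.0
        assert gl.co2rf(-5.0, 51.0) == 0.0

    def test_peaks_at_tau1(self):
        t = np.arange(0.0, 400.0, 1.0)
        k = gl.co2rf(t, 51.0)
        assert abs(t[np.argmax(k)] - 51.0) <= 1.0

    def test_closed_form_ratio(self):
        tau = 37.0
        assert gl.co2rf(2 * tau, tau) / gl.co2rf(tau, tau) == pytest.approx(
            2.0 * np.exp(-1.0), rel=1e-12
        )

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            gl.co2rf(1.0, 0.0)


class TestActivationRegressor:
    def test_phantom_mode_is_shifted_block(self, frame_times):
        proto = sy.CapniaProtocol(start_state="hyper")
        reg = gl.activation_regressor(proto, frame_times, delta_t=10.0, mode="phantom")
        expect = proto.block(frame_times - 10.0)
        assert np.ptp(reg) == pytest.approx(1.0)
        assert np.allclose(reg, expect)

    def test_flat_block_raises(self, frame_times):
        flat = lambda t: np.zeros_like(np.asarray(t, float))
        with pytest.raises(ValueError, match="flat"):
            gl.activation_regressor(flat, frame_times, mode="fmpi")

    def test_plateaus_reach_zero_and_one_without_decay(self):
        # slow square block, plateaus long vs tau1: normalized plateaus -> 0/1
        proto = sy.CapniaProtocol(state_duration=2000.0, n_cycles=1)
        t = np.arange(0.0, 4000.0, 5.0)
        reg = gl.activation_regressor(proto, t, tau1=51.0, tau2=1e12, mode="bold")
        assert reg[t < 1900].min() == pytest.approx(0.0, abs=1e-3)
        assert reg[(t > 3800)].max() == pytest.approx(1.0, abs=1e-3)


class TestBuildDesign:
    def test_fmpi_mode_has_five_regressors(self, frame_times):
        design, _ = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        assert list(design.columns) == [
            "activation", "constant", "linear", "quadratic", "transient",
        ]

    def test_phantom_mode_appends_conditional_drift(self, frame_times):
        params = gl.GLMParams(mode="phantom")
        proto = sy.CapniaProtocol(start_state="hyper")
        design, _ = gl.build_design(frame_times, params, proto)
        assert design.shape[1] == 6
        out = proto.block(frame_times) < 0.5
        assert np.all(design["conditional_drift"].to_numpy()[out] == 0.0)

    def test_full_column_rank_on_standard_protocol(self, frame_times):
        design, _ = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        X = design.to_numpy()
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="6 frames"):
            gl.build_design([0.0, 5.0, 10.0], gl.GLMParams(), sy.CapniaProtocol())


class TestFitVoxel:
    def test_pure_constant_data(self, frame_times):
        design, _ = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        betas, sd = gl.fit_voxel(3.0 * design["constant"].to_numpy(), design)
        assert betas == pytest.approx([0, 3, 0, 0, 0], abs=1e-10)
        assert sd == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_recovery_machine_precision(self, frame_times):
        design, _ = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        truth = np.array([2.0, 1.0, 0.0, 0.0, 0.5])
        betas, sd = gl.fit_voxel(design.to_numpy() @ truth, design)
        assert betas == pytest.approx(truth, abs=1e-10)
        assert sd < 1e-10

    def test_residual_sd_is_unbiased_for_known_noise(self, frame_times):
        design, _ = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        rng = np.random.default_rng(0)
        sigma = 0.25
        Y = rng.normal(0.0, sigma, size=(len(frame_times), 1000))
        fit = gl.fit_glm(Y[:, :, None], design)
        assert fit.residual_sd.mean() == pytest.approx(sigma, rel=0.02)


class TestOptimizeParams:
    def test_noiseless_global_minimum_at_truth(self, frame_times):
        proto = sy.CapniaProtocol()
        true = gl.GLMParams(51.0, 3100.0, 100.0, 10.0, "fmpi")
        design, _ = gl.build_design(frame_times, true, proto)
        y = design.to_numpy() @ np.array([2.0, 1.0, 0.1, 0.05, 0.5])
        series = pre.ImageSeries(
            y[:, None, None], frame_times, np.arange(len(frame_times)), proto.block(frame_times)
        )
        params, fit = gl.optimize_params(series, proto)
        assert params.delta_t == 10.0
        assert params.tau1 == pytest.approx(51.0, rel=0.01)
        assert params.tau2 == pytest.approx(3100.0, rel=0.01)
        assert fit.residual_sd.max() < 1e-6

    def test_phantom_mode_recovers_delay(self, frame_times):
        proto = sy.CapniaProtocol(start_state="hyper")
        block = lambda t: proto.block(t)
        y = 0.7 * proto.block(frame_times - 15.0)
        rng = np.random.default_rng(4)
        y = y + rng.normal(0, 0.01, len(frame_times))
        series = pre.ImageSeries(
            y[:, None, None], frame_times, np.arange(len(frame_times)), proto.block(frame_times)
        )
        params, _ = gl.optimize_params(series, block, mode="phantom")
        assert params.delta_t == 15.0


class TestMaps:
    def _fit(self, frame_times, y):
        design, meta = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        return gl.fit_glm(y, design, meta)

    def test_cnr_scale_invariance(self, frame_times):
        rng = np.random.default_rng(5)
        design, meta = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        y = (design.to_numpy() @ np.array([1.0, 5.0, 0, 0, 0]))[:, None, None]
        y = y + rng.normal(0, 0.1, y.shape)
        a = gl.cnr_map(gl.fit_glm(y, design, meta))
        b = gl.cnr_map(gl.fit_glm(2.0 * y, design, meta))
        assert np.allclose(a, b, rtol=1e-9)

    def test_degenerate_residual_capped_with_warning(self, frame_times):
        design, meta = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        y = (design.to_numpy() @ np.array([1.0, 5.0, 0, 0, 0]))[:, None, None]
        with pytest.warns(RuntimeWarning, match="capped"):
            fit = gl.fit_glm(y, design, meta)
        assert abs(gl.cnr_map(fit)[0, 0]) == gl.CNR_CAP

    def test_percent_change_recovers_generator_fraction(self, frame_times):
        proto = sy.CapniaProtocol()
        course = sy.cbv_timecourse(proto.block, frame_times, 51.0, 3100.0, 2.0, 0.25)
        rng = np.random.default_rng(6)
        y = np.repeat(course[:, None], 9, axis=1).reshape(len(frame_times), 3, 3)
        y = y + rng.normal(0, 0.005, y.shape)
        design, meta = gl.build_design(frame_times, gl.GLMParams(), proto)
        fit = gl.fit_glm(y, design, meta)
        assert np.nanmean(gl.percent_change_map(fit)) == pytest.approx(25.0, abs=3.0)

    def test_percent_change_invalid_baseline_flagged(self, frame_times):
        design, meta = gl.build_design(frame_times, gl.GLMParams(), sy.CapniaProtocol())
        rng = np.random.default_rng(7)
        y = rng.normal(-5.0, 0.1, size=(len(frame_times), 1, 1))  # negative baseline
        fit = gl.fit_glm(y, design, meta)
        assert np.isnan(fit.percent_change[0])

    def test_activation_map_boundaries(self, frame_times):
        proto = sy.CapniaProtocol()
        design, meta = gl.build_design(frame_times, gl.GLMParams(), proto)
        rng = np.random.default_rng(8)
        clean = (design.to_numpy() @ np.array([1.0, 5.0, 0, 0, 0]))[:, None, None]
        noisy = clean + rng.normal(0, 1e-6, clean.shape)
        fit = gl.fit_glm(noisy, design, meta)
        assert gl.activation_map(fit, alpha=1e-12).all()  # strong activation survives
        null = rng.normal(0, 1.0, size=(len(frame_times), 2, 2))
        fit0 = gl.fit_glm(null, design, meta)
        assert gl.activation_map(fit0, alpha=1.0).all()  # boundary: everything
        assert not gl.activation_map(fit0, alpha=1e-12).any()

    def test_residual_spectrum_flat_at_artifact_frequencies(self, frame_times, geometry):
        # band-stop + GLM leaves no residual line at 0.2 / 0.4 cycles/sample
        proto = sy.CapniaProtocol()
        course = sy.cbv_timecourse(proto.block, frame_times, 51.0, 3100.0, 2.0, 0.25)
        series = pre.ImageSeries(
            np.repeat(course[:, None], 4, axis=1).reshape(-1, 2, 2),
            frame_times,
            np.arange(len(frame_times)),
            proto.block(frame_times),
        )
        series = sy.inject_noise(series, sy.NoiseModel(quadrant_gain_delta=0.05), 9)
        series = pre.bandstop_filter(series)
        design, meta = gl.build_design(frame_times, gl.GLMParams(), proto)
        fit = gl.fit_glm(series.frames, design, meta)
        X = design.to_numpy()
        beta = np.linalg.lstsq(X, series.frames.reshape(len(frame_times), -1), rcond=None)[0]
        resid = series.frames.reshape(len(frame_times), -1) - X @ beta
        spec = np.abs(np.fft.rfft(resid[:, 0])) ** 2
        freqs = np.fft.rfftfreq(len(frame_times))
        for f0 in (0.2, 0.4):
            line = spec[np.argmin(np.abs(freqs - f0))]
            neighbors = spec[(np.abs(freqs - f0) > 0.05) & (np.abs(freqs - f0) < 0.1)]
            assert line < 2.0 * neighbors.mean()


class TestHalfLife:
    def test_closed_form(self):
        assert gl.blood_half_life(1.0 / np.log(2.0)) == pytest.approx(1.0)
        assert gl.blood_half_life(3100.0) == pytest.approx(2148.7, abs=0.1)

    def test_inverse_round_trip_48_minutes(self):
        tau2 = gl.tau2_from_half_life(48.0 * 60.0)
        assert tau2 == pytest.approx(4155.0, abs=1.0)
        assert gl.blood_half_life(tau2) == pytest.approx(2880.0)
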