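"""Spectral chain: DFT bookkeeping, peak finding, windowing, T2* fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import curve_fit

from fsvps import (
    AcquisitionParams,
    ComponentSpec,
    DegenerateSignalError,
    FidFrame,
    FilterConfig,
    NoiseModel,
    estimate_t2,
    estimate_t2_series,
    find_water_peak,
    from_spectrum,
    gaussian_window,
    generate_fid,
    generate_session,
    loglinear_t2,
    optimize_regression_length,
    shift_to_center,
    to_spectrum,
)


class TestSpectrumTransforms:
    def test_roundtrip_and_parseval(self, water_frame):
        spec = to_spectrum(water_frame)
        back = from_spectrum(spec, te=water_frame.te)
        np.testing.assert_allclose(
            back.samples, water_frame.samples, rtol=0, atol=1e-12
        )
        time_energy = np.sum(np.abs(water_frame.samples) ** 2)
        freq_energy = np.sum(np.abs(spec.values) ** 2) / water_frame.n_points
        assert freq_energy == pytest.approx(time_energy, rel=1e-9)

    def test_peak_at_zero_and_on_bin(self, acq):
        f0 = 125.0  # exactly on a bin at 1000/512 Hz spacing x 64
        frame = generate_fid([ComponentSpec(1.0, f0, 0.0, 0.05)], acq)
        assert find_water_peak(to_spectrum(frame)) == pytest.approx(f0, abs=0.1)
        frame0 = generate_fid([ComponentSpec(1.0, 0.0, 0.0, 0.05)], acq)
        assert find_water_peak(to_spectrum(frame0)) == pytest.approx(0.0, abs=0.1)

    def test_peak_off_bin_vs_dense_dft(self, acq):
        f0 = 37.5  # off-bin
        frame = generate_fid([ComponentSpec(1.0, f0, 0.0, 0.05)], acq)
        found = find_water_peak(to_spectrum(frame))
        # oracle: argmax of a 64x zero-padded DFT
        n = frame.n_points
        padded = np.fft.fftshift(np.fft.fft(frame.samples, n=64 * n))
        freqs = np.fft.fftshift(np.fft.fftfreq(64 * n, d=1.0 / acq.bandwidth))
        oracle = freqs[np.argmax(np.abs(padded))]
        bin_width = acq.bandwidth / n
        assert abs(found - f0) < bin_width
        assert abs(found - oracle) < bin_width

    def test_peak_picks_larger_component(self, acq):
        frame = generate_fid(
            [
                ComponentSpec(1.0, 100.0, 0.0, 0.05),
                ComponentSpec(0.1, -200.0, 0.0, 0.05),
            ],
            acq,
        )
        assert find_water_peak(to_spectrum(frame)) == pytest.approx(100.0, abs=2.0)

    def test_zero_spectrum_has_no_peak(self, acq):
        frame = FidFrame(np.zeros(acq.n_points), acq.bandwidth)
        with pytest.raises(DegenerateSignalError):
            find_water_peak(to_spectrum(frame))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(f=st.floats(-450.0, 450.0))
    def test_shift_roundtrip(self, f):
        acq = AcquisitionParams(n_points=64)
        frame = generate_fid([ComponentSpec(1.0, 40.0, 0.3, 0.05)], acq)
        back = shift_to_center(shift_to_center(frame, f), -f)
        np.testing.assert_allclose(back.samples, frame.samples, rtol=0, atol=1e-12)

    def test_shift_recenters_peak(self, acq):
        f0 = 37.5
        frame = generate_fid([ComponentSpec(1.0, f0, 0.0, 0.05)], acq)
        peak = find_water_peak(to_spectrum(frame))
        shifted = shift_to_center(frame, peak)
        residual = find_water_peak(to_spectrum(shifted))
        assert abs(residual) < acq.bandwidth / acq.n_points


class TestGaussianWindow:
    def test_unity_gain_at_center_and_energy(self, water_frame):
        spec = to_spectrum(water_frame)
        win = gaussian_window(spec, 20.0)
        i0 = int(np.argmin(np.abs(spec.freqs)))
        assert win.values[i0] == spec.values[i0]
        assert np.sum(np.abs(win.values) ** 2) <= np.sum(np.abs(spec.values) ** 2)

    def test_off_resonance_attenuation(self, acq):
        # a narrow line at offset df is scaled by ~exp(-df^2 / (2 sigma^2))
        df, sigma = 100.0, 30.0
        frame = generate_fid([ComponentSpec(1.0, df, 0.0, 0.2)], acq)
        win = from_spectrum(gaussian_window(to_spectrum(frame), sigma))
        # compare envelopes mid-FID, away from the window's edge transient
        t = frame.times()
        mid = (t > 0.1) & (t < 0.3)
        ratio = np.abs(win.samples[mid]).mean() / np.abs(frame.samples[mid]).mean()
        assert ratio == pytest.approx(np.exp(-(df**2) / (2 * sigma**2)), rel=0.05)


class TestLogLinearFit:
    def test_noiseless_exact(self, acq):
        frame = generate_fid([ComponentSpec(2.5, 0.0, 0.7, 0.05)], acq)
        est = loglinear_t2(frame, 0.1)
        assert est.ok
        assert est.t2star == pytest.approx(0.05, rel=1e-9)
        assert est.amplitude == pytest.approx(2.5, rel=1e-9)
        assert est.phase == pytest.approx(0.7, abs=1e-9)
        assert est.residual_rms < 1e-9

    def test_growing_signal_flags_failure(self, acq):
        t = acq.times()
        frame = FidFrame(np.exp(t / 0.5).astype(complex), acq.bandwidth)
        est = loglinear_t2(frame, 0.1)
        assert not est.ok
        assert np.isnan(est.t2star)

    def test_zero_magnitude_is_degenerate(self, acq):
        samples = np.ones(acq.n_points, dtype=complex)
        samples[3] = 0.0
        with pytest.raises(DegenerateSignalError):
            loglinear_t2(FidFrame(samples, acq.bandwidth), 0.05)

    def test_noisy_fit_matches_nonlinear_oracle(self, acq):
        """Log-line estimates agree with a direct exponential least-squares
        fit of the magnitude over 300 noisy frames."""
        T2, sigma, l = 0.05, 0.003, 0.064
        rng = np.random.default_rng(42)
        t = acq.times()
        sel = t <= l * (1 + 1e-12)
        impl, oracle = [], []
        for _ in range(300):
            f = generate_fid([ComponentSpec(1.0, 0.0, 0.3, T2)], acq, sigma, rng)
            impl.append(loglinear_t2(f, l).t2star)
            y = np.abs(f.samples[sel])
            popt, _ = curve_fit(
                lambda tt, a, tau: a * np.exp(-tt / tau), t[sel], y, p0=(1.0, T2)
            )
            oracle.append(popt[1])
        impl, oracle = np.asarray(impl), np.asarray(oracle)
        assert abs(impl.mean() - oracle.mean()) < 5e-4 * T2
        assert impl.std() == pytest.approx(oracle.std(), rel=0.3)

    def test_shift_invariance_of_estimate(self, acq):
        """Moving the component and the applied shift together leaves the
        windowed T2* estimate unchanged."""
        cfg = FilterConfig()
        base = generate_fid([ComponentSpec(1.0, 0.0, 0.5, 0.085)], acq)
        moved = generate_fid([ComponentSpec(1.0, 150.0, 0.5, 0.085)], acq)
        recentred = shift_to_center(moved, 150.0)

        def fit(frame):
            win = from_spectrum(
                gaussian_window(to_spectrum(frame), cfg.gaussian_sigma)
            )
            return loglinear_t2(win, cfg.regression_length).t2star

        assert fit(recentred) == pytest.approx(fit(base), rel=1e-6)

    def test_estimate_sd_decreases_with_noise(self, acq):
        cfg = FilterConfig()
        sds = []
        for sigma in (0.03, 0.01, 0.003):
            rng = np.random.default_rng(11)
            vals = [
                estimate_t2(
                    generate_fid(
                        [ComponentSpec(1.0, 0.0, 0.5, 0.085)], acq, sigma, rng
                    ),
                    cfg,
                ).t2star
                for _ in range(40)
            ]
            sds.append(np.std(vals))
        assert sds[0] > sds[1] > sds[2]


class TestOptimizeRegressionLength:
    def _session(self, small_design):
        noise = NoiseModel(spike_prob=0.0, rng_seed=17)
        frames, _ = generate_session(
            design=small_design,
            contaminants=[ComponentSpec(0.05, -180.0, 0.0, 0.03)],
            noise=noise,
        )
        return frames

    def test_single_candidate_returned(self, small_design):
        frames = self._session(small_design)
        l, curve = optimize_regression_length(
            frames, small_design, candidate_lengths=[0.1]
        )
        assert l == 0.1
        assert len(curve) == 1

    def test_optimum_is_argmax_of_curve(self, small_design):
        frames = self._session(small_design)
        grid = [0.06, 0.08, 0.1, 0.15, 0.25]
        l, curve = optimize_regression_length(
            frames, small_design, candidate_lengths=grid
        )
        assert l in grid
        t = curve["t_value"].to_numpy()
        assert t[curve["length_s"] == l][0] == np.nanmax(t)

    def test_matches_bruteforce_loop(self, small_design):
        """The optimizer equals an independent per-candidate loop that
        reprocesses every raw frame from scratch."""
        frames = self._session(small_design)
        grid = [0.06, 0.08, 0.1, 0.15]
        l_opt, curve = optimize_regression_length(
            frames, small_design, candidate_lengths=grid
        )

        retained = frames[small_design.n_discard:]
        labels = small_design.retained_labels
        best_l, best_t, oracle_t = None, -np.inf, []
        for l in grid:
            cfg = FilterConfig(regression_length=l)
            series = estimate_t2_series(retained, cfg)
            y = series["t2star"].to_numpy()
            # normal-equations OLS t-value of the boxcar coefficient
            X = np.column_stack([np.ones(y.size), (labels == 1).astype(float)])
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta
            s2 = resid @ resid / (y.size - 2)
            se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            oracle_t.append(t)
            if t > best_t:
                best_l, best_t = l, t
        assert l_opt == best_l
        np.testing.assert_allclose(
            curve["t_value"].to_numpy(), oracle_t, rtol=1e-8
        )
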