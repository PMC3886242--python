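"""Real-time chain: EMA detrending, spike-gating Kalman, normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fsvps import (
    BoldModel,
    ChainConfig,
    EmaFilter,
    FeedbackChain,
    FeedbackPipeline,
    NoiseModel,
    ParameterError,
    RangeNormalizer,
    RunningStats,
    SpikeGateKalman,
    ema_cutoff_hz,
    ema_time_constant,
    generate_session,
)
from fsvps.validation import ema_attenuation_error, kalman_band_power_ratio


class TestEma:
    def test_reference_constants(self):
        assert ema_time_constant(0.98) == pytest.approx(49.0, rel=1e-12)
        assert ema_cutoff_hz(0.98, tr=1.0) == pytest.approx(
            1.0 / (2 * math.pi * 49.0), rel=1e-12
        )

    def test_constant_input_is_fully_removed(self):
        ema = EmaFilter(0.98)
        out = [ema.step(3.7) for _ in range(50)]
        assert all(v == 0.0 for v in out)

    def test_alpha_zero_passes_nothing(self):
        ema = EmaFilter(0.0)
        rng = np.random.default_rng(0)
        for y in rng.standard_normal(20):
            assert ema.step(float(y)) == 0.0

    def test_sinusoid_matches_transfer_function(self):
        res = ema_attenuation_error(freq=0.05, alpha=0.98, tr=1.0)
        assert res["rel_error"] < 0.02

    def test_step_response_decays_geometrically(self):
        # a level step leaves a residual that shrinks by alpha each TR
        ema = EmaFilter(0.9)
        ema.step(0.0)
        out = [ema.step(1.0) for _ in range(10)]
        ratios = np.diff(np.log(out))
        np.testing.assert_allclose(ratios, math.log(0.9), rtol=1e-9)

    def test_rejects_non_finite(self):
        with pytest.raises(ParameterError):
            EmaFilter(0.98).step(float("nan"))


class TestRunningStats:
    def test_closed_forms(self):
        s = RunningStats()
        for v in (1.0, 1.0, 1.0):
            s.push(v)
        assert s.std == 0.0
        s2 = RunningStats()
        s2.push(0.0)
        s2.push(2.0)
        assert s2.std == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_single_sample_has_zero_sd(self):
        s = RunningStats()
        s.push(4.0)
        assert s.std == 0.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=200))
    def test_matches_two_pass_sd(self, values):
        s = RunningStats()
        for v in values:
            s.push(v)
        batch = float(np.std(values, ddof=1))
        assert s.std == pytest.approx(batch, rel=1e-10, abs=1e-10)


class TestSpikeGateKalman:
    def test_constant_input_converges_monotonically(self):
        k = SpikeGateKalman()
        k.step(0.0, threshold=None)
        outs = [k.step(1.0, threshold=None)[0] for _ in range(60)]
        assert np.all(np.diff(outs) >= -1e-15)
        assert outs[-1] == pytest.approx(1.0, abs=0.05)

    def test_outlier_is_vetoed(self):
        rng = np.random.default_rng(3)
        k = SpikeGateKalman()
        for y in rng.standard_normal(100):
            k.step(float(y))
        x_before = k.x_est
        filtered, spike = k.step(100.0)
        assert spike
        assert filtered == x_before  # coasted on the prediction

    def test_gate_disabled_during_warmup(self):
        k = SpikeGateKalman(warmup=10)
        k.step(0.0)
        _, spike = k.step(1e6)
        assert not spike

    def test_low_pass_spectral_shape(self):
        res = kalman_band_power_ratio(n=10_000, seed=0)
        assert res["ratio"] < 1.0


class TestRangeNormalizer:
    def test_first_sample_is_zero(self):
        n = RangeNormalizer(floor_range=1.0)
        assert n.step(5.0) == 0.0

    def test_extremes_map_to_unit_interval(self):
        n = RangeNormalizer(floor_range=0.1)
        n.step(0.0)
        assert n.step(2.0) == 1.0
        assert n.step(0.0) == 0.0
        assert n.step(1.0) == 0.5

    def test_range_never_shrinks(self):
        n = RangeNormalizer(floor_range=0.1)
        for v in (0.0, 10.0, 5.0, 5.1, 4.9):
            n.step(v)
        assert n._range == 10.0

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=100))
    def test_output_bounded(self, values):
        n = RangeNormalizer(floor_range=0.5)
        for v in values:
            assert 0.0 <= n.step(v) <= 1.0


class TestFeedbackChain:
    def _drifting_series(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        t = np.arange(n)
        y = 1.0 + 0.01 * t + 0.05 * rng.standard_normal(n)
        y[120] += 5.0
        return y

    def test_streaming_equals_batch(self):
        y = self._drifting_series()
        batch = FeedbackChain().process(y)
        chain = FeedbackChain()
        stream = [chain.step(float(v)) for v in y]
        for col in ("detrended", "filtered", "feedback"):
            np.testing.assert_array_equal(
                batch[col].to_numpy(), [row[col] for row in stream]
            )

    def test_stage_order_matters(self):
        """Kalman-before-EMA is a different map on drifting input."""
        y = self._drifting_series()
        normal = FeedbackChain().process(y)["filtered"].to_numpy()

        cfg = ChainConfig()
        kalman = SpikeGateKalman(cfg.lambda_ratio, cfg.thsp_coeff, cfg.spike_warmup)
        ema = EmaFilter(cfg.alpha)
        swapped = np.array([ema.step(kalman.step(float(v))[0]) for v in y])
        assert not np.allclose(normal, swapped, atol=1e-6)


class TestFeedbackPipeline:
    def test_constant_session_constant_feedback(self, small_design, quiet_noise):
        bold = BoldModel(activation_delta=0.0)
        frames, _ = generate_session(
            design=small_design, bold=bold, noise=quiet_noise
        )
        pipe = FeedbackPipeline(design=small_design)
        log = pipe.process_session(frames)
        fb = log["feedback_norm"].dropna().to_numpy()
        assert np.ptp(fb) == 0.0

    def test_replay_is_deterministic(self, small_design):
        frames, _ = generate_session(
            design=small_design, noise=NoiseModel(rng_seed=9)
        )
        log1 = FeedbackPipeline(design=small_design).process_session(frames)
        log2 = FeedbackPipeline(design=small_design).process_session(frames)
        assert log1.equals(log2)

    def test_plateau_sign_follows_t2_change(self, small_design, quiet_noise, boxcar_bold):
        """Noiseless boxcar session with the gate off: activation plateaus
        sit above baseline plateaus in the feedback."""
        frames, _ = generate_session(
            design=small_design, bold=boxcar_bold, noise=quiet_noise
        )
        cfg = ChainConfig(thsp_coeff=math.inf)
        pipe = FeedbackPipeline(chain_config=cfg, design=small_design)
        log = pipe.process_session(frames).dropna(subset=["filtered"])
        labels = small_design.labels[log["rep_index"].to_numpy()]
        # compare late-plateau samples (last 3 of each block)
        filt = log["filtered"].to_numpy()
        act = filt[(labels == 1)][-3:]
        bas = filt[(labels == 0)][-3:]
        assert act.mean() > bas.mean()

    def test_discarded_frames_never_touch_state(self, small_design):
        frames, _ = generate_session(
            design=small_design, noise=NoiseModel(rng_seed=4)
        )
        pipe = FeedbackPipeline(design=small_design)
        log = pipe.process_session(frames)
        head = log[log["rep_index"] < small_design.n_discard]
        assert head["feedback_norm"].isna().all()
        assert pipe.chain.kalman.stats.n == small_design.n_reps - small_design.n_discard
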