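"""Streaming conditioning of the T2* series into a feedback value.

One sample arrives per TR.  Three stages run in fixed order:

1. **EMA detrend** — an exponential moving average tracks the slow level;
   its residual ``y - EMA`` is the drift-free signal (one-pole high-pass,
   cutoff ``1/(2*pi*tau)`` with ``tau = alpha/(1-alpha)`` samples; the
   default alpha = 0.98 at TR = 1 s gives tau = 49 and ~0.003 Hz, below the
   0.01-0.12 Hz BOLD band).
2. **Spike-gating Kalman filter** — a scalar random-walk Kalman smoother
   doubling as low-pass and despiker: when the innovation-weighted update
   ``|K*(y - x_pred)|`` exceeds ``Th_sp = 0.9 * std(y_0..y_t)`` (SD tracked
   incrementally), the measurement update is vetoed and the filter coasts on
   its prediction.  The noise ratio is set from the update ratio lambda = 4
   (``q = r / lambda**2`` with r tracking the running input variance), which
   places the low-pass cutoff near ``1/(pi*lambda)`` ~ 0.1 Hz.
3. **Range normalization** — the display value is the position of the sample
   inside the incrementally tracked [min, max] range, floored by the range
   implied by a 1% expected BOLD effect; once grown the range never shrinks
   within a session.

Stage order matters: despiking relies on a stationary (detrended) input, and
normalization must see the filtered signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .spectral import FilterConfig, estimate_t2
from .types import FidFrame, ParameterError, SessionDesign

__all__ = [
    "ChainConfig",
    "RunningStats",
    "EmaFilter",
    "SpikeGateKalman",
    "RangeNormalizer",
    "FeedbackChain",
    "FeedbackPipeline",
    "ema_time_constant",
    "ema_cutoff_hz",
    "ema_highpass_gain",
]


def ema_time_constant(alpha: float) -> float:
    """Filter time constant in samples, ``tau = alpha / (1 - alpha)``."""
    if not 0 <= alpha < 1:
        raise ParameterError("alpha must be in [0, 1)")
    return alpha / (1.0 - alpha)


def ema_cutoff_hz(alpha: float, tr: float = 1.0) -> float:
    """-3 dB cutoff of the EMA low-pass, ``1 / (2*pi*tau*TR)`` in Hz."""
    tau = ema_time_constant(alpha)
    if tau == 0:
        return math.inf
    return 1.0 / (2.0 * math.pi * tau * tr)


def ema_highpass_gain(alpha: float, freq: float, tr: float = 1.0) -> float:
    """Closed-form amplitude gain of the detrending residual ``y - EMA``.

    The smoother has transfer ``H(z) = (1-alpha) / (1 - alpha z^-1)``; the
    residual path is ``1 - H`` evaluated at ``z = exp(i*2*pi*freq*tr)``.
    """
    w = 2.0 * math.pi * freq * tr
    z = complex(math.cos(w), math.sin(w))
    h = (1.0 - alpha) / (1.0 - alpha / z)
    return abs(1.0 - h)


class RunningStats:
    """Single-pass (Welford) mean/SD tracker; SD uses the n-1 denominator."""

    def __init__(self) -> None:
        self.n = 0
        self.mean = 0.0
        self._m2 = 0.0

    def push(self, y: float) -> None:
        if not math.isfinite(y):
            raise ParameterError("non-finite input to RunningStats")
        self.n += 1
        delta = y - self.mean
        self.mean += delta / self.n
        self._m2 += delta * (y - self.mean)

    @property
    def var(self) -> float:
        if self.n < 2:
            return 0.0
        return self._m2 / (self.n - 1)

    @property
    def std(self) -> float:
        return math.sqrt(self.var)


class EmaFilter:
    """Exponential moving average; ``step`` returns the detrended residual."""

    def __init__(self, alpha: float = 0.98) -> None:
        if not 0 <= alpha < 1:
            raise ParameterError("alpha must be in [0, 1)")
        self.alpha = alpha
        self.current_avg: float | None = None

    def step(self, y: float) -> float:
        if not math.isfinite(y):
            raise ParameterError("non-finite input to EmaFilter")
        if self.current_avg is None:
            self.current_avg = y
        else:
            self.current_avg = self.alpha * self.current_avg + (1.0 - self.alpha) * y
        return y - self.current_avg


class SpikeGateKalman:
    """Scalar random-walk Kalman filter with a spike veto on the update.

    The observation-noise variance ``r`` tracks the running variance of the
    input (floored at ``r_floor``) and the process noise is
    ``q = r / lambda_ratio**2``, so the steady-state gain — and with it the
    low-pass cutoff — depends only on lambda.  When ``step`` is called
    without an explicit threshold the spike threshold is
    ``thsp_coeff * std`` of the inputs seen so far; the gate stays disabled
    until ``warmup`` samples have accumulated (a sample SD from fewer points
    is too unstable to gate on).
    """

    def __init__(
        self,
        lambda_ratio: float = 4.0,
        thsp_coeff: float = 0.9,
        warmup: int = 10,
        r_floor: float = 1e-12,
    ) -> None:
        if lambda_ratio <= 0:
            raise ParameterError("lambda_ratio must be > 0")
        self.lambda_ratio = lambda_ratio
        self.thsp_coeff = thsp_coeff
        self.warmup = max(2, int(warmup))
        self.r_floor = r_floor
        self.x_est: float | None = None
        self.p_cov = 0.0
        self.stats = RunningStats()

    def threshold(self) -> float | None:
        """Current spike threshold, or None while the gate is disabled."""
        if self.stats.n < self.warmup:
            return None
        sd = self.stats.std
        if sd <= 0:
            return None
        return self.thsp_coeff * sd

    def step(self, y: float, threshold: float | None = "auto") -> tuple[float, bool]:
        """Advance one sample; return ``(filtered, spike_flag)``.

        ``threshold`` overrides the internal running-SD threshold (pass
        ``None`` to disable the gate, ``math.inf`` to force plain Kalman
        behaviour explicitly).
        """
        if not math.isfinite(y):
            raise ParameterError("non-finite input to SpikeGateKalman")
        # r is estimated from the samples *before* the current one, so an
        # outlier cannot deflate its own gain; the spike threshold, per the
        # incremental-SD rule, does include the current sample.
        prior_var = self.stats.var
        self.stats.push(y)
        if isinstance(threshold, str) and threshold == "auto":
            threshold = self.threshold()
        r = max(prior_var, self.r_floor)
        q = r / self.lambda_ratio**2
        if self.x_est is None:
            self.x_est = y
            self.p_cov = r
            return y, False
        x_pred = self.x_est
        p_pred = self.p_cov + q
        gain = p_pred / (p_pred + r)
        update = gain * (y - x_pred)
        if threshold is not None and abs(update) > threshold:
            # Spike: veto the measurement, coast on the prediction.
            self.x_est = x_pred
            self.p_cov = p_pred
            return self.x_est, True
        self.x_est = x_pred + update
        self.p_cov = (1.0 - gain) * p_pred
        return self.x_est, False


class RangeNormalizer:
    """Map the filtered signal into [0, 1] against a non-shrinking range."""

    def __init__(self, floor_range: float) -> None:
        if floor_range < 0:
            raise ParameterError("floor_range must be >= 0")
        self.floor_range = floor_range
        self.obs_min: float | None = None
        self.obs_max: float | None = None
        self._range = floor_range

    def step(self, y: float) -> float:
        if not math.isfinite(y):
            raise ParameterError("non-finite input to RangeNormalizer")
        if self.obs_min is None:
            self.obs_min = self.obs_max = y
        else:
            self.obs_min = min(self.obs_min, y)
            self.obs_max = max(self.obs_max, y)
        self._range = max(self._range, self.obs_max - self.obs_min,
                          self.floor_range)
        if self._range <= 0:
            return 0.0
        return float(np.clip((y - self.obs_min) / self._range, 0.0, 1.0))


@dataclass(frozen=True)
class ChainConfig:
    """Parameters of the three-stage feedback chain (reference defaults)."""

    alpha: float = 0.98
    lambda_ratio: float = 4.0
    thsp_coeff: float = 0.9
    floor_fraction: float = 0.01
    spike_source: str = "detrended"
    spike_warmup: int = 10

    def __post_init__(self) -> None:
        if self.spike_source not in ("detrended", "raw"):
            raise ParameterError("spike_source must be 'detrended' or 'raw'")
        if not 0 <= self.alpha < 1:
            raise ParameterError("alpha must be in [0, 1)")
        if self.floor_fraction < 0:
            raise ParameterError("floor_fraction must be >= 0")


class FeedbackChain:
    """EMA -> spike-gating Kalman -> normalizer, on a scalar stream.

    ``floor_range`` defaults to ``floor_fraction`` of the first input (the
    1%-expected-effect convention on a T2* series whose first retained sample
    approximates the baseline level).
    """

    def __init__(
        self, config: ChainConfig | None = None, floor_range: float | None = None
    ) -> None:
        self.config = config if config is not None else ChainConfig()
        self.ema = EmaFilter(self.config.alpha)
        self.kalman = SpikeGateKalman(
            lambda_ratio=self.config.lambda_ratio,
            thsp_coeff=self.config.thsp_coeff,
            warmup=self.config.spike_warmup,
        )
        self._raw_stats = RunningStats()
        self._floor_range = floor_range
        self.normalizer: RangeNormalizer | None = None

    def _raw_threshold(self) -> float | None:
        if self._raw_stats.n < self.config.spike_warmup:
            return None
        sd = self._raw_stats.std
        return self.config.thsp_coeff * sd if sd > 0 else None

    def step(self, y: float) -> dict:
        """Process one raw sample; returns every intermediate value."""
        if self._floor_range is None:
            self._floor_range = self.config.floor_fraction * abs(y)
        if self.normalizer is None:
            self.normalizer = RangeNormalizer(self._floor_range)
        self._raw_stats.push(y)
        detrended = self.ema.step(y)
        if self.config.spike_source == "raw":
            # Threshold tracks the raw series (current sample included).
            filtered, spike = self.kalman.step(
                detrended, threshold=self._raw_threshold()
            )
        else:
            filtered, spike = self.kalman.step(detrended)
        feedback = self.normalizer.step(filtered)
        return {
            "raw": y,
            "detrended": detrended,
            "filtered": filtered,
            "filtered_abs": filtered + (self.ema.current_avg or 0.0),
            "spike": spike,
            "feedback": feedback,
        }

    def process(self, series: Sequence[float]) -> pd.DataFrame:
        """Batch convenience: identical to feeding ``step`` sample by sample."""
        return pd.DataFrame([self.step(float(y)) for y in series])


class FeedbackPipeline:
    """Frame-in, feedback-out: spectral T2* estimation + feedback chain.

    The first ``design.n_discard`` repetitions are estimated (and logged)
    but never enter the filter states, mirroring the discarded T1-transient
    volumes.  A frame whose fit fails reuses the previous valid T2* (with a
    warning); leading failures before any valid estimate are logged as NaN
    and skipped by the chain.
    """

    def __init__(
        self,
        filter_config: FilterConfig | None = None,
        chain_config: ChainConfig | None = None,
        design: SessionDesign | None = None,
    ) -> None:
        self.filter_config = filter_config if filter_config is not None else FilterConfig()
        self.chain_config = chain_config if chain_config is not None else ChainConfig()
        self.design = design if design is not None else SessionDesign()
        self.chain = FeedbackChain(self.chain_config)
        self._last_valid: float | None = None
        self._rep = 0

    def process_frame(self, frame: FidFrame) -> dict:
        """One repetition: returns the full diagnostics row."""
        k = self._rep
        self._rep += 1
        est = estimate_t2(frame, self.filter_config)
        t2 = est.t2star
        if not est.ok:
            warnings.warn(f"repetition {k}: non-decaying fit, reusing previous T2*")
            t2 = self._last_valid if self._last_valid is not None else np.nan
        else:
            self._last_valid = est.t2star
        row = {
            "rep_index": k,
            "t2star_raw": t2,
            "fit_ok": est.ok,
            "detrended": np.nan,
            "filtered": np.nan,
            "filtered_abs": np.nan,
            "spike_flag": False,
            "feedback_norm": np.nan,
        }
        if k < self.design.n_discard or not np.isfinite(t2):
            return row
        out = self.chain.step(float(t2))
        row.update(
            detrended=out["detrended"],
            filtered=out["filtered"],
            filtered_abs=out["filtered_abs"],
            spike_flag=out["spike"],
            feedback_norm=out["feedback"],
        )
        return row

    def process_session(self, frames: Sequence[FidFrame]) -> pd.DataFrame:
        """Streaming replay of a stored session, one frame per step."""
        return pd.DataFrame([self.process_frame(f) for f in frames])
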