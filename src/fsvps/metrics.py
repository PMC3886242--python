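"""Session-level quality measures for block-design T2* time series.

Implements the standard performance measures for the method: contrast-to-noise
ratio, percent signal change, a block-design GLM t-value, event-related
(cycle-locked) averages with their SD, and an event-related SNR.

Conventions: variances use the n-1 denominator throughout; CNR and percent
change use block-wise means/variances over all labelled repetitions without
transition trimming (a ``trim`` option exists, default 0); the GLM regressor
is the raw condition boxcar — a haemodynamic convolution switch is provided
but off by default, since with 30 s blocks its effect on the regressor is
minor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy.special import gamma as _gamma_fn

from .types import ACTIVATION, BASELINE, ParameterError, SessionDesign

__all__ = [
    "BlockStats",
    "EventAverage",
    "MetricError",
    "block_stats",
    "cnr",
    "percent_change",
    "block_glm_tvalue",
    "event_average",
    "event_snr",
    "session_metrics",
]


class MetricError(ValueError):
    """The requested metric is undefined for this input."""


@dataclass(frozen=True)
class BlockStats:
    """Block-wise first and second moments of a labelled series."""

    mean_cond: float
    mean_bas: float
    var_cond: float
    var_bas: float
    n_cond: int
    n_bas: int


@dataclass
class EventAverage:
    """Cycle-locked mean and SD over complete baseline+activation cycles."""

    cycle_mean: np.ndarray
    cycle_sd: np.ndarray
    n_cycles: int


def _check_series(series: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels)
    if series.shape != labels.shape:
        raise ParameterError("series and labels must have equal length")
    return series, labels


def block_stats(series: np.ndarray, labels: np.ndarray) -> BlockStats:
    series, labels = _check_series(series, labels)
    cond = series[labels == ACTIVATION]
    bas = series[labels == BASELINE]
    if cond.size < 2 or bas.size < 2:
        raise ParameterError("both conditions need >= 2 samples")
    return BlockStats(
        mean_cond=float(cond.mean()),
        mean_bas=float(bas.mean()),
        var_cond=float(cond.var(ddof=1)),
        var_bas=float(bas.var(ddof=1)),
        n_cond=cond.size,
        n_bas=bas.size,
    )


def cnr(series: np.ndarray, labels: np.ndarray) -> float:
    """Contrast-to-noise ratio
    ``(mean_cond - mean_bas) / sqrt(var_cond + var_bas)``."""
    s = block_stats(series, labels)
    denom = s.var_cond + s.var_bas
    if denom <= 0:
        raise MetricError("zero total variance: CNR undefined")
    return (s.mean_cond - s.mean_bas) / float(np.sqrt(denom))


def percent_change(series: np.ndarray, labels: np.ndarray) -> float:
    """Fractional signal change ``(mean_cond - mean_bas) / mean_bas``."""
    s = block_stats(series, labels)
    if s.mean_bas == 0:
        raise MetricError("zero baseline mean: percent change undefined")
    return (s.mean_cond - s.mean_bas) / s.mean_bas


def _canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Double-gamma haemodynamic response sampled at TR, unit sum."""
    t = np.arange(0.0, duration, tr)
    # peak ~5 s, undershoot ~15 s, undershoot ratio 1/6
    def g(t, shape, scale):
        return (
            t ** (shape - 1)
            * np.exp(-t / scale)
            / (scale**shape * _gamma_fn(shape))
        )

    h = g(t, 6.0, 1.0) - g(t, 16.0, 1.0) / 6.0
    return h / h.sum()


def block_glm_tvalue(
    series: np.ndarray,
    labels: np.ndarray,
    tr: float = 1.0,
    convolve_hrf: bool = False,
    trim: int = 0,
) -> float:
    """t-value of the boxcar regressor in ``series ~ 1 + boxcar``.

    Ordinary least squares with n-2 degrees of freedom.  ``trim`` drops that
    many repetitions after every condition transition before fitting.  A
    perfectly explained series (zero residual variance) returns ``inf`` as
    the infinite-t flag.
    """
    series, labels = _check_series(series, labels)
    regressor = (labels == ACTIVATION).astype(float)
    if convolve_hrf:
        h = _canonical_hrf(tr)
        regressor = np.convolve(regressor, h)[: regressor.size]
    if trim > 0:
        edges = np.flatnonzero(np.diff(labels) != 0) + 1
        drop = np.zeros(labels.size, dtype=bool)
        for e in edges:
            drop[e : e + trim] = True
        series, regressor = series[~drop], regressor[~drop]
    n = series.size
    if n < 5:
        raise ParameterError("need >= 3 more samples than regressors")
    if np.ptp(regressor) == 0:
        raise ParameterError("regressor is constant: contrast undefined")
    X = sm.add_constant(regressor)
    fit = sm.OLS(series, X).fit()
    scale = float(np.dot(series, series)) or 1.0
    if fit.ssr <= 1e-12 * scale:
        return float(np.inf)
    return float(fit.tvalues[1])


def event_average(series: np.ndarray, design: SessionDesign) -> EventAverage:
    """Cycle-locked average of a full-session series.

    ``series`` is aligned to ``design.labels`` (length ``n_reps``).  Cycles
    are consecutive baseline+activation pairs; only complete cycles entirely
    inside the retained portion (index >= ``n_discard``) are used, so a
    leading cycle broken by the discards and any trailing partial cycle are
    dropped.
    """
    series = np.asarray(series, dtype=float)
    if series.size != design.n_reps:
        raise ParameterError("series must cover the full session")
    cyc = design.cycle_len
    start = int(np.ceil(design.n_discard / cyc)) * cyc
    n_cycles = (design.n_reps - start) // cyc
    if n_cycles < 2:
        raise MetricError("need >= 2 complete cycles for an event average")
    block = series[start : start + n_cycles * cyc].reshape(n_cycles, cyc)
    return EventAverage(
        cycle_mean=block.mean(axis=0),
        cycle_sd=block.std(axis=0, ddof=1),
        n_cycles=n_cycles,
    )


def event_snr(ev: EventAverage) -> float:
    """Peak-to-peak of the cycle mean over the mean positionwise SD.

    The estimator is a repository convention: an event-related SNR is
    reported in the field without a standard definition.
    """
    sd = float(np.mean(ev.cycle_sd))
    if sd <= 0:
        raise MetricError("zero mean cycle SD: event SNR undefined")
    return float(np.ptp(ev.cycle_mean)) / sd


def session_metrics(feedback: "pd.DataFrame", design: SessionDesign) -> dict:
    """Quality report of one processed session.

    ``feedback`` is the frame-by-frame log produced by the real-time chain
    (see :mod:`fsvps.chain`).  CNR and the GLM t-value are computed on the
    detrended + Kalman-filtered series (both are invariant to the removed
    offset); percent change and the event-related measures need the baseline
    level, so they use the re-offset series (Kalman output plus the current
    EMA level, i.e. the despiked series on its original scale).
    """
    import pandas as pd  # local: keep module import light

    if not isinstance(feedback, pd.DataFrame):
        raise ParameterError("feedback must be the chain's log DataFrame")
    retained = feedback[feedback["rep_index"] >= design.n_discard]
    labels = design.retained_labels
    filt = retained["filtered"].to_numpy()
    filt_abs = retained["filtered_abs"].to_numpy()

    full_abs = np.full(design.n_reps, np.nan)
    full_abs[retained["rep_index"].to_numpy()] = filt_abs
    # Discarded leading frames never enter an averaged cycle, but the array
    # must span the session for cycle alignment.
    ev = event_average(np.nan_to_num(full_abs, nan=0.0), design)

    t_value = block_glm_tvalue(filt, labels, tr=design.tr)
    return {
        "cnr": cnr(filt, labels),
        "percent": percent_change(filt_abs, labels),
        "t_value": t_value,
        "dof": int(filt.size - 2),
        "event_snr": event_snr(ev),
        "n_cycles": ev.n_cycles,
    }
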