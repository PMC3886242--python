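"""Core data types shared across the fSVPS pipeline.

The method works on repeated single-voxel free-induction decays (FIDs): one
complex time-domain acquisition per repetition (TR), from a voxel whose water
signal is *not* suppressed.  Everything downstream — T2* estimation, the
real-time feedback chain, quality metrics — is expressed in terms of the
small value objects defined here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Condition codes used in block-design labels.
BASELINE: int = 0
ACTIVATION: int = 1


class ParameterError(ValueError):
    """An input parameter violates a type invariant."""


class DegenerateSignalError(ValueError):
    """The signal content makes the requested operation undefined."""


@dataclass(frozen=True)
class ComponentSpec:
    """One exponentially decaying oscillator of the FID model.

    The FID is modelled as a sum of components
    ``A * exp(i*2*pi*f*t) * exp(i*phi) * exp(-t/T2*)``.

    Parameters
    ----------
    amplitude : float
        Component amplitude ``A`` (arbitrary signal units, >= 0).
    frequency : float
        Offset frequency ``f`` in Hz relative to the receiver centre.
    phase : float
        Constant phase ``phi`` in radians.
    t2star : float
        Effective transverse relaxation time ``T2*`` in seconds (> 0).
    """

    amplitude: float
    frequency: float
    phase: float
    t2star: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise ParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if not np.isfinite(self.t2star) or self.t2star <= 0:
            raise ParameterError(f"t2star must be > 0, got {self.t2star}")


@dataclass(frozen=True)
class AcquisitionParams:
    """Receiver settings of one FID readout.

    Defaults emulate a 7 T spin-echo single-voxel protocol: 1 kHz acquisition
    bandwidth (1 ms dwell), 512 complex points, TE = 20 ms.  The time axis
    starts at t = 0 at the first acquired sample; TE is metadata recording the
    offset of that sample from excitation and takes no part in the fits.
    """

    bandwidth: float = 1000.0
    n_points: int = 512
    te: float = 0.020

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ParameterError(f"bandwidth must be > 0, got {self.bandwidth}")
        if self.n_points < 8:
            raise ParameterError(f"n_points must be >= 8, got {self.n_points}")

    @property
    def dwell(self) -> float:
        """Sampling interval in seconds (1/bandwidth)."""
        return 1.0 / self.bandwidth

    @property
    def duration(self) -> float:
        """Total readout duration in seconds."""
        return self.n_points / self.bandwidth

    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t_k = k / bandwidth``."""
        return np.arange(self.n_points) / self.bandwidth


@dataclass
class FidFrame:
    """One complex FID: the raw signal of a single repetition."""

    samples: np.ndarray
    bandwidth: float
    te: float = 0.020

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ParameterError("samples must be a non-empty 1-D array")
        if self.bandwidth <= 0:
            raise ParameterError(f"bandwidth must be > 0, got {self.bandwidth}")

    @property
    def n_points(self) -> int:
        return self.samples.size

    def times(self) -> np.ndarray:
        return np.arange(self.n_points) / self.bandwidth


def alternating_block_labels(n_reps: int, block_len: int) -> np.ndarray:
    """Per-repetition condition labels of an alternating block design.

    Blocks of ``block_len`` repetitions alternate BASELINE / ACTIVATION,
    starting with baseline.
    """
    if block_len <= 0:
        raise ParameterError(f"block_len must be > 0, got {block_len}")
    return ((np.arange(n_reps) // block_len) % 2).astype(np.int64)


@dataclass
class SessionDesign:
    """Block timing of one session.

    Defaults follow the reference paradigm: TR = 1 s, 300 repetitions in ten
    alternating 30 s blocks (5 baseline + 5 activation), with the first 10
    repetitions discarded to avoid the T1 saturation transient.
    """

    tr: float = 1.0
    n_reps: int = 300
    n_discard: int = 10
    block_len: int = 30
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ParameterError(f"tr must be > 0, got {self.tr}")
        if self.n_reps <= 0:
            raise ParameterError(f"n_reps must be > 0, got {self.n_reps}")
        if not 0 <= self.n_discard < self.n_reps:
            raise ParameterError(
                f"n_discard must be in [0, n_reps), got {self.n_discard}"
            )
        if self.labels is None:
            self.labels = alternating_block_labels(self.n_reps, self.block_len)
        else:
            self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.n_reps,):
            raise ParameterError("labels must have length n_reps")
        if not np.isin(self.labels, (BASELINE, ACTIVATION)).all():
            raise ParameterError("labels must contain only BASELINE/ACTIVATION")
        if self.labels[0] != BASELINE:
            raise ParameterError("blocks must start with a baseline block")

    @property
    def retained_labels(self) -> np.ndarray:
        """Labels of the repetitions kept for analysis."""
        return self.labels[self.n_discard:]

    @property
    def cycle_len(self) -> int:
        """Length of one baseline+activation cycle in repetitions."""
        return 2 * self.block_len


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance processes of a simulated session.

    complex_noise_sd
        Per-quadrature SD of the additive complex Gaussian sample noise
        (signal units; water amplitude defaults to 1).
    drift_amplitude, drift_period
        Fractional amplitude and period (s) of a slow sinusoidal modulation
        applied to both the water amplitude and its T2* (scanner/physiology
        drift); the sinusoid phase is randomised per session.
    spike_prob, spike_scale
        Per-repetition probability of a transient artifact and its size as a
        multiple of the SD of the deterministic true-T2* path.
    b0_wander_sd
        Per-repetition SD (Hz) of the random walk of the water centre
        frequency (slow B0 drift).
    rng_seed
        Seed of the session random stream.
    """

    complex_noise_sd: float = 0.01
    drift_amplitude: float = 0.01
    drift_period: float = 120.0
    spike_prob: float = 0.02
    spike_scale: float = 8.0
    b0_wander_sd: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("complex_noise_sd", "drift_amplitude", "drift_period",
                     "spike_scale", "b0_wander_sd"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if not 0.0 <= self.spike_prob <= 1.0:
            raise ParameterError("spike_prob must be in [0, 1]")


@dataclass(frozen=True)
class BoldModel:
    """BOLD modulation of the water T2*.

    ``baseline_t2star`` is the resting T2* (s); during activation blocks T2*
    tends to ``baseline * (1 + activation_delta)`` with a first-order
    transition of time constant ``transition_tau`` (s).  ``transition_tau = 0``
    gives an ideal boxcar.
    """

    baseline_t2star: float = 0.085
    activation_delta: float = 0.05
    transition_tau: float = 3.0

    def __post_init__(self) -> None:
        if self.baseline_t2star <= 0:
            raise ParameterError("baseline_t2star must be > 0")
        if 1.0 + self.activation_delta <= 0:
            raise ParameterError("1 + activation_delta must be > 0")
        if self.transition_tau < 0:
            raise ParameterError("transition_tau must be >= 0")


@dataclass
class TruthRecord:
    """Ground truth of a simulated session, for recovery tests."""

    true_t2star: np.ndarray
    spike_positions: np.ndarray
    labels: np.ndarray
    center_freq: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.true_t2star)
        if not (len(self.labels) == n == len(self.center_freq)):
            raise ParameterError("truth arrays must all have length n_reps")
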