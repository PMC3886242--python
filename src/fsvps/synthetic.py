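"""Synthetic unsuppressed-water FID sessions with ground truth.

Every downstream stage of the package is testable against this generator: it
produces FID frames with the statistical structure the analysis assumes —
an exponentially decaying water resonance whose T2* is modulated by a block
BOLD paradigm, plus the nuisances the real-time filters exist to remove
(slow amplitude/T2* drift, sporadic spike artifacts, additive complex
Gaussian noise, and a slow random walk of the water centre frequency).

The generator is deterministic for a fixed seed, and its random stream is
consumed in a fixed order (drift phase, B0 walk, spike mask, per-frame
noise), so two sessions differing only in ``spike_prob`` share every frame
outside the spiked repetitions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import (
    ACTIVATION,
    AcquisitionParams,
    BoldModel,
    ComponentSpec,
    FidFrame,
    NoiseModel,
    ParameterError,
    SessionDesign,
    TruthRecord,
)

__all__ = ["generate_fid", "bold_t2star_path", "generate_session"]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def generate_fid(
    components: Sequence[ComponentSpec],
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> FidFrame:
    """Synthesize one FID from a list of exponential components.

    ``samples[k] = sum_j A_j exp(i 2 pi f_j t_k) exp(i phi_j) exp(-t_k/T2*_j)``
    with ``t_k = k / bandwidth``, plus additive complex Gaussian noise of SD
    ``noise_sd`` per quadrature.
    """
    if len(components) == 0:
        raise ParameterError("at least one component is required")
    for c in components:
        if abs(c.frequency) >= acq.bandwidth / 2:
            raise ParameterError(
                f"component frequency {c.frequency} Hz outside +/- bandwidth/2"
            )
    t = acq.times()
    samples = np.zeros(acq.n_points, dtype=np.complex128)
    for c in components:
        samples += (
            c.amplitude
            * np.exp(1j * (2.0 * np.pi * c.frequency * t + c.phase))
            * np.exp(-t / c.t2star)
        )
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    if noise_sd > 0:
        rng = _as_rng(rng)
        samples = samples + noise_sd * (
            rng.standard_normal(acq.n_points)
            + 1j * rng.standard_normal(acq.n_points)
        )
    return FidFrame(samples=samples, bandwidth=acq.bandwidth, te=acq.te)


def bold_t2star_path(design: SessionDesign, bold: BoldModel) -> np.ndarray:
    """Deterministic per-repetition water T2* under the block paradigm.

    T2* relaxes toward the label-dependent target with a first-order step
    response of time constant ``transition_tau``; ``tau = 0`` reproduces the
    ideal boxcar.
    """
    base = bold.baseline_t2star
    active = base * (1.0 + bold.activation_delta)
    targets = np.where(design.labels == ACTIVATION, active, base)
    if bold.transition_tau <= 0:
        return targets.astype(np.float64)
    decay = np.exp(-design.tr / bold.transition_tau)
    path = np.empty(design.n_reps, dtype=np.float64)
    x = base
    for k in range(design.n_reps):
        x = targets[k] + (x - targets[k]) * decay
        path[k] = x
    return path


def generate_session(
    design: SessionDesign | None = None,
    bold: BoldModel | None = None,
    water: ComponentSpec | None = None,
    contaminants: Sequence[ComponentSpec] = (),
    acq: AcquisitionParams | None = None,
    noise: NoiseModel | None = None,
) -> tuple[list[FidFrame], TruthRecord]:
    """Simulate a full block-design session; return frames and ground truth.

    The water component's T2* follows :func:`bold_t2star_path`; its amplitude
    and T2* are modulated by the fractional drift sinusoid, every component's
    frequency is offset by the cumulative B0 random walk, and spiked
    repetitions have the water T2* displaced by
    ``spike_scale * SD(deterministic T2* path)``.

    The ``water.t2star`` field serves as nominal metadata only — the session
    value comes from ``bold``; ``water.frequency`` is the nominal centre
    offset the B0 walk starts from.
    """
    design = design if design is not None else SessionDesign()
    bold = bold if bold is not None else BoldModel()
    acq = acq if acq is not None else AcquisitionParams()
    noise = noise if noise is not None else NoiseModel()
    if water is None:
        water = ComponentSpec(
            amplitude=1.0, frequency=0.0, phase=0.5, t2star=bold.baseline_t2star
        )

    rng = np.random.default_rng(noise.rng_seed)
    n = design.n_reps
    rep_times = np.arange(n) * design.tr

    t2_path = bold_t2star_path(design, bold)

    # Fractional drift on water amplitude and T2*; random phase per session.
    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    if noise.drift_period > 0:
        drift = noise.drift_amplitude * np.sin(
            2.0 * np.pi * rep_times / noise.drift_period + drift_phase
        )
    else:
        drift = np.zeros(n)

    # Slow random walk of the centre frequency (B0 wander); shifts all lines.
    wander = np.cumsum(rng.normal(0.0, noise.b0_wander_sd, size=n))

    # Spike mask drawn unconditionally to keep the stream position fixed.
    spike_draws = rng.random(n)
    spike_mask = spike_draws < noise.spike_prob

    true_t2 = t2_path * (1.0 + drift)
    sd_ref = float(np.std(true_t2))
    true_t2 = true_t2.copy()
    true_t2[spike_mask] += noise.spike_scale * sd_ref

    amp = water.amplitude * (1.0 + drift)

    frames: list[FidFrame] = []
    for k in range(n):
        comps = [
            ComponentSpec(
                amplitude=amp[k],
                frequency=water.frequency + wander[k],
                phase=water.phase,
                t2star=true_t2[k],
            )
        ]
        for c in contaminants:
            comps.append(
                ComponentSpec(
                    amplitude=c.amplitude,
                    frequency=c.frequency + wander[k],
                    phase=c.phase,
                    t2star=c.t2star,
                )
            )
        frames.append(generate_fid(comps, acq, noise.complex_noise_sd, rng))

    truth = TruthRecord(
        true_t2star=true_t2,
        spike_positions=np.flatnonzero(spike_mask),
        labels=design.labels.copy(),
        center_freq=water.frequency + wander,
    )
    return frames, truth
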