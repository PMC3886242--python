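import pytest

from fsvps import (
    AcquisitionParams,
    BoldModel,
    ComponentSpec,
    NoiseModel,
    SessionDesign,
    generate_fid,
)


@pytest.fixture
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture
def water_frame(acq):
    """Noiseless on-resonance water FID (A=1, phi=0.5, T2*=85 ms)."""
    return generate_fid([ComponentSpec(1.0, 0.0, 0.5, 0.085)], acq)


@pytest.fixture
def small_design() -> SessionDesign:
    """Compact block design for fast session-level tests."""
    return SessionDesign(tr=1.0, n_reps=60, n_discard=4, block_len=10)


@pytest.fixture
def quiet_noise() -> NoiseModel:
    """All nuisance processes off."""
    return NoiseModel(
        complex_noise_sd=0.0,
        drift_amplitude=0.0,
        spike_prob=0.0,
        b0_wander_sd=0.0,
        rng_seed=0,
    )


@pytest.fixture
def boxcar_bold() -> BoldModel:
    return BoldModel(activation_delta=0.05, transition_tau=0.0)
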