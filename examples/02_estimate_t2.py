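"""Estimate T2* from a single FID by complex log-linear regression.

A noiseless on-resonance water component is recovered exactly by the
log-line fit; a noisy off-resonance frame goes through the full chain
(peak shift, Gaussian window, fit with window-transfer correction).
"""

import numpy as np

from fsvps import (
    AcquisitionParams,
    ComponentSpec,
    FilterConfig,
    estimate_t2,
    generate_fid,
    loglinear_t2,
)

acq = AcquisitionParams()  # 1 kHz bandwidth, 512 points, TE 20 ms

clean = generate_fid([ComponentSpec(2.5, 0.0, 0.7, 0.05)], acq)
est = loglinear_t2(clean, l=0.1)
print("noiseless fit: "
      f"T2* = {est.t2star * 1e3:.6f} ms (true 50), "
      f"A = {est.amplitude:.6f} (true 2.5), phi = {est.phase:.6f} (true 0.7)")

noisy = generate_fid(
    [
        ComponentSpec(1.0, 35.0, 0.5, 0.085),      # water, 35 Hz off-centre
        ComponentSpec(0.05, -180.0, 0.0, 0.03),    # lipid-like contaminant
    ],
    acq,
    noise_sd=0.01,
    rng=np.random.default_rng(0),
)
est = estimate_t2(noisy, FilterConfig())
print("full chain on a noisy off-resonance frame: "
      f"T2* = {est.t2star * 1e3:.2f} ms (true 85), "
      f"residual rms = {est.residual_rms:.4f}")
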