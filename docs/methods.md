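# Methods

## Signal model

The free-induction decay of one repetition is modelled as a sum of
exponentially decaying oscillators,

    FID(t) = Σ_j A_j · exp(i 2π f_j t) · exp(i φ_j) · exp(−t / T2*_j),

sampled at the acquisition bandwidth (default 1 kHz, 512 complex points,
t = 0 at the first acquired sample; the echo time, default 20 ms, is carried
as metadata only and plays no part in any fit).  In an unsuppressed-water
acquisition the water line dominates; off-resonance lines (lipids,
metabolites) are nuisances.  After shifting the detected water peak to 0 Hz
and windowing the spectrum with a Gaussian centred there, the processed FID
is approximated by the single water component, so its complex logarithm is a
straight line: the real slope is −1/T2*, the real intercept ln A, the
imaginary intercept the phase.  The regression is realised as two real OLS
fits — log magnitude for T2* and amplitude, time-unwrapped phase for φ —
which avoids the branch ambiguity of the complex logarithm.  A window with a
non-negative fitted slope has no net decay; the estimate is flagged invalid
and streaming callers reuse the previous valid sample.

### Water-peak detection

Argmax of the magnitude spectrum refined by three-point parabolic
interpolation on the log magnitude.  The refinement is exact for a Gaussian
line and good to a small fraction of a bin for a Lorentzian; an all-zero
spectrum raises a no-peak error, and edge bins fall back to the raw argmax.

### Gaussian window and its transfer correction

The default window SD is 20 Hz — wide enough to pass the few-Hz water line
after shimming, narrow enough to suppress lines ≥ ~100 Hz off-water at 7 T
(a lipid-like line 180 Hz off-water is attenuated ~10⁻¹⁸).  Multiplying the
spectrum by a Gaussian equals convolving the FID with a ~1/(2πσ) ≈ 8 ms
kernel.  On a one-sided decay this distorts the first few kernel widths
(the kernel reaches into t < 0 where no signal exists), which tilts the
early log magnitude and biases the fitted T2* upward — about +24% at the
default σ = 20 Hz and l = 100 ms, and, because the bias is nonlinear in
T2*, it also inflates a 5% block contrast to about 6.1%.  Since the forward
map (noiseless exponential → window → log-line fit) is known exactly, the
estimator inverts it: a cached table of the transfer on a log grid of decay
times initialises a Newton solve per frame.  With the correction a noiseless
single-component frame is recovered to machine precision and the block
contrast is unbiased; `FilterConfig(window_bias_correction=False)` restores
the raw log-line estimate.  Very short windows (≲ 45 samples at the default
σ) contain the rising edge of the kernel transient and no net decay; they
are structurally unusable and the fit flags them rather than extrapolating.

### Regression-length optimization

Too short a regression window wastes decay information; too long a window
includes the nonlinear FID tail (poor shim, residual contamination, noise
floor).  `optimize_regression_length` scans a candidate grid (default every
sample from 16 points to the full readout), computes the full T2* series per
candidate on a labelled calibration session (discarded repetitions removed),
scores each series with the block GLM t-value, and returns the argmax with
ties broken toward the shorter length (shorter sampling favours speed).
Candidates where any per-frame fit fails, or whose series is degenerate
(non-finite t, e.g. a saturated constant series), are ineligible — the
carry-forward rule exists for streaming sessions, and scoring a curve on
carried-forward samples would reward exactly the lengths that cannot be
fit.  On simulated default sessions the optimum falls around 130–250 ms
with t ≈ 16–20, an interior optimum of the same character the method shows
on real voxels.

## Real-time chain

Three stages run per TR, in fixed order (detrend → despike/low-pass →
normalize); the first `n_discard` repetitions (default 10, the T1
saturation transient) are estimated and logged but never touch filter
state.

**EMA detrending.**  `avg ← α·avg + (1−α)·y` (initialised at the first
sample), output `y − avg`.  With α = 0.98 at TR = 1 s the time constant is
τ = α/(1−α) = 49 samples and the −3 dB cutoff 1/(2πτ) ≈ 0.0032 Hz — below
the 0.01–0.12 Hz band where block-design BOLD power lives, so drift is
removed while the response passes.  The residual form `y − EMA` is the
high-pass reading of "drift removal"; the closed-form residual gain
|1 − H(e^{iω})| of the one-pole smoother is exported and verified against
simulation to 0.01%.

**Spike-gating Kalman filter.**  Scalar random-walk model, H = 1: predict
`x⁻ = x`, `p⁻ = p + q`; gain `K = p⁻/(p⁻ + r)`.  The observation-noise
variance r tracks the running variance of the filter input and the process
noise is `q = r/λ²`, so the steady-state gain — hence the low-pass cutoff,
≈ 1/(πλ) ≈ 0.08 Hz at λ = 4 — depends only on the update ratio λ.  r is
estimated from the samples *before* the current one: letting the current
sample into r would allow an outlier to deflate its own gain and slip under
the threshold.  The spike rule vetoes the measurement update (the filter
coasts on its prediction) when |K(y − x⁻)| exceeds 0.9·std(y₀…y_t), the
incrementally (Welford) tracked SD of the input *including* the current
sample.  The gate stays disabled for the first `spike_warmup` samples
(default 10): a sample SD from fewer points is too unstable to gate on.
The threshold source is configurable (`spike_source`): the detrended series
(default — it is the stationary one) or the raw T2* series.

Two structural properties follow from the threshold definition and are
visible in the validation numbers: spikes arriving while n is still small
inflate their own threshold (a single spike before n ≈ 18 cannot exceed
0.9·SD of a series it dominates), and the second of two adjacent spikes
sees an r already inflated by the first.  Sensitivity on injected 100×-SD
artifacts is therefore ~90–100% rather than 100%, with zero false alarms
on matched spike-free sessions.  A related limitation: early in a session
with strong BOLD modulation, the first activation onset is statistically
indistinguishable from a spike until the running SD has absorbed a
transition or two, so onset samples can be gated; the first-order
haemodynamic transitions (below) soften this in practice.

**Normalization.**  The display value is the position of the filtered
sample inside the incrementally tracked [min, max] range, clipped to [0, 1].
The range is floored at `floor_fraction` (default 1%, the expected BOLD
effect) of the first retained T2* sample, and never shrinks within a
session — a subject who has reached a level is assumed able to reach it
again.  The first sample maps to 0 by construction.

## Quality metrics

Computed per session on the conditioned series, normalization excluded.
CNR and the GLM t-value are invariant to the removed baseline level, so
they use the detrended + Kalman-filtered series.  Percent change and the
event-related average need the baseline level, which detrending removes;
they use the despiked series re-offset by the current EMA level (Kalman
output + EMA), i.e. the despiked series on its original scale.  Variances
use n−1 throughout.  The GLM regressor is the raw condition boxcar —
haemodynamic convolution is available but off by default, since with 30 s
blocks it barely changes the regressor — and no motion regressors exist for
spectroscopic data.  A perfectly explained series returns an infinite-t
flag.  Event-related averages reshape the retained series into complete
baseline+activation cycles (a leading cycle broken by the discards and any
trailing partial cycle are dropped) and report positionwise mean and SD;
the event-related SNR — peak-to-peak of the cycle mean over the mean
positionwise SD — is an explicit repository convention, since the quantity
is reported in the field without a standard estimator.

## Simulator

`generate_session` emulates a 7 T spin-echo single-voxel protocol without
water suppression: TR = 1 s, 300 repetitions in ten alternating 30 s
blocks, 1 kHz bandwidth, 512 points, TE 20 ms.  The water T2* (baseline
85 ms) follows the block labels through a first-order transition
(τ = 3 s by default; τ = 0 gives an ideal boxcar) with a 5% activation
increase — the magnitude the method is designed to detect.  Nuisances, each
individually switchable:

* additive complex Gaussian noise, SD 0.01 per quadrature against a unit
  water amplitude (estimator noise ≈ 0.5 ms per T2* sample at the default
  regression length, giving session t-values in the 15–25 range observed
  for the method);
* a slow sinusoidal drift (default 1% fractional, 120 s period, random
  phase per session) applied to both the water amplitude and its T2* —
  the drift the EMA stage exists to remove;
* sporadic whole-frame spike artifacts (probability 0.02 per repetition):
  the frame's water T2* is displaced by `spike_scale` × the SD of the
  deterministic T2* path (default 8×, a ~20% excursion).  A pure amplitude
  scaling of the frame would leave the log-magnitude slope — and hence the
  control signal — unchanged, which is why spikes perturb the decay rather
  than the scale;
* a slow random walk of the centre frequency (SD 0.2 Hz per repetition),
  shifting every line, which exercises the per-frame peak tracking.

The random stream is consumed in a fixed order (drift phase, B0 walk,
spike mask, per-frame noise), so sessions differing only in `spike_prob`
are frame-identical outside the spiked repetitions — the basis of the
matched spike/no-spike specificity check.  What the simulator does *not*
model: pulse-sequence physics, multi-compartment water (the single-T2*
truth is exactly the model the estimator assumes), subject motion, and
physiological noise spectra.  Passing the recovery tests therefore shows
the pipeline is correct and well-calibrated under its own assumptions, not
that those assumptions hold in vivo — on real voxels the absolute T2* is
known to absorb spin-echo and partial-volume components, and a
multicomponent model would be the next step.

## Validation harnesses (and the conditions they fix)

* *Percent-change recovery*: 200 sessions with the boxcar limit (τ = 0,
  where the block means carry the full 5% contrast) and spikes off (a
  separate artifact channel with its own harness); noise, drift and wander
  at defaults.  Mean recovered percent change within the Monte-Carlo CI
  of 5%.
* *Spike gate*: matched session pairs with the BOLD contrast off — with a
  5% contrast the first activation onset is indistinguishable from a spike
  while the threshold warms up, so specificity is only well-posed on null
  sessions — and spikes at 100× the path SD.  ≥ 80% flagged, zero false
  alarms.
* *GLM type-I*: 2000 null white-noise series, two-sided 5% level, rejection
  rate inside the binomial 95% band.
* *Filter spectra*: EMA residual gain vs the closed form at 0.05 Hz (2%);
  Kalman periodogram power at 0.2 Hz below 0.01 Hz on 10⁴ white-noise
  samples.
* *Oracle equivalences*: GLM t vs hand-written normal equations; the
  length optimizer vs an independent brute-force candidate loop; Welford
  SD vs two-pass SD.
* *Determinism*: seeded sessions and their processed feedback are
  bitwise identical on replay.

Problem sizes (200 sessions, 2000 GLM draws, 10⁴ filter samples) are the
package's chosen Monte-Carlo budgets: large enough that the CI half-widths
sit well under the effects being checked, small enough to run routinely.

## Numerical choices

* DFT conventions: numpy FFT with centred frequency axis; the
  spectrum/FID pair is exactly invertible and Parseval-consistent.
* Phase fitting uses standard 2π-jump unwrapping along the time axis; the
  reported residual combines magnitude and phase residuals
  (`rms(res_mag² + res_phase²)`).
* Welford updates for all running statistics; SD is 0 (gate disabled)
  below two samples.
* The Kalman r is floored at 10⁻¹² to keep the gain defined before the
  input variance is observable.
* Ties in the length optimizer go to the shortest candidate; candidate
  grids are scanned in ascending order so the first maximum wins.
* Degenerate inputs raise typed errors (`ParameterError`,
  `DegenerateSignalError`, `MetricError`, `OptimizationError`) rather than
  returning silent NaNs, except where the contract specifies a flag (failed
  fit, infinite t).
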