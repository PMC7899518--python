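# Methods

This note documents the physical model behind the simulator, the
numerical choices, and the defaults — and what the synthetic experiments
do and do not demonstrate about real data.

## Scene model

The specimen is a set of fluorescent polymer beads (default 25 beads of
15.45 µm diameter, relative brightness uniform in [0.2, 1]) in a
300×300 µm² field of view, each bead a hard-edged disk of uniform
relative fluorescence yield.  Overlaps resolve to the per-point maximum
so the yield stays in [0, 1], which keeps the ADC headroom calibration
meaningful.  Optional Gaussian edge softening (`edge_sigma_um`) is off
by default so that ground-truth masks are exact.  Bead centers are drawn
uniformly from the region where the full disk fits inside the field of
view.  Excitation is treated as sampling the yield at the instantaneous
beam position — there is no point-spread-function or focal-volume model,
no fluorophore saturation, and no photobleaching.  Bead density and the
brightness distribution are not constrained by anything measurable here;
they were chosen once for visual similarity to a sparse bead slide.

## Scan geometry

The fast mirror follows a sine with period 2 ms (one line per half
period, so consecutive lines are scanned in opposite directions) and the
slow mirror steps one row per line:

    x_cmd(t) = (n_x − 1)/2 · (1 + sin(2πt/T + φ0)),   φ0 = −π/2.

Because the drive exceeds the mirror's faithful bandwidth, the actual
position carries an anharmonic correction

    x_act(t) = x_cmd(t) + A · sin²(2πt/T + φ0 − δ)

with amplitude A = 16 output pixels (on the 400-px grid; scaled with the
grid for reduced frames) and phase lag δ = π/30.  The correction is
non-negative, so the leftmost ~A pixel columns of the grid are never
visited; they are filled by interpolation and excluded through the
validity mask.  The same formula serves as forward map (simulation) and
inverse map (regridding), making the reconstruction exact by
construction; passing a different `ScanConfig` to the regridder exposes
the residual distortion of a miscalibrated correction.

Regridding uses bin-averaging with half-open pixel bins [k, k+1), which
conserves total signal and is linear; pixels with zero samples are
linearly interpolated and flagged (count 0).  One x pixel is
fov/n_x = 0.75 µm at defaults.

## Timing and signal chain

The seed oscillator (58.2 MHz) is both the fast-mode sample clock and,
divided by 14 through the pulse picker, the laser repetition rate
(4.157 MHz, 240.5 ns between pulses).  The per-pulse detector response
is the fluorescence decay (lifetime τ_f, default 1.3 ns) cascaded with
the transimpedance amplifier pole (τ_a = 1/2πB; B = 60 MHz → 2.65 ns in
the fast chain, 10 MHz → 15.9 ns plus a 0.5 MHz anti-alias pole →
318 ns in the conventional chain), normalized to unit area:

    h(t) = (e^{−t/τ_f} − e^{−t/τ_a}) / (τ_f − τ_a),  t ≥ 0.

The ADC is modelled as an integrate-over-one-sample-period sampler: the
digitizer's analog front end is bandwidth-matched to the sample rate, so
sample n reports the mean of the filtered signal over its own sample
period.  For the fluorescence this boxcar-sampled cascade response is
evaluated in closed form (the cumulative response of a cascade of
distinct poles is a sum of exponentials), so no fine-grained time grid
is needed; with the default clocks a pulse deposits 99.6 % of its energy
in its own window (the "captured fraction") and 0.36 % in the next.
The slowly varying background path uses the exact open fraction of the
chopper square wave per window, followed by the discrete single-pole
recursion y[n] = a·y[n−1] + (1−a)·x[n], a = e^{−Δt/τ} — identical to
convolution with the sampled exponential kernel, which the test suite
verifies to < 10⁻⁶.

Calibration follows the PMT-gain convention: the brightest fluorescence
(yield 1) maps to 30 % of full scale in the conventional chain and the
same physical gain converts to 20 % in the fast chain.  Background
amplitudes are detector-referred in conventional-chain full-scale units;
the fast chain sees amplitude × (0.20/0.30)/(14 × captured fraction)
≈ amplitude/20.9, the duty-cycle advantage of gating.

Noise is Gaussian with variance `shot_noise_scale × signal +
dark_noise_sigma²` per sample (a per-photon Poisson mode is available
for small-signal studies but bead signals are many-photon).  Defaults:
shot scale 10⁻⁴ (≈2 % relative noise at the fluorescence peak), dark
sigma 7×10⁻⁴ full scale in the fast chain and 5× that (3.5×10⁻³) in the
conventional chain.  The factor 5 between the chains is a simulator
input, not a result; the absolute level is set so that the conventional
mode's dark-pixel noise matches the corrected stripe-pixel noise of the
gated mode, the operating point of the hardware demonstration this
package models.  Each chain also has a small analog pedestal
(`input_offset`, 2 %/1 % of full scale) so dark samples are not
truncated at the converter's zero — the conventional mode's zero level
must then be estimated from the image, while the gated mode zeroes
itself through the subtraction.  ADC depths default to 12 bits
(conventional) and 14 bits (fast); both are configurable since neither
is pinned by the modelled hardware families.  Values at or above full
scale are clipped and flagged; quantization rounds to 2^bits − 1 levels.

The pulse clock sits at integer sample offset `pulse_phase` (default 0)
within the oscillator clock, with a sub-sample arrival delay
`pulse_delay_ns` (default 0.5 ns) after the window start.  Chopper edges
are instantaneous; the beam-crossing time of a real chopper is not
modelled beyond the amplifier smoothing.

## Gated processing

Demultiplexing reshapes the oversampled trace into rows of 14 samples
aligned to the pulse clock (trailing remainder dropped; the operation is
exactly invertible, which the tests assert).  The signal bin is
calibrated as the argmax of the column means after subtracting each
row's minimum — robust to any column-uniform background; calibration
refuses flat profiles and traces shorter than 100 pulses.  Background
offsets default to [−2, +5] bins: round(30 ns/17.18 ns) = 2 before and
round(80 ns/17.18 ns) = 5 after the pulse, the two bins a real ADC left
clean of ringing; the offsets are a configurable list and may wrap into
neighbouring pulse rows.  Clipped background samples are excluded
(using them would bias the subtraction low); pulses with no usable
background sample borrow the nearest valid estimate and are flagged.
The per-pulse estimate is the mean of the selected bins or,
alternatively, a cubic smoothing spline over pulse index (λ
configurable, default 1.0); mean is the default.  Corrected values are
not clamped at zero, preserving unbiased noise statistics around the
baseline.

## Metrics

All masks come from generator ground truth, never from image content.
The stripe mask marks lines fully inside a chopper-open interval
(edge-touching lines ±1 guard line excluded); the bead mask is
rasterized from the phantom, eroded by 1 px for fluorescence means
(avoiding edge mixing) and dilated by 2 px for background selections
(avoiding bead spill).

* **Stripe reduction factor** — mean background level over stripe
  non-bead pixels of the conventional image divided by the same for the
  gated signal-only image, each normalized by its bead-fluorescence
  level taken from background-free companion frames (this removes the
  gain ratio of the chains).  Analytically the factor is
  divider × captured fraction ≈ 13.95, the "up to 14" duty-cycle bound;
  when the conventional stripes clip, the measured value is a lower
  bound and flagged as such.
* **Suppression ratio** — applied background level (generator truth, in
  fast-chain signal-bin units) over |mean| of the corrected image on
  stripe non-bead pixels.  The |mean| (bias), not the std, is used
  because unbiasedness is the method's claim; the noise is reported
  separately.  Under white residual noise the ratio grows as √N with
  the pixel count and is a random variable: the acceptance experiment
  takes the minimum over three seeds.
* **Noise stats / cross-sections** — plain masked mean/std and vertical
  line profiles for the four-panel comparison.

## Problem sizes

The full default frame (400 lines, 1 ms each) is ~23 M oversampled
samples; the package's standard experiment scale is the reduced frame —
200 lines of 0.25 ms (14 550 samples, ~1039 pulses per line), which
keeps a four-frame comparison around a second while retaining ~10⁵
pulses in the stripe region, enough for the suppression ratio to
resolve levels of order 10⁴.  The stripe-reduction experiment uses a
noise-free 100×100 frame; the noise-ratio experiment uses 10⁵
synthetic pulses.  All experiment scales are recorded in the config
files their runs emit.

## What passing tests do and do not show

The simulator demonstrates the *mechanism*: that per-pulse gating and
subtraction removes modulated background exactly where a conventional
chain clips, with the predicted duty-cycle factor, noise propagation and
unbiasedness.  It does not model PMT dynode statistics, afterpulsing or
overload protection, optical spectra and filter transmission, ADC
ringing (the reason the hardware used only two background bins),
absolute power levels, or data-transfer constraints — so absolute
suppression figures hold only under the documented noise defaults, and
agreement with any particular instrument is not claimed.  The
conventional/gated dark-noise factor of 5 is an input.  Scenario-style
asynchronous stimulation pulses are available as a background waveform
(`pulsed_async`) but per-pixel artifact flagging for them is out of
scope.
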