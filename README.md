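# pulsegate

Pulse-synchronized, time-gated background subtraction for multiphoton
laser-scanning microscopy — implemented as a complete, testable software
pipeline: a signal-chain simulator for the two acquisition modes of a
two-photon microscope, and the gated per-pulse reconstruction that
removes uncorrelated background light which would otherwise clip the
conventional acquisition.

## The problem

Combining two-photon fluorescence imaging with optical stimulation
(visual stimuli, optogenetics) or simply working under ambient light
sends *uncorrelated* background light onto the detector.  In a
conventional acquisition — transimpedance amplifier, low-pass filter,
slow ADC — the photocurrent from several laser pulses is integrated into
every sample, so background and fluorescence are inseparable; strong
background saturates the ADC and the affected stripes of the image are
irrecoverable.

The gated scheme exploits two time scales: popular fluorescent reporters
decay within a few nanoseconds (Dragon Green beads ~1.3 ns, GCaMP
~2.8 ns), while a low-repetition-rate ultrafast laser (58.2 MHz seed
oscillator, pulse-picked by *N* = 14 to ~4.16 MHz) leaves 240 ns between
pulses.  Clocking the ADC with the seed oscillator puts exactly *N*
samples between consecutive pulses, each at a fixed delay from the
pulse.  Writing the demultiplexed samples of pulse *k* as
*s*<sub>*k*</sub>(0), …, *s*<sub>*k*</sub>(*N*−1) with the fluorescence in bin 0,
the corrected per-pulse value is

```
F_k = s_k(0) − B_k ,   B_k = mean{ s_k(−2), s_k(+5) }
```

where the background bins −2 and +5 (~34 ns before / ~86 ns after the
pulse) see only stray light.  Gating alone (no subtraction) already
reduces the background-to-signal ratio by the phase-bin duty cycle,
≈ *N* = 14; the subtraction removes the remainder to the noise floor,
and averaging two background samples instead of one lowers the
corrected noise by √(2σ²/1.5σ²) = √(4/3) ≈ 1.15.

The simulator covers the whole signal path: a fluorescent-bead phantom,
the sinusoidal galvo trajectory with its sin² inertia distortion,
single-pole amplifier responses, sample-period integration at the ADC,
shot + dark noise, quantization and clipping — plus the resampling of
the distorted raw lines onto an equidistant pixel grid and the metrics
comparing the two modes.

## Worked example

Run the reduced four-frame demonstration (200×200 px, 50 ms frame,
chopped background at 3× the conventional chain's full scale):

```
$ pulsegate -v demo --seed 1 --out demo_run
pulsegate: derived pulse_period_ns = 240.54982817869413
pulsegate: derived pulse_rate_mhz = 4.1571428571428575
pulsegate: derived bins_per_pulse = 14
pulsegate: derived pulses_per_slow_sample = 4
pulsegate: derived samples_per_line_mode2 = 14550
pulsegate: derived captured_fraction = 0.9963615693756416
stripe_reduction_factor = 4.58368
suppression_ratio = 23106.6
report -> demo_run/report.json
```

What the numbers mean: the background clips the conventional mode
(`clip_fraction["mode1"] = 0.5` — half the frame is saturated white
stripes), so the measured stripe-reduction factor 4.58 is only a lower
bound (flagged in the report); the corrected image has no clipping and
its residual background is 23 000× smaller than the applied level.  The
report also shows the corrected stripe-region noise (std ≈ 2.3×10⁻³
full-scale) matching the conventional mode's dark noise (≈ 3.3×10⁻³),
i.e. the subtraction adds no visible penalty.  `demo_run/` contains the
four images plus masks as TIFFs, cross-sections as CSV, and the exact
config (YAML) from which the run is bit-reproducible.

The same pipeline is scriptable:

```python
from pulsegate import ExperimentConfig, run_experiment
frames, report = run_experiment(ExperimentConfig.reduced(seed=1))
print(report["suppression_ratio"])      # 23106.6...
```

## Layout

| module | contents |
| --- | --- |
| `pulsegate.phantom` | bead phantom, ground-truth yield lookup |
| `pulsegate.scan` | galvo trajectory (commanded + inertia), line regridding |
| `pulsegate.chain` | timing, background model, amplifier/ADC simulation |
| `pulsegate.gating` | phase-bin demux, signal-bin calibration, subtraction |
| `pulsegate.metrics` | frame assembly, stripe/suppression/noise metrics |
| `pulsegate.experiment` | config, orchestration of the four-frame comparison |
| `pulsegate.cli` | `pulsegate simulate / process / metrics / demo` |

See `docs/methods.md` for the model, its assumptions, and all defaults.
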