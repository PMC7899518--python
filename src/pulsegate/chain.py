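"""Detector signal synthesis: fluorescence pulses, background, noise, ADC.

Physical model
--------------
Every laser pulse deposits a fluorescence energy proportional to the
phantom yield at the instantaneous beam position.  The photocurrent is
the pulse train convolved with the fluorophore decay (single
exponential, lifetime ~1.3 ns) and the transimpedance amplifier
response, modelled as single-pole low-pass filters at the stated 3 dB
bandwidths (10 MHz for the slow chain plus a 0.5 MHz anti-alias pole;
60 MHz for the fast chain).  The digitizer averages the analog signal
over one sample period before conversion ("detection bandwidth matches
the sampling rate"): sample n reports the mean of the signal over
[n, n+1) sample periods.  For the fluorescence path this boxcar-sampled
cascade response is evaluated in closed form (the cumulative response of
a cascade of distinct poles is a sum of exponentials); the slowly
varying background path uses the analytic open fraction of the chopper
square wave per window followed by the discrete single-pole recursion.

Two acquisition modes share the pulse timing:

* mode 1 ("conventional"): 10 MHz amplifier, 1 MS/s ADC.  Each sample
  physically integrates ~4 laser pulses; uncorrelated background cannot
  be measured separately.
* mode 2 (oversampled): 60 MHz amplifier, ADC clocked by the 58.2 MHz
  seed oscillator, i.e. exactly ``divider`` (14) samples between
  consecutive picked pulses, each at a fixed delay from the pulse.

Amplitudes are expressed in ADC full-scale units [0, 1].  The PMT gain
calibration is expressed through ``gain_target``: the peak fluorescence
(yield 1) maps to that fraction of full scale (0.30 in mode 1; the same
physical gain converts to ~0.20 in mode 2).  Background amplitudes are
detector-referred against the mode-1 chain (see BackgroundModel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .errors import ConfigError, ProcessingError
from .phantom import BeadPhantom
from .scan import ScanConfig, beam_position_arrays

__all__ = [
    "TimingConfig",
    "BackgroundModel",
    "DetectionChain",
    "RawTrace",
    "pulse_period",
    "per_pulse_signal_gain",
    "pulses_per_slow_sample",
    "background_level",
    "background_window_mean",
    "fluorescence_impulse",
    "single_pole_lowpass",
    "bandwidth_to_tau_ns",
    "cascade_cumulative",
    "bin_fractions",
    "captured_fraction",
    "mode2_background_gain",
    "synthesize_trace",
]


# --------------------------------------------------------------------------
# timing

@dataclass
class TimingConfig:
    """Oscillator / pulse-picker / ADC clock relationships.

    The seed oscillator at ``f_osc_mhz`` is both the mode-2 sample clock
    and, divided by ``divider`` through the pulse picker, the laser
    repetition rate (58.2 / 14 ~= 4.16 MHz).  ``pulse_phase`` is the
    integer offset of the pulse clock within the sample clock (cable
    delays); ``pulse_delay_ns`` is the sub-sample arrival time of the
    pulse after the start of its ADC window.
    """

    f_osc_mhz: float = 58.2
    divider: int = 14
    mode1_rate_msps: float = 1.0
    pulse_phase: int = 0
    pulse_delay_ns: float = 0.5

    def __post_init__(self) -> None:
        if self.f_osc_mhz <= 0 or self.mode1_rate_msps <= 0:
            raise ConfigError("clock rates must be > 0")
        if int(self.divider) != self.divider or self.divider < 1:
            raise ConfigError(f"divider must be an integer >= 1, got {self.divider}")
        self.divider = int(self.divider)
        if not 0 <= self.pulse_phase < self.divider:
            raise ConfigError("pulse_phase must be in [0, divider)")
        if not 0 <= self.pulse_delay_ns < 1000.0 / self.f_osc_mhz:
            raise ConfigError("pulse_delay_ns must be within one sample period")

    @property
    def sample_period_us(self) -> float:
        return 1.0 / self.f_osc_mhz

    @property
    def pulse_rate_mhz(self) -> float:
        return self.f_osc_mhz / self.divider

    @property
    def pulse_period_us(self) -> float:
        return self.divider / self.f_osc_mhz


def pulse_period(rep_rate_mhz: float) -> float:
    """Time between pulses in ns for a repetition rate in MHz (4 MHz -> 250 ns)."""
    if rep_rate_mhz <= 0:
        raise ConfigError(f"repetition rate must be > 0, got {rep_rate_mhz}")
    return 1000.0 / rep_rate_mhz


def per_pulse_signal_gain(rate_high_mhz: float, rate_low_mhz: float) -> float:
    """Two-photon per-pulse signal ratio when the repetition rate drops from
    ``rate_high`` to ``rate_low`` at constant average power, pulse duration
    and focusing.  Pulse energy scales as 1/rate and the two-photon signal
    as energy squared times rate, so the per-pulse gain is (high/low)^2
    (80 -> 4 MHz gives 400)."""
    if rate_high_mhz <= 0 or rate_low_mhz <= 0:
        raise ConfigError("repetition rates must be > 0")
    return (rate_high_mhz / rate_low_mhz) ** 2


def pulses_per_slow_sample(timing: TimingConfig) -> int:
    """Laser pulses physically integrated into one mode-1 ADC sample."""
    return int(math.floor(timing.pulse_rate_mhz / timing.mode1_rate_msps))


# --------------------------------------------------------------------------
# background light

@dataclass
class BackgroundModel:
    """Uncorrelated background light reaching the detector.

    ``amplitude`` is detector-referred in mode-1 ADC full-scale units
    (the conventional chain, whose fluorescence calibration is
    ``ref_gain_target`` of full scale); the level seen by the fast chain
    follows from the gain ratio of the two chains.  ``chopped`` is a
    square wave from a mechanical chopper (open at t=0 for phase 0);
    ``pulsed_async`` is a low-duty square wave at ``async_rate_hz``, not
    synchronized to the laser (optogenetic-stimulation scenario).
    """

    waveform: str = "chopped"  # off | chopped | constant | pulsed_async
    amplitude: float = 3.0
    chop_rate_hz: float = 20.0
    duty: float = 0.5
    phase_rad: float = 0.0
    async_rate_hz: float = 1000.0
    ref_gain_target: float = 0.30

    def __post_init__(self) -> None:
        if self.waveform not in ("off", "chopped", "constant", "pulsed_async"):
            raise ConfigError(f"unknown background waveform {self.waveform!r}")
        if self.amplitude < 0:
            raise ConfigError("background amplitude must be >= 0")
        if not 0.0 < self.duty < 1.0:
            raise ConfigError(f"duty must be in (0, 1), got {self.duty}")
        if self.chop_rate_hz <= 0 or self.async_rate_hz <= 0:
            raise ConfigError("modulation rates must be > 0")

    def _rate_hz(self) -> float:
        return self.async_rate_hz if self.waveform == "pulsed_async" else self.chop_rate_hz


def background_level(t_us, model: BackgroundModel):
    """Instantaneous background level (mode-1 referred units, edges sharp)."""
    t = np.asarray(t_us, dtype=float)
    if model.waveform == "off":
        out = np.zeros_like(t)
    elif model.waveform == "constant":
        out = np.full_like(t, model.amplitude)
    else:
        period_us = 1e6 / model._rate_hz()
        u = t / period_us + model.phase_rad / (2.0 * math.pi)
        out = np.where(u - np.floor(u) < model.duty, model.amplitude, 0.0)
    return out if out.ndim else float(out)


def _open_time(t_us, model: BackgroundModel):
    """Total chopper-open time in [0, t) for the square-wave models."""
    period_us = 1e6 / model._rate_hz()
    u = np.asarray(t_us, dtype=float) / period_us + model.phase_rad / (2.0 * math.pi)
    fl = np.floor(u)
    return period_us * (model.duty * fl + np.minimum(u - fl, model.duty))


def background_window_mean(window_starts_us, dt_us: float, model: BackgroundModel):
    """Background averaged over ADC windows [t, t+dt) (exact for square waves)."""
    t0 = np.asarray(window_starts_us, dtype=float)
    if model.waveform == "off":
        return np.zeros_like(t0)
    if model.waveform == "constant":
        return np.full_like(t0, model.amplitude)
    frac = (_open_time(t0 + dt_us, model) - _open_time(t0, model)) / dt_us
    return model.amplitude * frac


# --------------------------------------------------------------------------
# impulse responses and filters

def bandwidth_to_tau_ns(bw_mhz: float) -> float:
    """Single-pole time constant for a 3 dB bandwidth (tau = 1/(2 pi f))."""
    if bw_mhz <= 0:
        raise ConfigError("bandwidth must be > 0")
    return 1000.0 / (2.0 * math.pi * bw_mhz)


def fluorescence_impulse(t_rel_ns, lifetime_ns: float, tia_tau_ns: float):
    """Normalized (unit-area) detector response to one laser pulse, in 1/ns.

    Cascade of the fluorescence decay and the amplifier pole:
    (exp(-t/tau_f) - exp(-t/tau_a)) / (tau_f - tau_a) for t >= 0, with
    the t * exp(-t/tau) / tau^2 limit when the constants coincide.
    """
    if lifetime_ns <= 0 or tia_tau_ns <= 0:
        raise ConfigError("time constants must be > 0")
    t = np.asarray(t_rel_ns, dtype=float)
    tf, ta = lifetime_ns, tia_tau_ns
    if math.isclose(tf, ta, rel_tol=1e-9):
        h = t * np.exp(-np.clip(t, 0, None) / tf) / tf**2
    else:
        tc = np.clip(t, 0, None)
        h = (np.exp(-tc / tf) - np.exp(-tc / ta)) / (tf - ta)
    out = np.where(t < 0, 0.0, h)
    return out if out.ndim else float(out)


def _cascade_weights(taus):
    taus = [float(t) for t in taus]
    if len(set(taus)) != len(taus):
        # nudge exact duplicates: the partial-fraction form needs distinct poles
        taus = [t * (1 + 1e-9 * i) for i, t in enumerate(taus)]
    n = len(taus)
    w = []
    for i, ti in enumerate(taus):
        denom = 1.0
        for j, tj in enumerate(taus):
            if j != i:
                denom *= ti - tj
        w.append(ti ** (n - 2) / denom)
    return np.array(taus), np.array(w)


def cascade_cumulative(t, taus):
    """Integral from 0 to t of the unit-area impulse response of a cascade
    of distinct single poles (time constants ``taus``); saturates at 1."""
    tv, w = _cascade_weights(taus)
    tc = np.clip(np.asarray(t, dtype=float), 0.0, None)
    out = np.sum(w * tv * (1.0 - np.exp(-tc[..., None] / tv)), axis=-1)
    return out if np.ndim(out) else float(out)


def captured_fraction(timing: TimingConfig, lifetime_ns: float, tia_tau_ns: float) -> float:
    """Fraction of one pulse's energy landing in its own ADC window (mode 2)."""
    dt_ns = 1000.0 * timing.sample_period_us
    return float(cascade_cumulative(dt_ns - timing.pulse_delay_ns,
                                    (lifetime_ns, tia_tau_ns)))


def bin_fractions(timing: TimingConfig, lifetime_ns: float, tia_tau_ns: float,
                  n_bins: int = 4):
    """Energy fractions of one pulse falling in ADC windows 0..n_bins-1
    after the pulse (window 0 contains the pulse itself)."""
    dt_ns = 1000.0 * timing.sample_period_us
    edges = np.arange(n_bins + 1) * dt_ns - timing.pulse_delay_ns
    H = cascade_cumulative(edges, (lifetime_ns, tia_tau_ns))
    return np.diff(H)


def single_pole_lowpass(x, dt, tau, y0=None):
    """Discrete single-pole low-pass (unit DC gain): y[n] = a y[n-1] + (1-a) x[n]
    with a = exp(-dt/tau).  Identical to convolution with the sampled
    exponential kernel (1-a) a^k.  ``y0`` seeds the initial state (defaults
    to x[0], i.e. no startup transient for signals already settled)."""
    if tau <= 0 or dt <= 0:
        raise ConfigError("dt and tau must be > 0")
    x = np.asarray(x, dtype=float)
    a = math.exp(-dt / tau)
    if y0 is None:
        y0 = x[0] if x.size else 0.0
    y, _ = scipy.signal.lfilter([1.0 - a], [1.0, -a], x, zi=[a * y0])
    return y


# --------------------------------------------------------------------------
# detection chains and digitization

@dataclass
class DetectionChain:
    """Amplifier + noise + ADC parameters for one acquisition mode."""

    tia_bandwidth_mhz: float
    anti_alias_mhz: float | None
    shot_noise_scale: float
    dark_noise_sigma: float
    adc_bits: int
    gain_target: float
    input_offset: float = 0.0
    noise_model: str = "gaussian"  # gaussian | poisson

    def __post_init__(self) -> None:
        if self.tia_bandwidth_mhz <= 0:
            raise ConfigError("tia_bandwidth_mhz must be > 0")
        if self.anti_alias_mhz is not None and self.anti_alias_mhz <= 0:
            raise ConfigError("anti_alias_mhz must be > 0 or None")
        if self.shot_noise_scale < 0 or self.dark_noise_sigma < 0:
            raise ConfigError("noise parameters must be >= 0")
        if not 0 < self.gain_target < 1:
            raise ConfigError("gain_target must be in (0, 1)")
        if self.adc_bits < 1:
            raise ConfigError("adc_bits must be >= 1")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")

    @property
    def tia_tau_ns(self) -> float:
        return bandwidth_to_tau_ns(self.tia_bandwidth_mhz)

    @classmethod
    def mode1(cls, **kw) -> "DetectionChain":
        """Conventional chain: 10 MHz amplifier, 0.5 MHz anti-alias, 12-bit ADC."""
        defaults = dict(tia_bandwidth_mhz=10.0, anti_alias_mhz=0.5,
                        shot_noise_scale=1e-4, dark_noise_sigma=3.5e-3,
                        adc_bits=12, gain_target=0.30, input_offset=0.02)
        defaults.update(kw)
        return cls(**defaults)

    @classmethod
    def mode2(cls, **kw) -> "DetectionChain":
        """Fast chain: 60 MHz amplifier, oscillator-clocked 14-bit ADC."""
        defaults = dict(tia_bandwidth_mhz=60.0, anti_alias_mhz=None,
                        shot_noise_scale=1e-4, dark_noise_sigma=7e-4,
                        adc_bits=14, gain_target=0.20, input_offset=0.01)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class RawTrace:
    """Digitized detector samples for one frame, with clock-phase metadata."""

    mode: int
    samples: np.ndarray          # in [0, 1] full-scale units
    sample_rate_msps: float
    pulse_phase: int | None
    line_triggers: np.ndarray    # sample indices of line starts
    clip_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lt = np.asarray(self.line_triggers)
        if lt.size > 1 and not np.all(np.diff(lt) > 0):
            raise ConfigError("line_triggers must be strictly increasing")


def mode2_background_gain(timing: TimingConfig, chain2: DetectionChain,
                          lifetime_ns: float, ref_gain_target: float = 0.30) -> float:
    """Mode-2 full-scale units per mode-1 full-scale unit of background.

    Both chains see the same physical light; their gains are pinned by
    the fluorescence calibration (peak fluorescence -> gain_target).  A
    slow background passes each chain with unit DC gain, so its mode-2
    level is amplitude * (g2/g1) with
    g2/g1 = (gt2/gt1) * (sample period * pulse rate) / captured_fraction,
    i.e. roughly gt2/gt1 / 14: the gated sample integrates the background
    for only one of the ``divider`` windows per pulse.
    """
    f0 = captured_fraction(timing, lifetime_ns, chain2.tia_tau_ns)
    return (chain2.gain_target / ref_gain_target) / (timing.divider * f0)


def _digitize(clean_signal, chain: DetectionChain, rng):
    """Noise + offset + clipping + quantization.  ``clean_signal`` excludes
    the electronic pedestal (shot noise acts on light only)."""
    total = clean_signal + chain.input_offset
    if chain.noise_model == "poisson" and chain.shot_noise_scale > 0:
        k = 1.0 / chain.shot_noise_scale
        total = rng.poisson(np.clip(clean_signal, 0, None) * k) / k + chain.input_offset
        if chain.dark_noise_sigma > 0:
            total = total + rng.normal(0.0, chain.dark_noise_sigma, total.shape)
    elif chain.shot_noise_scale > 0 or chain.dark_noise_sigma > 0:
        var = (chain.shot_noise_scale * np.clip(clean_signal, 0, None)
               + chain.dark_noise_sigma ** 2)
        total = total + rng.standard_normal(total.shape) * np.sqrt(var)
    clip_mask = total >= 1.0
    levels = 2 ** chain.adc_bits - 1
    quant = np.round(np.clip(total, 0.0, 1.0) * levels) / levels
    return quant, clip_mask


def _pulse_schedule(phantom: BeadPhantom, scan: ScanConfig, timing: TimingConfig):
    """Pulse times (us from frame start) and per-pulse phantom yields."""
    dt = timing.sample_period_us
    n_osc = int(round(timing.f_osc_mhz * scan.line_time_us)) * scan.n_lines
    n_pulses = (n_osc - timing.pulse_phase) // timing.divider
    pulse_sample = timing.pulse_phase + timing.divider * np.arange(n_pulses)
    t_pulse = pulse_sample * dt + 1e-3 * timing.pulse_delay_ns
    x_px, line = beam_position_arrays(t_pulse, scan, actual=True)
    x_um = x_px * scan.px_um
    y_um = (line + 0.5) * scan.fov_um / scan.n_lines
    yld = np.asarray(phantom.yield_at(x_um, y_um), dtype=float)
    return pulse_sample, t_pulse, yld


def _synthesize_mode2(phantom, scan, timing, background, chain):
    dt = timing.sample_period_us
    spl = int(round(timing.f_osc_mhz * scan.line_time_us))
    n = spl * scan.n_lines
    pulse_sample, _t_pulse, yld = _pulse_schedule(phantom, scan, timing)

    # background: window average of the square wave, then the amplifier pole
    amp2 = mode2_background_gain(timing, chain, phantom.lifetime_ns,
                                 background.ref_gain_target)
    bg = background_window_mean(np.arange(n) * dt, dt, background) * amp2
    if background.waveform != "off":
        bg = single_pole_lowpass(bg, dt, 1e-3 * chain.tia_tau_ns)

    # fluorescence: closed-form boxcar-sampled cascade response per pulse
    fr = bin_fractions(timing, phantom.lifetime_ns, chain.tia_tau_ns, n_bins=4)
    amp = chain.gain_target * yld / fr[0]
    clean = bg
    for lag, f in enumerate(fr):
        idx = pulse_sample + lag
        ok = idx < n
        clean[idx[ok]] += amp[ok] * f
    return clean, spl, n


def _synthesize_mode1(phantom, scan, timing, background, chain):
    dt1 = 1.0 / timing.mode1_rate_msps
    spl1 = int(round(timing.mode1_rate_msps * scan.line_time_us))
    n1 = spl1 * scan.n_lines
    _ps, t_pulse, yld = _pulse_schedule(phantom, scan, timing)

    t0 = np.arange(n1) * dt1
    amp1 = chain.gain_target / background.ref_gain_target  # usually 1
    bg = background_window_mean(t0, dt1, background) * amp1
    taus_us = [1e-3 * phantom.lifetime_ns, 1e-3 * chain.tia_tau_ns]
    if chain.anti_alias_mhz is not None:
        taus_us.append(1e-3 * bandwidth_to_tau_ns(chain.anti_alias_mhz))
    if background.waveform != "off":
        for tau in taus_us[1:]:
            bg = single_pole_lowpass(bg, dt1, tau)

    # per-pulse energy so that the steady-state plateau at yield 1 is gain_target
    energy = chain.gain_target * yld / timing.pulse_rate_mhz  # full-scale * us
    t1 = t0 + dt1
    last = np.searchsorted(t_pulse, t1, side="right") - 1
    n_lags = int(math.ceil((8.0 * max(taus_us) + dt1) / timing.pulse_period_us)) + 1
    clean = bg
    for lag in range(n_lags):
        k = last - lag
        ok = k >= 0
        if not np.any(ok):
            break
        ki = k[ok]
        a = np.clip(t0[ok] - t_pulse[ki], 0.0, None)
        b = np.clip(t1[ok] - t_pulse[ki], 0.0, None)
        clean[ok] += energy[ki] * (cascade_cumulative(b, taus_us)
                                   - cascade_cumulative(a, taus_us)) / dt1
    return clean, spl1, n1


def synthesize_trace(phantom: BeadPhantom, scan: ScanConfig, timing: TimingConfig,
                     background: BackgroundModel, chain: DetectionChain,
                     mode: int, seed: int) -> RawTrace:
    """Simulate one full frame of digitized detector samples.

    Deterministic for a fixed seed.  Mode 2 requires the sample clock to
    be the oscillator (it is, by construction of TimingConfig); mode 1
    samples at ``mode1_rate_msps``.
    """
    if mode not in (1, 2):
        raise ConfigError(f"mode must be 1 or 2, got {mode}")
    rng = np.random.default_rng(seed)
    if mode == 2:
        clean, spl, _n = _synthesize_mode2(phantom, scan, timing, background, chain)
        rate = timing.f_osc_mhz
        phase = timing.pulse_phase
    else:
        clean, spl, _n = _synthesize_mode1(phantom, scan, timing, background, chain)
        rate = timing.mode1_rate_msps
        phase = None
    samples, clip_mask = _digitize(clean, chain, rng)
    bg_amp_mode = (background.amplitude if background.waveform != "off" else 0.0)
    if mode == 2:
        bg_amp_mode *= mode2_background_gain(timing, chain, phantom.lifetime_ns,
                                             background.ref_gain_target)
    else:
        bg_amp_mode *= chain.gain_target / background.ref_gain_target
    return RawTrace(
        mode=mode,
        samples=samples,
        sample_rate_msps=rate,
        pulse_phase=phase,
        line_triggers=np.arange(scan.n_lines) * spl,
        clip_mask=clip_mask,
        meta={
            "seed": int(seed),
            "line_time_us": scan.line_time_us,
            "pulse_delay_ns": timing.pulse_delay_ns,
            "divider": timing.divider,
            "background_amplitude_mode_units": float(bg_amp_mode),
            "lifetime_ns": phantom.lifetime_ns,
            "gain_target": chain.gain_target,
            "input_offset": chain.input_offset,
        },
    )
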