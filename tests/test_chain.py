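import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pulsegate.chain import (BackgroundModel, DetectionChain, TimingConfig,
                             background_level, background_window_mean,
                             bandwidth_to_tau_ns, bin_fractions,
                             captured_fraction, cascade_cumulative,
                             fluorescence_impulse, mode2_background_gain,
                             per_pulse_signal_gain, pulse_period,
                             pulses_per_slow_sample, single_pole_lowpass,
                             synthesize_trace)
from pulsegate.errors import ConfigError
from pulsegate.phantom import Bead, BeadPhantom
from pulsegate.scan import ScanConfig


class TestTimingArithmetic:
    @pytest.mark.parametrize("rate,period", [(4.0, 250.0), (58.2, 1000 / 58.2),
                                             (1000.0, 1.0)])
    def test_pulse_period(self, rate, period):
        assert pulse_period(rate) == pytest.approx(period)

    def test_pulse_period_rejects_nonpositive_rate(self):
        with pytest.raises(ConfigError):
            pulse_period(0.0)

    @pytest.mark.parametrize("hi,lo,gain", [
        (80.0, 4.0, 400.0), (7.3, 7.3, 1.0), (58.2, 58.2 / 14, 196.0)])
    def test_per_pulse_signal_gain(self, hi, lo, gain):
        assert per_pulse_signal_gain(hi, lo) == pytest.approx(gain)

    @pytest.mark.parametrize("kw,expect", [
        (dict(), 4),                                   # 58.2/14 MHz vs 1 MS/s
        (dict(f_osc_mhz=14.0, divider=14), 1),         # pulse rate == ADC rate
        (dict(f_osc_mhz=80.0, divider=1), 80),
    ])
    def test_pulses_per_slow_sample(self, kw, expect):
        assert pulses_per_slow_sample(TimingConfig(**kw)) == expect

    def test_default_pulse_rate_near_4mhz(self):
        t = TimingConfig()
        assert t.pulse_rate_mhz == pytest.approx(58.2 / 14)
        assert pulse_period(t.pulse_rate_mhz) == pytest.approx(240.55, abs=0.01)

    @pytest.mark.parametrize("bad", [
        dict(f_osc_mhz=0), dict(divider=0), dict(divider=2.5),
        dict(pulse_phase=14), dict(pulse_delay_ns=100.0)])
    def test_invalid_timing_rejected(self, bad):
        with pytest.raises(ConfigError):
            TimingConfig(**bad)


class TestBackgroundModel:
    def test_off_is_zero_for_all_t(self):
        m = BackgroundModel(waveform="off")
        assert np.all(background_level(np.linspace(0, 1e6, 100), m) == 0.0)

    def test_chopper_open_at_frame_start(self):
        m = BackgroundModel(waveform="chopped", amplitude=1.5, duty=0.5,
                            phase_rad=0.0)
        assert background_level(0.0, m) == 1.5

    def test_open_fraction_matches_duty_over_one_period(self):
        m = BackgroundModel(waveform="chopped", amplitude=1.0, duty=0.3,
                            chop_rate_hz=20.0)
        t = np.arange(0, 50_000.0, 1.0)  # one 50 ms period, 1 us samples
        frac = (background_level(t, m) > 0).mean()
        assert frac == pytest.approx(0.3, abs=1.0 / t.size * 2)

    @given(st.floats(0, 1e5), st.floats(10.0, 2000.0),
           st.floats(0.1, 0.9), st.floats(0, 2 * math.pi))
    def test_window_mean_matches_dense_numeric_average(self, t0, dt, duty, phase):
        m = BackgroundModel(waveform="chopped", amplitude=2.0, duty=duty,
                            chop_rate_hz=180.0, phase_rad=phase)
        analytic = background_window_mean(np.array([t0]), dt, m)[0]
        tt = t0 + (np.arange(20000) + 0.5) * dt / 20000
        numeric = background_level(tt, m).mean()
        assert analytic == pytest.approx(numeric, abs=2e-3)

    def test_pulsed_async_is_a_low_duty_square_wave(self):
        m = BackgroundModel(waveform="pulsed_async", amplitude=1.0,
                            async_rate_hz=1000.0, duty=0.1)
        t = np.arange(0, 10_000.0, 1.0)  # 10 periods at 1 us resolution
        lvl = background_level(t, m)
        assert (lvl > 0).mean() == pytest.approx(0.1, abs=0.01)
        # on for the first 100 us of each 1 ms period
        assert lvl[50] == 1.0 and lvl[500] == 0.0

    def test_invalid_waveform_and_duty_rejected(self):
        with pytest.raises(ConfigError):
            BackgroundModel(waveform="sine")
        with pytest.raises(ConfigError):
            BackgroundModel(duty=1.0)


class TestImpulseResponse:
    def test_causality(self):
        assert fluorescence_impulse(-0.1, 1.3, 2.653) == 0.0

    def test_unit_area(self):
        t = np.linspace(0, 200, 400_001)
        area = np.trapezoid(fluorescence_impulse(t, 1.3, 2.653), t)
        assert area == pytest.approx(1.0, rel=1e-6)

    def test_peak_time_closed_form(self):
        tf, ta = 1.3, 2.653
        t_peak = math.log(tf / ta) * tf * ta / (tf - ta)
        assert t_peak == pytest.approx(1.818, abs=0.002)
        t = np.linspace(0, 20, 200_001)
        h = fluorescence_impulse(t, tf, ta)
        assert t[np.argmax(h)] == pytest.approx(t_peak, abs=1e-3)

    def test_equal_time_constants_limit_form(self):
        t = np.linspace(0, 100, 200_001)
        h = fluorescence_impulse(t, 2.0, 2.0)
        assert np.trapezoid(h, t) == pytest.approx(1.0, rel=1e-5)
        assert t[np.argmax(h)] == pytest.approx(2.0, abs=1e-3)  # peak at tau

    def test_cumulative_matches_numeric_integral(self):
        taus = (1.3, 2.653)
        t = np.linspace(0, 40, 40_001)
        h = fluorescence_impulse(t, *taus)
        numeric = np.concatenate([[0.0], np.cumsum((h[1:] + h[:-1]) / 2) * np.diff(t)])
        assert np.allclose(cascade_cumulative(t, taus), numeric, atol=1e-5)

    def test_bandwidth_to_tau(self):
        assert bandwidth_to_tau_ns(60.0) == pytest.approx(2.653, abs=1e-3)
        assert bandwidth_to_tau_ns(10.0) == pytest.approx(15.92, abs=0.01)


class TestSinglePoleFilter:
    def test_matches_brute_force_convolution(self):
        """The IIR implementation equals convolution with the sampled
        exponential kernel to < 1e-6 relative error."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=10_000)
        dt, tau = 1.0, 7.3
        a = math.exp(-dt / tau)
        kernel = (1 - a) * a ** np.arange(x.size)
        brute = np.convolve(x, kernel)[: x.size]
        y = single_pole_lowpass(x, dt, tau, y0=0.0)
        err = np.linalg.norm(y - brute) / np.linalg.norm(brute)
        assert err < 1e-6

    def test_dc_gain_is_unity(self):
        y = single_pole_lowpass(np.full(100, 4.2), dt=1.0, tau=3.0)
        assert np.allclose(y, 4.2)


def _one_bead_phantom():
    return BeadPhantom(fov_um=300.0, beads=[Bead(150.0, 150.0, 60.0, 1.0)])


@pytest.fixture(scope="module")
def small_scan():
    return ScanConfig.reduced(n_lines=20, n_pixels_x=80, line_period_ms=0.2)


class TestSynthesizeTrace:
    def test_dark_silent_chain_gives_all_zero(self, small_scan):
        ph = BeadPhantom(fov_um=300.0, beads=[])
        chain = DetectionChain.mode2(shot_noise_scale=0.0, dark_noise_sigma=0.0,
                                     input_offset=0.0)
        tr = synthesize_trace(ph, small_scan, TimingConfig(),
                              BackgroundModel(waveform="off"), chain, mode=2, seed=0)
        assert np.all(tr.samples == 0.0)
        assert not tr.clip_mask.any()

    def test_mode2_peak_hits_gain_target(self, small_scan, noisefree_chains):
        _, c2 = noisefree_chains
        tr = synthesize_trace(_one_bead_phantom(), small_scan, TimingConfig(),
                              BackgroundModel(waveform="off"), c2, mode=2, seed=0)
        peak = tr.samples.max() - c2.input_offset
        assert peak == pytest.approx(c2.gain_target, rel=0.01)

    def test_mode1_plateau_hits_gain_target(self, small_scan, noisefree_chains):
        c1, _ = noisefree_chains
        tr = synthesize_trace(_one_bead_phantom(), small_scan, TimingConfig(),
                              BackgroundModel(waveform="off"), c1, mode=1, seed=0)
        # plateau: samples well above 90% of max are on the bead
        plateau = tr.samples[tr.samples > 0.9 * tr.samples.max()]
        assert plateau.mean() - c1.input_offset == pytest.approx(
            c1.gain_target, rel=0.05)

    def test_overdriven_background_clips_mode1_during_open_chopper(
            self, small_scan, noisefree_chains):
        c1, _ = noisefree_chains
        bg = BackgroundModel(waveform="chopped", amplitude=2.0, chop_rate_hz=500.0)
        tr = synthesize_trace(BeadPhantom(fov_um=300.0), small_scan,
                              TimingConfig(), bg, c1, mode=1, seed=0)
        t_us = (np.arange(tr.samples.size) + 0.5) / tr.sample_rate_msps
        open_now = background_level(t_us, bg) > 0
        # interior of open windows is clipped; closed windows never are
        assert tr.clip_mask[open_now].mean() > 0.9
        assert np.all(tr.samples[tr.clip_mask] == 1.0)
        closed_interior = ~open_now & ~np.roll(open_now, 1) & ~np.roll(open_now, -2)
        assert not tr.clip_mask[closed_interior].any()

    def test_mode2_periodic_over_constant_region(self, small_scan, noisefree_chains):
        _, c2 = noisefree_chains
        ph = BeadPhantom(fov_um=300.0, beads=[Bead(150.0, 150.0, 1e4, 1.0)])
        bg = BackgroundModel(waveform="constant", amplitude=0.5)
        tr = synthesize_trace(ph, small_scan, TimingConfig(), bg, c2, mode=2, seed=0)
        s = tr.samples[1000:3000]
        assert np.array_equal(s, tr.samples[1000 + 14:3000 + 14])

    def test_quantization_and_range(self, small_scan):
        c2 = DetectionChain.mode2()
        tr = synthesize_trace(_one_bead_phantom(), small_scan, TimingConfig(),
                              BackgroundModel(waveform="constant", amplitude=1.0),
                              c2, mode=2, seed=3)
        levels = 2 ** c2.adc_bits - 1
        assert np.all((tr.samples >= 0) & (tr.samples <= 1))
        assert np.allclose(np.round(tr.samples * levels), tr.samples * levels,
                           atol=1e-9)

    def test_seed_determinism_and_variation(self, small_scan):
        args = (_one_bead_phantom(), small_scan, TimingConfig(),
                BackgroundModel(waveform="chopped", amplitude=0.5,
                                chop_rate_hz=500.0), DetectionChain.mode2())
        a = synthesize_trace(*args, mode=2, seed=42)
        b = synthesize_trace(*args, mode=2, seed=42)
        c = synthesize_trace(*args, mode=2, seed=43)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_energy_conservation_between_modes(self, small_scan, noisefree_chains,
                                               flat_phantom):
        """Total fluorescence energy per frame agrees between the chains
        after removing the calibration gain ratio (linear filters conserve
        the pulse area)."""
        c1, c2 = noisefree_chains
        t = TimingConfig()
        bg = BackgroundModel(waveform="off")
        tr1 = synthesize_trace(flat_phantom, small_scan, t, bg, c1, mode=1, seed=0)
        tr2 = synthesize_trace(flat_phantom, small_scan, t, bg, c2, mode=2, seed=0)
        tot1 = (tr1.samples - c1.input_offset).sum() / tr1.sample_rate_msps
        tot2 = (tr2.samples - c2.input_offset).sum() / tr2.sample_rate_msps
        f0 = captured_fraction(t, flat_phantom.lifetime_ns, c2.tia_tau_ns)
        expected_ratio = (c1.gain_target / t.pulse_rate_mhz) / \
            (c2.gain_target / (f0 * t.f_osc_mhz))
        assert tot1 / tot2 == pytest.approx(expected_ratio, rel=0.02)

    def test_mode_validation(self, small_scan):
        with pytest.raises(ConfigError):
            synthesize_trace(_one_bead_phantom(), small_scan, TimingConfig(),
                             BackgroundModel(), DetectionChain.mode2(),
                             mode=3, seed=0)


class TestBinFractions:
    def test_fractions_sum_to_unity(self):
        fr = bin_fractions(TimingConfig(), 1.3, bandwidth_to_tau_ns(60.0), n_bins=6)
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)
        assert fr[0] > 0.99  # nearly all energy in the pulse's own window

    def test_background_gain_reflects_duty_cycle(self):
        t = TimingConfig()
        c2 = DetectionChain.mode2()
        g = mode2_background_gain(t, c2, 1.3)
        # ~ (0.2/0.3)/14: the gated bin sees background for 1 of 14 windows
        assert g == pytest.approx((0.2 / 0.3) / 14, rel=0.02)
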