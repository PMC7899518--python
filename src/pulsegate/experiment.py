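"""Experiment orchestration: the four-frame comparison on synthetic data.

``run_experiment`` simulates both acquisition modes with and without
background light on the same phantom, runs the gated processing, builds
the images and computes all metrics.  A run is reproducible bit-exactly
from config + seed: the single seed is expanded into per-frame child
seeds through ``numpy.random.SeedSequence.spawn`` in a fixed order
(phantom, mode-1 background frame, mode-1 reference, mode-2 background
frame, mode-2 reference).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import io as pio
from .chain import (BackgroundModel, DetectionChain, RawTrace, TimingConfig,
                    captured_fraction, mode2_background_gain, pulse_period,
                    pulses_per_slow_sample, synthesize_trace)
from .errors import ConfigError
from .gating import (DEFAULT_OFFSETS, calibrate_signal_bin, demux,
                     estimate_background, mode1_series, signal_only_series,
                     subtract)
from .metrics import (FrameImage, FrameSet, build_frame, cross_section,
                      noise_stats, rasterize_bead_mask,
                      stripe_mask_from_timing, stripe_reduction_factor,
                      suppression_ratio)
from .phantom import BeadPhantom, generate_bead_field
from .scan import ScanConfig

__all__ = [
    "PhantomConfig",
    "ExperimentConfig",
    "child_seeds",
    "process_mode1_trace",
    "process_mode2_trace",
    "run_experiment",
]

log = logging.getLogger("pulsegate")


@dataclass
class PhantomConfig:
    n_beads: int = 25
    diameter_um: float = 15.45
    brightness_min: float = 0.2
    brightness_max: float = 1.0
    lifetime_ns: float = 1.3
    edge_sigma_um: float = 0.0


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one four-frame comparison."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    scan: ScanConfig = field(default_factory=ScanConfig)
    timing: TimingConfig = field(default_factory=TimingConfig)
    background: BackgroundModel = field(default_factory=BackgroundModel)
    chain_mode1: DetectionChain = field(default_factory=DetectionChain.mode1)
    chain_mode2: DetectionChain = field(default_factory=DetectionChain.mode2)
    background_offsets: tuple = DEFAULT_OFFSETS
    background_method: str = "mean"
    seed: int = 0

    @classmethod
    def reduced(cls, n_lines: int = 200, n_pixels_x: int = 200,
                line_period_ms: float = 0.5, seed: int = 0, **kw) -> "ExperimentConfig":
        """Reduced-frame configuration for fast runs (the full default frame
        is ~23 M oversampled samples)."""
        return cls(scan=ScanConfig.reduced(n_lines=n_lines, n_pixels_x=n_pixels_x,
                                           line_period_ms=line_period_ms),
                   seed=seed, **kw)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_offsets"] = list(self.background_offsets)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        sections = {
            "phantom": PhantomConfig, "scan": ScanConfig, "timing": TimingConfig,
            "background": BackgroundModel, "chain_mode1": DetectionChain,
            "chain_mode2": DetectionChain,
        }
        kw = {}
        for key, val in d.items():
            if key in sections:
                try:
                    kw[key] = sections[key](**val)
                except (TypeError, ConfigError) as exc:
                    raise ConfigError(f"{key}: {exc}") from exc
            elif key == "background_offsets":
                kw[key] = tuple(int(o) for o in val)
            elif key in ("background_method", "seed"):
                kw[key] = val
            else:
                raise ConfigError(f"unknown config field {key!r}")
        return cls(**kw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def child_seeds(seed: int, n: int = 5) -> list[int]:
    """Deterministic per-frame seeds derived from the run seed."""
    return [int(s.generate_state(1)[0] % 2**31)
            for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# trace -> image pipelines

def process_mode1_trace(trace: RawTrace, scan: ScanConfig) -> FrameImage:
    """Conventional pathway: per-sample series regridded (sample time is the
    center of its integration window)."""
    values, clip = mode1_series(trace)
    dt = 1.0 / trace.sample_rate_msps
    times = (np.arange(values.size) + 0.5) * dt
    return build_frame(values, times, scan, clip=clip)


def process_mode2_trace(trace: RawTrace, timing: TimingConfig, scan: ScanConfig,
                        offsets=DEFAULT_OFFSETS, method: str = "mean"):
    """Gated pathway: demux, calibrate, estimate, subtract, regrid.

    Returns (corrected FrameImage, signal-only FrameImage, PhaseBins,
    CorrectedSeries).
    """
    bins = demux(trace, timing)
    calibrate_signal_bin(bins)
    est = estimate_background(bins, offsets=offsets, method=method)
    corr = subtract(bins, est)
    sig_only, sig_clip = signal_only_series(bins)
    t = bins.pulse_times_us
    img_corr = build_frame(corr.corrected, t, scan, clip=corr.clipped)
    img_sig = build_frame(sig_only, t, scan, clip=sig_clip)
    return img_corr, img_sig, bins, corr


# --------------------------------------------------------------------------
# the four-frame experiment

def _derived_timing(cfg: ExperimentConfig, phantom: BeadPhantom) -> dict:
    t, s, c2 = cfg.timing, cfg.scan, cfg.chain_mode2
    return {
        "pulse_period_ns": pulse_period(t.pulse_rate_mhz),
        "pulse_rate_mhz": t.pulse_rate_mhz,
        "bins_per_pulse": t.divider,
        "pulses_per_slow_sample": pulses_per_slow_sample(t),
        "samples_per_line_mode1": int(round(t.mode1_rate_msps * s.line_time_us)),
        "samples_per_line_mode2": int(round(t.f_osc_mhz * s.line_time_us)),
        "pulses_per_line": t.f_osc_mhz * s.line_time_us / t.divider,
        "frame_time_ms": s.frame_time_us / 1000.0,
        "captured_fraction": captured_fraction(t, phantom.lifetime_ns, c2.tia_tau_ns),
        "background_gain_mode2": mode2_background_gain(
            t, c2, phantom.lifetime_ns, cfg.background.ref_gain_target),
    }


def run_experiment(cfg: ExperimentConfig, outdir=None):
    """Simulate, process and measure the four-frame comparison.

    Returns (FrameSet, report dict); when ``outdir`` is given, also
    writes the images (TIFF), masks, cross-sections (CSV), the config
    (YAML) and the metrics report (JSON + flat text).
    """
    seeds = child_seeds(cfg.seed)
    phantom = generate_bead_field(
        cfg.phantom.n_beads, fov_um=cfg.scan.fov_um,
        diameter_um=cfg.phantom.diameter_um,
        brightness_range=(cfg.phantom.brightness_min, cfg.phantom.brightness_max),
        seed=seeds[0], lifetime_ns=cfg.phantom.lifetime_ns,
        edge_sigma_um=cfg.phantom.edge_sigma_um,
    )
    bg_off = replace(cfg.background, waveform="off")
    timing = cfg.timing
    info = _derived_timing(cfg, phantom)
    for k, v in info.items():
        log.info("derived %s = %s", k, v)

    tr_m1 = synthesize_trace(phantom, cfg.scan, timing, cfg.background,
                             cfg.chain_mode1, mode=1, seed=seeds[1])
    tr_m1_ref = synthesize_trace(phantom, cfg.scan, timing, bg_off,
                                 cfg.chain_mode1, mode=1, seed=seeds[2])
    tr_m2 = synthesize_trace(phantom, cfg.scan, timing, cfg.background,
                             cfg.chain_mode2, mode=2, seed=seeds[3])
    tr_m2_ref = synthesize_trace(phantom, cfg.scan, timing, bg_off,
                                 cfg.chain_mode2, mode=2, seed=seeds[4])

    img_m1 = process_mode1_trace(tr_m1, cfg.scan)
    img_m1_ref = process_mode1_trace(tr_m1_ref, cfg.scan)
    img_c, img_s, _, _ = process_mode2_trace(
        tr_m2, timing, cfg.scan, cfg.background_offsets, cfg.background_method)
    img_c_ref, img_s_ref, _, _ = process_mode2_trace(
        tr_m2_ref, timing, cfg.scan, cfg.background_offsets, cfg.background_method)

    bead_mask = rasterize_bead_mask(phantom, cfg.scan)
    stripe = stripe_mask_from_timing(cfg.background, cfg.scan)
    amp_m2 = tr_m2.meta["background_amplitude_mode_units"]
    truth = np.where(stripe, amp_m2, 0.0)

    fs = FrameSet(
        mode1=img_m1, mode2_signal_only=img_s, mode2_corrected=img_c,
        mode1_ref=img_m1_ref, mode2_signal_only_ref=img_s_ref,
        mode2_corrected_ref=img_c_ref,
        truth_background=truth, stripe_mask=stripe, bead_mask=bead_mask,
        meta={"config_hash": cfg.config_hash(), "seed": cfg.seed,
              "phantom": phantom},
    )

    report = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
              "derived_timing": info, "clip_fraction": fs.clip_fraction}
    if cfg.background.waveform != "off" and cfg.background.amplitude > 0:
        factor, lower = stripe_reduction_factor(fs)
        ratio, n_pix = suppression_ratio(fs)
        report["stripe_reduction_factor"] = factor
        report["stripe_reduction_is_lower_bound"] = lower
        report["suppression_ratio"] = ratio
        report["suppression_ratio_pixels"] = n_pix
        report["background_amplitude_mode2_units"] = amp_m2

    from scipy import ndimage  # local: only needed for the guard masks
    guard = ndimage.binary_dilation(bead_mask, iterations=2)
    valid = fs.valid_mask
    dark_sel = ~guard & valid
    report["noise"] = {
        "mode1_dark": noise_stats(img_m1_ref, dark_sel),
        "mode2_corrected_dark": noise_stats(img_c_ref, dark_sel),
    }
    if stripe.any():
        sel = stripe & dark_sel
        if sel.any():
            report["noise"]["mode2_corrected_stripe"] = noise_stats(img_c, sel)

    if phantom.beads:
        bright = max(phantom.beads, key=lambda b: b.brightness)
        col = int(np.clip(round(bright.x_um / cfg.scan.px_um), 0,
                          cfg.scan.n_pixels_x - 1))
        report["cross_section_column"] = col

    if outdir is not None:
        _write_outputs(outdir, cfg, fs, report)
    return fs, report


def _write_outputs(outdir, cfg: ExperimentConfig, fs: FrameSet, report: dict) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    desc = json.dumps({"config_hash": cfg.config_hash(), "seed": cfg.seed})
    images = {
        "mode1.tif": fs.mode1, "mode1_ref.tif": fs.mode1_ref,
        "mode2_signal_only.tif": fs.mode2_signal_only,
        "mode2_signal_only_ref.tif": fs.mode2_signal_only_ref,
        "mode2_corrected.tif": fs.mode2_corrected,
        "mode2_corrected_ref.tif": fs.mode2_corrected_ref,
    }
    for name, img in images.items():
        pio.save_image(img.data, out / name, description=desc)
    pio.save_mask(fs.stripe_mask, out / "stripe_mask.tif")
    pio.save_mask(fs.bead_mask, out / "bead_mask.tif")
    pio.save_mask(fs.valid_mask, out / "valid_mask.tif")
    pio.save_image(fs.truth_background, out / "truth_background.tif", description=desc)
    fs.meta["phantom"].to_table(out / "phantom.txt")
    cfg.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    lines = []
    if "cross_section_column" in report:
        col = report["cross_section_column"]
        profiles = np.column_stack([
            cross_section(fs.mode1_ref, col), cross_section(fs.mode2_signal_only_ref, col),
            cross_section(fs.mode1, col), cross_section(fs.mode2_corrected, col),
            cross_section(fs.truth_background, col),
        ])
        np.savetxt(out / "cross_section.csv", profiles, delimiter=",",
                   header="mode1_ref,mode2_ref,mode1_bg,mode2_corrected,truth_background")
    def flat(d, prefix=""):
        for k, v in d.items():
            if isinstance(v, dict):
                flat(v, f"{prefix}{k}.")
            else:
                lines.append(f"{prefix}{k} = {v}")
    flat(report)
    (out / "report.txt").write_text("\n".join(lines) + "\n")
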