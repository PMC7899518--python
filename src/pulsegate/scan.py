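"""Galvo scan geometry: trajectory model and raw-line regridding.

The fast (x) mirror is driven sinusoidally (one image line per half
period, so consecutive lines are scanned in opposite directions) while
the slow (y) mirror steps one output row per line.  Because the drive
frequency exceeds what the mirror follows faithfully, the actual beam
position carries an anharmonic correction: an additive sin^2 term with
the drive's angular frequency, a phase lag, and an amplitude expressed
in output pixels.  The same trajectory formula is used to synthesize raw
data (forward map) and to resample it onto the equidistant pixel grid
(inverse map), so the reconstruction is exact by construction; passing a
different ``ScanConfig`` to :func:`regrid` than was used for simulation
exposes the residual distortion of a miscalibrated correction.

All times are micro-seconds from the frame start.  Pixel x coordinates
are continuous with pixel k owning the half-open bin [k, k+1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, ProcessingError

__all__ = [
    "ScanConfig",
    "BeamSample",
    "commanded_position",
    "actual_position",
    "beam_position_arrays",
    "regrid",
]

PHI0 = -0.5 * math.pi  # line starts at the sine minimum (left edge)


@dataclass
class ScanConfig:
    """Commanded and actual galvo trajectory parameters.

    line_period_ms is the full sine period of the x mirror; a single
    image line takes half of it.  ``inertia_amplitude_px`` is quoted in
    output pixels and therefore should be scaled together with
    ``n_pixels_x`` (16 px on the default 400-px grid = 12 um of beam
    displacement).
    """

    line_period_ms: float = 2.0
    n_lines: int = 400
    n_pixels_x: int = 400
    fov_um: float = 300.0
    inertia_amplitude_px: float = 16.0
    inertia_phase_lag_rad: float = math.pi / 30.0

    def __post_init__(self) -> None:
        if self.line_period_ms <= 0:
            raise ConfigError(f"line_period_ms must be > 0, got {self.line_period_ms}")
        if self.n_lines < 1:
            raise ConfigError(f"n_lines must be >= 1, got {self.n_lines}")
        if self.n_pixels_x < 2:
            raise ConfigError(f"n_pixels_x must be >= 2, got {self.n_pixels_x}")
        if self.fov_um <= 0:
            raise ConfigError("fov_um must be > 0")
        if self.inertia_amplitude_px < 0:
            raise ConfigError("inertia_amplitude_px must be >= 0")

    @property
    def line_time_us(self) -> float:
        """One image line = half the sine period."""
        return 500.0 * self.line_period_ms

    @property
    def frame_time_us(self) -> float:
        return self.line_time_us * self.n_lines

    @property
    def px_um(self) -> float:
        """Pixel size along x (and y with square defaults)."""
        return self.fov_um / self.n_pixels_x

    @classmethod
    def reduced(cls, n_lines: int = 200, n_pixels_x: int = 200,
                line_period_ms: float = 0.5, **kw) -> "ScanConfig":
        """Smaller/faster frame with the inertia amplitude scaled to the grid."""
        kw.setdefault("inertia_amplitude_px", 16.0 * n_pixels_x / 400.0)
        return cls(line_period_ms=line_period_ms, n_lines=n_lines,
                   n_pixels_x=n_pixels_x, **kw)


@dataclass(frozen=True)
class BeamSample:
    """Beam position at one instant, in output-pixel units."""

    t_us: float
    x_px: float
    y_px: float
    line_index: int


def _phase(t_us, cfg: ScanConfig):
    period_us = 1000.0 * cfg.line_period_ms
    return 2.0 * math.pi * t_us / period_us + PHI0


def beam_position_arrays(t_us, cfg: ScanConfig, actual: bool = True):
    """Vectorised trajectory: (x_px, line_index) for times in [0, frame).

    Raises ProcessingError for any time outside the frame (a line/frame
    trigger misalignment in a real acquisition).
    """
    t = np.asarray(t_us, dtype=float)
    if np.any(t < 0) or np.any(t >= cfg.frame_time_us):
        raise ProcessingError(
            "sample time outside the frame duration (trigger misalignment): "
            f"frame is [0, {cfg.frame_time_us}) us"
        )
    theta = _phase(t, cfg)
    x = 0.5 * (cfg.n_pixels_x - 1) * (1.0 + np.sin(theta))
    if actual and cfg.inertia_amplitude_px:
        x = x + cfg.inertia_amplitude_px * np.sin(theta - cfg.inertia_phase_lag_rad) ** 2
    line = np.floor(t / cfg.line_time_us).astype(int)
    return x, line


def commanded_position(t_us: float, cfg: ScanConfig) -> BeamSample:
    """Set position of the beam following the programmed sine drive."""
    x, line = beam_position_arrays(float(t_us), cfg, actual=False)
    return BeamSample(float(t_us), float(x), float(line), int(line))


def actual_position(t_us: float, cfg: ScanConfig) -> BeamSample:
    """Commanded position plus the sin^2 mirror-inertia correction."""
    x, line = beam_position_arrays(float(t_us), cfg, actual=True)
    return BeamSample(float(t_us), float(x), float(line), int(line))


def regrid(values, times_us, cfg: ScanConfig, actual: bool = True):
    """Resample one raw line onto the equidistant x pixel grid.

    Each raw value is assigned to the pixel bin [k, k+1) containing its
    (actual) beam x position and bins are averaged, which conserves total
    signal; samples falling outside the grid (inertia overscan) are
    dropped.  Pixels that received no sample are filled by linear
    interpolation from their neighbours and reported with count 0 so the
    caller can mask them.

    Returns
    -------
    (pixel_values, counts): float and int arrays of length n_pixels_x.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(times_us, dtype=float)
    if v.shape != t.shape or v.ndim != 1 or v.size == 0:
        raise ProcessingError("values and times must be equal-length 1-D, non-empty")
    x, line = beam_position_arrays(t, cfg, actual=actual)
    if line.min() != line.max():
        raise ProcessingError("regrid expects samples from a single line")
    bins = np.floor(x).astype(int)
    ok = (bins >= 0) & (bins < cfg.n_pixels_x)
    if not np.any(ok):
        raise ProcessingError("all samples fall outside the pixel grid")
    counts = np.bincount(bins[ok], minlength=cfg.n_pixels_x)
    acc = np.bincount(bins[ok], weights=v[ok], minlength=cfg.n_pixels_x)
    out = np.full(cfg.n_pixels_x, np.nan)
    covered = counts > 0
    out[covered] = acc[covered] / counts[covered]
    if not covered.all():
        idx = np.arange(cfg.n_pixels_x)
        out[~covered] = np.interp(idx[~covered], idx[covered], out[covered])
    return out, counts
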