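"""Synthetic fluorescent-bead sample.

The simulated specimen is a monolayer of fluorescent polymer beads
(nominal diameter 15.45 um) in a square field of view, each bead an
opaque disk of uniform relative fluorescence yield.  The phantom is the
simulator's ground truth: every laser pulse samples ``yield_at`` at the
instantaneous beam position, so exact bead geometry is what makes the
downstream image metrics testable.

Coordinates are continuous micrometres with the origin at the lower-left
corner of the field of view; x is the fast (sinusoidally scanned) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .errors import ConfigError

__all__ = ["Bead", "BeadPhantom", "generate_bead_field"]


@dataclass(frozen=True)
class Bead:
    x_um: float
    y_um: float
    diameter_um: float
    brightness: float

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ConfigError(f"bead diameter must be > 0, got {self.diameter_um}")
        if not 0.0 <= self.brightness <= 1.0:
            raise ConfigError(f"bead brightness must be in [0, 1], got {self.brightness}")


@dataclass
class BeadPhantom:
    """Ground-truth fluorescence yield map of the sample plane.

    Parameters
    ----------
    fov_um:
        Physical extent of the (square) field of view in micrometres.
    beads:
        Bead list; disks may overlap, yield is the per-point maximum.
    lifetime_ns:
        Excited-state lifetime of the fluorophore (Dragon Green ~1.3 ns;
        GCaMP ~2.8 ns).  Used by the signal chain, carried here because
        it is a property of the specimen.
    edge_sigma_um:
        Optional Gaussian softening of the disk edge; 0 keeps hard edges
        (the default, so ground truth stays exact).
    """

    fov_um: float = 300.0
    beads: list[Bead] = field(default_factory=list)
    lifetime_ns: float = 1.3
    edge_sigma_um: float = 0.0

    def __post_init__(self) -> None:
        if self.fov_um <= 0:
            raise ConfigError(f"fov_um must be > 0, got {self.fov_um}")
        if self.lifetime_ns <= 0:
            raise ConfigError(f"lifetime_ns must be > 0, got {self.lifetime_ns}")
        if self.edge_sigma_um < 0:
            raise ConfigError("edge_sigma_um must be >= 0")
        for b in self.beads:
            if not (0.0 <= b.x_um <= self.fov_um and 0.0 <= b.y_um <= self.fov_um):
                raise ConfigError(
                    f"bead center ({b.x_um}, {b.y_um}) outside field of view"
                )

    # -- ground-truth lookup ------------------------------------------------

    def yield_at(self, x_um, y_um):
        """Relative fluorescence yield in [0, 1] at (x, y).

        Vectorised over array inputs.  Out-of-FOV queries are allowed and
        return 0 (there are no beads there).  Points exactly on a disk
        boundary count as inside (closed disk); overlapping beads resolve
        to the maximum brightness, keeping the yield bounded by 1.
        """
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape, dtype=float)
        for b in self.beads:
            r = 0.5 * b.diameter_um
            d = np.hypot(x - b.x_um, y - b.y_um)
            if self.edge_sigma_um > 0:
                w = np.where(
                    d <= r,
                    b.brightness,
                    b.brightness * np.exp(-0.5 * ((d - r) / self.edge_sigma_um) ** 2),
                )
            else:
                w = np.where(d <= r, b.brightness, 0.0)
            np.maximum(out, w, out=out)
        if out.ndim == 0:
            return float(out)
        return out

    # -- serialization ------------------------------------------------------

    def to_table(self, path) -> None:
        """Write one bead per row: x_um, y_um, diameter_um, brightness."""
        rows = np.array(
            [[b.x_um, b.y_um, b.diameter_um, b.brightness] for b in self.beads],
            dtype=float,
        ).reshape(-1, 4)
        header = (
            f"fov_um={self.fov_um} lifetime_ns={self.lifetime_ns} "
            f"edge_sigma_um={self.edge_sigma_um}\n"
            "x_um y_um diameter_um brightness"
        )
        np.savetxt(path, rows, header=header)

    @classmethod
    def from_table(cls, path) -> "BeadPhantom":
        with open(path) as fh:
            first = fh.readline()
        meta = dict(
            kv.split("=") for kv in first.lstrip("# ").split() if "=" in kv
        )
        rows = np.loadtxt(path, ndmin=2)
        beads = [Bead(*row) for row in rows] if rows.size else []
        return cls(
            fov_um=float(meta.get("fov_um", 300.0)),
            beads=beads,
            lifetime_ns=float(meta.get("lifetime_ns", 1.3)),
            edge_sigma_um=float(meta.get("edge_sigma_um", 0.0)),
        )

    def render(self, n_pixels: int = 400):
        """Rasterize the yield map on an n x n grid (pixel centers)."""
        scale = self.fov_um / n_pixels
        c = (np.arange(n_pixels) + 0.5) * scale
        xx, yy = np.meshgrid(c, c)
        return self.yield_at(xx, yy)

    def to_tiff(self, path, n_pixels: int = 400) -> None:
        tifffile.imwrite(path, self.render(n_pixels).astype(np.float32))


def generate_bead_field(
    n_beads: int,
    fov_um: float = 300.0,
    diameter_um: float = 15.45,
    brightness_range: tuple[float, float] = (0.2, 1.0),
    seed: int = 0,
    lifetime_ns: float = 1.3,
    edge_sigma_um: float = 0.0,
) -> BeadPhantom:
    """Place ``n_beads`` uniformly at random in the field of view.

    Centers are drawn uniformly from [r, fov - r] on each axis so every
    disk lies fully inside the field of view; brightnesses are uniform in
    ``brightness_range``.  Reproducible for a fixed seed (bit-identical
    bead lists).  Beads may overlap.
    """
    if n_beads < 0:
        raise ConfigError(f"n_beads must be >= 0, got {n_beads}")
    if fov_um <= 0 or diameter_um <= 0:
        raise ConfigError("fov_um and diameter_um must be > 0")
    lo, hi = brightness_range
    if not (0.0 <= lo <= hi <= 1.0):
        raise ConfigError(f"brightness_range must satisfy 0 <= lo <= hi <= 1, got {brightness_range}")
    r = 0.5 * diameter_um
    if 2 * r > fov_um:
        raise ConfigError("bead diameter exceeds the field of view")
    rng = np.random.default_rng(seed)
    beads = []
    for _ in range(int(n_beads)):
        x, y = rng.uniform(r, fov_um - r, size=2)
        b = rng.uniform(lo, hi)
        beads.append(Bead(float(x), float(y), float(diameter_um), float(b)))
    return BeadPhantom(
        fov_um=fov_um, beads=beads, lifetime_ns=lifetime_ns, edge_sigma_um=edge_sigma_um
    )
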