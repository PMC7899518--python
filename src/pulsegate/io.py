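"""Persistence for traces, images and reports.

Traces go into an .npz container (columnar sample data) whose header is
a plain-text JSON string stored alongside the arrays, so a trace file is
self-describing; small traces can also be exported to CSV for
inspection.  Images are written as 32-bit float single-channel TIFFs
with boolean masks as 8-bit companions.
"""

from __future__ import annotations

import json

import numpy as np
import tifffile

from .chain import RawTrace
from .errors import ProcessingError

__all__ = ["save_trace", "load_trace", "trace_to_csv", "save_image", "save_mask"]

_FORMAT = "pulsegate-trace-1"


def save_trace(trace: RawTrace, path) -> None:
    header = {
        "format": _FORMAT,
        "mode": trace.mode,
        "sample_rate_msps": trace.sample_rate_msps,
        "pulse_phase": trace.pulse_phase,
        "meta": trace.meta,
    }
    np.savez(
        path,
        header=np.frombuffer(json.dumps(header, sort_keys=True).encode(), dtype=np.uint8),
        samples=trace.samples,
        clip_mask=trace.clip_mask,
        line_triggers=np.asarray(trace.line_triggers, dtype=np.int64),
    )


def load_trace(path) -> RawTrace:
    with np.load(path) as z:
        try:
            header = json.loads(bytes(z["header"].tobytes()).decode())
        except Exception as exc:  # noqa: BLE001
            raise ProcessingError(f"not a pulsegate trace file: {path}") from exc
        if header.get("format") != _FORMAT:
            raise ProcessingError(f"unknown trace format in {path}")
        return RawTrace(
            mode=int(header["mode"]),
            samples=z["samples"],
            sample_rate_msps=float(header["sample_rate_msps"]),
            pulse_phase=(None if header["pulse_phase"] is None
                         else int(header["pulse_phase"])),
            line_triggers=z["line_triggers"],
            clip_mask=z["clip_mask"],
            meta=header.get("meta", {}),
        )


def trace_to_csv(trace: RawTrace, path, max_samples: int = 1_000_000) -> None:
    if trace.samples.size > max_samples:
        raise ProcessingError(
            f"trace has {trace.samples.size} samples; CSV export is for small traces"
        )
    dt = 1.0 / trace.sample_rate_msps
    t = np.arange(trace.samples.size) * dt
    np.savetxt(
        path,
        np.column_stack([t, trace.samples, trace.clip_mask.astype(int)]),
        header="t_us sample clipped",
        fmt=("%.6f", "%.8f", "%d"),
    )


def save_image(data, path, description: str | None = None) -> None:
    tifffile.imwrite(path, np.asarray(data, dtype=np.float32),
                     description=description)


def save_mask(mask, path) -> None:
    tifffile.imwrite(path, (np.asarray(mask) != 0).astype(np.uint8))
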