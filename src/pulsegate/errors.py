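"""Exception types shared across the package."""


class PulsegateError(Exception):
    """Base class for all pulsegate errors."""


class ConfigError(PulsegateError, ValueError):
    """A configuration value violates its constraints."""


class ProcessingError(PulsegateError, RuntimeError):
    """A processing step received data it cannot handle (mode mismatch,
    missing metadata, empty input, trigger misalignment ...)."""


class CalibrationError(ProcessingError):
    """Timing/signal-bin calibration is impossible on the given data."""
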