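"""Exception hierarchy for the lvpress pipeline."""


class LvpressError(Exception):
    """Base class for all lvpress errors."""


class ConfigError(LvpressError):
    """Invalid configuration value or combination."""


class InvalidGeometryError(LvpressError):
    """Pressure ordering required by the relaxation geometry is violated."""


class InfeasibleBeatError(LvpressError):
    """The requested beat morphology does not fit in the RR interval."""


class ParseError(LvpressError):
    """A waveform or table file could not be parsed.

    Carries the 1-based line number when the offending line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CalibrationError(LvpressError):
    """Calibration record is insufficient or degenerate."""


class AlignmentError(LvpressError):
    """Two series that must share a time base do not align."""


class EmptySignalError(LvpressError):
    """Operation requires non-gap samples but none are available."""


class InvalidBeatError(LvpressError):
    """A beat annotation does not support the requested computation."""
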