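"""Exception hierarchy.

Fatal configuration/input problems raise; per-triple analysis problems are
collected as skips with reasons (see :mod:`ionflux.drift`), never raised.
"""


class IonFluxError(Exception):
    """Base class for all package errors."""


class UnknownSpeciesError(IonFluxError):
    """Requested ion or buffer is not in the shipped tables."""


class BufferValidityError(IonFluxError):
    """Polyprotic buffer used at a pH too far from its tabulated pK."""


class ConfigError(IonFluxError):
    """Inconsistent or incomplete analysis/acquisition configuration."""


class ParseError(IonFluxError):
    """Malformed recording or table file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SegmentationError(IonFluxError):
    """Position channel cannot be split into two-level loops."""


class ScenarioError(IonFluxError):
    """Physically impossible simulation scenario (e.g. concentration <= 0)."""


class CalibrationError(IonFluxError):
    """Degenerate electrode calibration table."""


class EstimateError(IonFluxError):
    """A voltage/dV estimate cannot be formed from the available samples."""
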