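"""Exception hierarchy for microdma.

All package-specific errors derive from :class:`MicroDmaError` so callers can
catch everything from this package with a single except clause.
"""


class MicroDmaError(Exception):
    """Base class for all microdma errors."""


class ParameterError(MicroDmaError, ValueError):
    """A configuration or model parameter is invalid."""


class TimeDomainUnsupportedError(MicroDmaError):
    """The model has no exact finite-state time-domain update (springpot)."""


class LinearityError(MicroDmaError):
    """Oscillation amplitude exceeds the configured linearity bound."""


class PhaseRangeError(MicroDmaError):
    """Measured phase lag is outside [0, pi/2) for a passive sample."""


class ReadoutQualityError(MicroDmaError):
    """Interferometric signal too poor to demodulate reliably."""


class NoContactError(MicroDmaError):
    """No persistent load-threshold crossing found in the approach."""


class ProbeRejectionError(MicroDmaError):
    """Glass calibration deviates too far from ideal; probe must be replaced."""


class ProtocolFaultError(MicroDmaError):
    """The protocol cannot be executed (e.g. load setpoint unreachable)."""


class SimulationFaultError(MicroDmaError):
    """The simulated instrument entered a non-physical state."""


class InsufficientDataError(MicroDmaError):
    """A segment is too short for the requested analysis."""


class FormatError(MicroDmaError):
    """A recording or table file violates the expected dialect."""


class IncompatibleGridsError(MicroDmaError):
    """Sweep results on different frequency grids cannot be aggregated."""
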