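"""Exception hierarchy for the canalbedo toolkit.

Every stage raises a specific subclass of :class:`CanalbedoError` so that
pipeline drivers can attribute failures to a stage and exit cleanly.
"""


class CanalbedoError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CanalbedoError):
    """A file does not conform to the documented text dialect."""


class GridMismatch(FormatError):
    """A spectrum's wavelength set differs from the session grid."""


class ConfigError(CanalbedoError):
    """Invalid or inconsistent configuration (e.g. overlapping windows)."""


class PanelCoverageError(CanalbedoError):
    """No white-reference panel capture close enough in time."""


class ReflectanceQCError(CanalbedoError):
    """Too many invalid bands in a reflectance spectrum."""


class EmptySpectrumError(CanalbedoError):
    """No retained bands left to average."""


class NoDataInWindow(CanalbedoError):
    """A time window contains no kept observations."""


class DegenerateRegression(CanalbedoError):
    """Regression input has zero variance or too few points."""


class InsufficientPairs(DegenerateRegression):
    """Fewer than the minimum number of matched pairs."""


class InsufficientDesign(CanalbedoError):
    """Trial design too small for the requested fit."""


class ConvergenceError(CanalbedoError):
    """Iterative REML failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace if trace is not None else []


class NoOverlapError(CanalbedoError):
    """Two logger series share no time-matched records."""


class ScalingError(CanalbedoError):
    """Requested scaling is undefined (e.g. sd-scaling a constant column)."""
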