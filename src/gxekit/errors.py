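"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`GxeError` so that callers (and the
CLI) can distinguish bad configuration from degenerate data.
"""


class GxeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GxeError):
    """Invalid or inconsistent configuration (bad dimensions, missing paths)."""


class InsufficientDataError(GxeError):
    """Not enough observations to compute the requested quantity."""


class DegenerateDesignError(GxeError):
    """Design has no usable variation (constant regressor, all years equal)."""


class DegenerateTableError(GxeError):
    """Contingency table with a zero margin."""


class UndefinedORError(GxeError):
    """2x2 odds ratio undefined (zero cell) and continuity correction is off."""


class AlignmentError(GxeError):
    """Participant or variant sets do not line up between inputs."""


class RankDeficiencyError(GxeError):
    """Model matrix is not full rank (collinear terms)."""


class ConvergenceError(GxeError):
    """Iterative fit failed to converge (e.g. perfect separation)."""


class DegenerateTestError(GxeError):
    """Test statistic undefined (zero variance term)."""


class DegenerateCategorizationError(GxeError):
    """Too few distinct values to form quartile categories."""
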