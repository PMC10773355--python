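"""Exception hierarchy shared across the package."""


class DvaCeaError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DvaCeaError):
    """A parameter set or configuration violates a model invariant.

    The message names the offending field(s).
    """


class MissingParameterError(ValidationError):
    """A required named parameter is absent from the configuration."""


class InfeasibleMomentsError(DvaCeaError):
    """Moment matching asked for a variance a Beta cannot support."""


class InvalidRowError(DvaCeaError):
    """A transition row is not a probability vector."""


class InfeasibleRowError(DvaCeaError):
    """A row's stated exits leave no probability mass for staying put."""


class DegenerateRowError(DvaCeaError):
    """All of a row's surviving mass is on the absorbing death state."""


class CalibrationInfeasibleError(DvaCeaError):
    """No free-parameter value in [0, 1] can reach the calibration target."""
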