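"""Exception and warning hierarchy for the phenodist pipeline."""


class PhenodistError(Exception):
    """Base class for all phenodist errors."""


class InvalidArgumentError(PhenodistError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(PhenodistError, ValueError):
    """A configuration value or key is invalid."""


class DataError(PhenodistError, ValueError):
    """Input data violate a record-level invariant (NaN, n_birds = 0, ...)."""


class SchemaError(PhenodistError, KeyError):
    """A required column, layer or field is missing or mismatched."""


class EmptyDatasetError(PhenodistError, ValueError):
    """An operation that needs at least one row received none."""


class EmptyResultError(PhenodistError, ValueError):
    """Every candidate cell/row was masked or filtered away."""


class DegenerateBasisError(PhenodistError, ValueError):
    """A covariate is constant; no spline basis can be built for it."""


class CalibrationError(PhenodistError, ValueError):
    """The requested effective degrees of freedom are unreachable."""


class RankDeficiencyWarning(UserWarning):
    """The household design matrix is rank deficient; a minimum-norm solution is used."""


class DroppedVariableWarning(UserWarning):
    """A constant covariate was dropped from the base-learner set."""


class EmptySummaryWarning(UserWarning):
    """No region passed the sample-size gate; the summary is empty."""


class TieWarning(UserWarning):
    """An argmax/argmin tie was broken by the documented deterministic rule."""
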