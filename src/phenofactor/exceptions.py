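"""Exception hierarchy for phenofactor.

All errors raised by the package derive from :class:`PhenofactorError`
so callers can catch the package's failures with a single except clause.
"""


class PhenofactorError(Exception):
    """Base class for all phenofactor errors."""


class InvalidParameterError(PhenofactorError, ValueError):
    """A scalar argument is outside its legal range (e.g. MAF not in (0, 0.5])."""


class InvalidSpecError(PhenofactorError, ValueError):
    """A population or model specification is internally inconsistent."""


class DataError(PhenofactorError, ValueError):
    """Observed data violate a declared contract (e.g. category out of range)."""


class DegeneratePredictorError(PhenofactorError, ValueError):
    """A predictor is constant after filtering and cannot enter a regression."""


class EstimationError(PhenofactorError, RuntimeError):
    """An iterative estimator failed to converge."""


class IdentificationError(PhenofactorError, ValueError):
    """A model has negative degrees of freedom (more parameters than moments)."""


class ConfigError(PhenofactorError, ValueError):
    """A run configuration file is malformed or contains unknown keys."""
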