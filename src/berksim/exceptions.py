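"""Exception hierarchy.

Configuration / domain errors are ValueErrors so they behave naturally in
scripting contexts; analysis-stage failures are RuntimeErrors.
"""


class BerksimError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BerksimError, ValueError):
    """Invalid configuration object or generator settings."""


class SpecificationError(ConfigurationError):
    """An error specification is internally inconsistent (e.g. s-ratio out of bounds)."""


class DomainError(BerksimError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateSeriesError(DomainError):
    """A series has zero variance (or is otherwise degenerate) where variation is required."""


class AlignmentError(BerksimError, ValueError):
    """Dated inputs do not share the required date index."""


class AnalysisError(BerksimError, RuntimeError):
    """An analysis stage cannot produce a result from the data it was given."""


class FitError(AnalysisError):
    """A model fit failed to converge or could not be computed."""


class IllPosedFitError(FitError):
    """The fit is unidentifiable from the given design (e.g. all pairs at one distance)."""


class IdentifiabilityError(FitError):
    """The regression design matrix is rank deficient."""
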