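"""Exception hierarchy.

Every failure mode raised by the package derives from :class:`RatphenoError`
so callers can catch the whole family.  Subclasses map one-to-one onto the
distinct error contracts of the analysis stages.
"""


class RatphenoError(Exception):
    """Base class for all package errors."""


class SchemaError(RatphenoError):
    """A table is missing a mandatory column or has a malformed header."""


class ValidationError(RatphenoError):
    """A row violates a field invariant (e.g. non-positive tibia length)."""


class FormatError(RatphenoError):
    """A trace file is empty, non-numeric or non-uniformly sampled."""


class ConfigurationError(RatphenoError):
    """A pipeline/analysis configuration is inconsistent or incomplete."""


class GenerationError(RatphenoError):
    """A synthesis recipe would produce degenerate or invalid data."""


class InsufficientDataError(RatphenoError):
    """Too few records to fit or validate a model."""


class DegenerateFitError(RatphenoError):
    """Regression is undefined (zero-variance regressor or ~zero slope)."""


class DomainError(RatphenoError):
    """An input is outside the mathematical domain of a formula."""


class InsufficientCyclesError(RatphenoError):
    """Too few cardiac cycles detected/usable for averaged-beat analysis."""


class LandmarkFailureError(RatphenoError):
    """An averaged beat has no analyzable landmark (e.g. no T deflection)."""


class TraceShapeError(RatphenoError):
    """A trial series has the wrong length or a non-monotone axis."""


class DegenerateInputError(RatphenoError):
    """An input is formally valid but carries no information (all zero...)."""


class NoBreathError(RatphenoError):
    """A flow trace contains no complete inspiration phase."""


class GateError(RatphenoError):
    """The normality gate is undefined (constant group)."""
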