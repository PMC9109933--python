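"""Exception hierarchy for mrorient.

All exceptions derive from :class:`MROrientError`, so callers can catch the
package's failures with a single except clause while still distinguishing
format problems from statistical degeneracies.
"""


class MROrientError(Exception):
    """Base class for all mrorient errors."""


class ValidationError(MROrientError, ValueError):
    """A dataset or parameter violates an invariant."""


class FormatError(ValidationError):
    """A file does not conform to the expected tabular format."""


class DimensionError(ValidationError):
    """Vector lengths do not agree."""


class CapacityError(ValidationError):
    """More coding schemes requested than distinct equivalence classes exist."""


class DegenerateSNPError(MROrientError, ValueError):
    """A SNP is monomorphic in the simulated sample (zero genotype variance)."""


class DegenerateInstrumentsError(MROrientError, ValueError):
    """All SNP-exposure associations are zero; no estimator is defined."""


class CollinearityError(MROrientError, ValueError):
    """Zero (weighted) variance of the SNP-exposure associations."""


class RatioUndefinedError(MROrientError, ZeroDivisionError):
    """A Wald ratio is undefined because an exposure association is exactly zero."""


class NomeExactError(MROrientError, ValueError):
    """I-squared is undefined when all exposure standard errors are zero (exact NOME)."""


class MethodMismatchError(MROrientError, TypeError):
    """An operation received an estimate from an incompatible method."""
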