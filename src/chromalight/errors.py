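"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`ChromalightError` so callers can catch the package's own failures
without swallowing genuine bugs.
"""


class ChromalightError(Exception):
    """Base class for all errors raised by chromalight."""


class GridError(ChromalightError, ValueError):
    """Spectral grids of two operands do not match."""


class RangeError(ChromalightError, ValueError):
    """A wavelength range extends beyond the data that supports it."""


class UndefinedChromaticityError(ChromalightError, ValueError):
    """Chromaticity requested for a spectrum with no visual signal."""


class DivisionGuardError(ChromalightError, ValueError):
    """Ratio estimate would divide by a (near-)zero denominator channel."""


class ValidationError(ChromalightError, ValueError):
    """Input record or table violates a structural contract."""


class DomainError(ChromalightError, ValueError):
    """Scalar parameter outside its physical or model domain."""


class FitError(ChromalightError, ValueError):
    """A model fit cannot be performed (e.g. rank-deficient design)."""


class NormalizationError(ChromalightError, ValueError):
    """A normalization constant is zero or undefined."""


class OutsideSupportError(ChromalightError, ValueError):
    """A query point falls outside the support of a computed surface."""


class ParseError(ChromalightError, ValueError):
    """A CSV input does not conform to the spectral dialect."""


class PipelineError(ChromalightError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
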