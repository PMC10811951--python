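"""Exception hierarchy.

All errors raised by this package derive from :class:`GenopcaError` so
callers can catch everything with one clause; the subclasses distinguish
the failure modes the API contracts name.
"""


class GenopcaError(Exception):
    """Base class for all package errors."""


class ParameterError(GenopcaError, ValueError):
    """A numeric parameter is outside its documented domain."""


class CodingError(GenopcaError, ValueError):
    """Genotype values are incompatible with the declared coding."""


class DegenerateInputError(GenopcaError, ValueError):
    """Input is structurally valid but the operation is undefined on it
    (e.g. a single locus for the covariance matrix, an all-zero matrix
    for the approximate Jaccard normalizer)."""


class ShapeError(GenopcaError, ValueError):
    """Dimension mismatch between operands."""


class SizeGuardError(GenopcaError, ValueError):
    """A dense oracle was requested on an input too large to densify."""


class FormatError(GenopcaError, ValueError):
    """A file could not be parsed in the expected format."""
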