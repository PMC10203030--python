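"""Exception hierarchy for the scale-of-effect pipeline.

All errors derive from :class:`ScaleOfEffectError` so callers can catch the
package's failures with a single clause; most are also ``ValueError``
subclasses because they signal invalid inputs.
"""


class ScaleOfEffectError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(ScaleOfEffectError, ValueError):
    """An argument violates a documented precondition."""


class OutOfExtentError(ScaleOfEffectError, ValueError):
    """A buffer disc extends beyond the landscape grid.

    Buffers are required to lie fully inside the grid; silently truncated
    buffers would bias cover proportions.
    """


class ParseError(ScaleOfEffectError, ValueError):
    """A file does not conform to its declared format."""


class UndefinedResponseError(ScaleOfEffectError, ValueError):
    """A response value is undefined for a site (e.g. all-zero counts)."""


class AlignmentError(ScaleOfEffectError, ValueError):
    """Sites in a cover profile and a response vector do not match."""


class CollinearityError(ScaleOfEffectError, ValueError):
    """Two predictors are too correlated for a stable multiple regression."""


class FeasibilityError(ScaleOfEffectError, RuntimeError):
    """A stochastic construction (e.g. site packing) could not be satisfied."""
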