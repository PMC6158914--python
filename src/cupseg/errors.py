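"""Exception hierarchy for cupseg.

Every error raised by the package derives from :class:`CupsegError` so
callers can catch the library's failures without catching programming
errors.
"""


class CupsegError(Exception):
    """Base class for all cupseg errors."""


class FormatError(CupsegError):
    """Raster has the wrong number of channels / dtype for the operation."""


class ShapeMismatchError(CupsegError):
    """Two grids that must share a shape do not."""


class ParameterError(CupsegError):
    """A parameter violates its documented constraint."""


class DegenerateInputError(CupsegError):
    """Input is formally valid but the operation is undefined on it
    (constant image for seeding, empty mask for a diameter, ...)."""


class NumericalError(CupsegError):
    """An iterative scheme produced non-finite values (blow-up)."""


class ConvergenceError(CupsegError):
    """An evolution collapsed to a degenerate state (e.g. empty region)."""
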