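"""Exception hierarchy used across the package."""


class ShgTexError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(ShgTexError, ValueError):
    """A configuration or function parameter is outside its valid range."""


class ShapeError(ShgTexError, ValueError):
    """An array does not have the shape an operation requires."""


class RangeError(ShgTexError, ValueError):
    """Pixel values are outside the declared bit-depth range."""


class EmptyPairError(ShgTexError, ValueError):
    """A region yields no pixel pairs for the requested (d, theta) offset."""


class InsufficientDataError(ShgTexError, ValueError):
    """Fewer samples than required (e.g. fewer feature vectors than k)."""


class NoSignalError(ShgTexError, ValueError):
    """An image has no patch passing the signal filter."""


class DegenerateTrainingError(ShgTexError, ValueError):
    """Training data contains fewer than two classes."""


class FoldError(ShgTexError, ValueError):
    """A class has too few members to fill the requested number of folds."""
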