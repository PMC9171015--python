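"""Exception hierarchy.

``ParameterError`` signals bad user input (CLI exit code 1); the remaining
errors signal processing failures (CLI exit code 2).
"""


class CocScreenError(Exception):
    """Base class for all package errors."""


class ParameterError(CocScreenError, ValueError):
    """Invalid argument values (negative areas, bad probabilities, ...)."""


class SegmentationError(CocScreenError):
    """No usable object could be segmented from an image."""


class PlacementError(CocScreenError):
    """Synthetic spot placement failed (infeasible packing)."""


class ThresholdUndefinedError(CocScreenError):
    """Automatic thresholding is undefined (saturated/constant image)."""


class TableFormatError(CocScreenError):
    """A CSV table violates the documented schema."""


class PairingError(CocScreenError):
    """Before/after measurements cannot be matched one-to-one."""
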