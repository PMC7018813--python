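"""Exception hierarchy shared across the pipeline.

All errors derive from :class:`DynconnError` so callers can catch the whole
family; each subclass also derives from the closest builtin (``ValueError``,
``OSError``) so untargeted handling behaves conventionally.
"""


class DynconnError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DynconnError, ValueError):
    """A parameter violates its documented domain (negative rate, bad span, ...)."""


class ShapeMismatchError(DynconnError, ValueError):
    """Two series/arrays that must be aligned have different lengths or rates."""


class WindowError(DynconnError, ValueError):
    """A trace is too short for the requested window/span."""


class DegenerateBaselineError(DynconnError, ValueError):
    """Baseline fluorescence F0 <= 0 (typically over-subtracted background)."""


class LayoutError(DynconnError, ValueError):
    """Synthetic ROI layout is infeasible (overlapping disks, out of frame)."""


class BoundsError(DynconnError, ValueError):
    """An ROI seed falls outside the frame (with its 1-pixel margin)."""


class InsufficientDataError(DynconnError, ValueError):
    """Not enough samples/pairs for the requested statistic."""


class StackIOError(DynconnError, OSError):
    """A video stack could not be read (missing, truncated, zero frames)."""


class ConfigError(DynconnError, ValueError):
    """A run configuration file is inconsistent or incomplete."""
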