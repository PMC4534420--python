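"""Exception hierarchy for aslpower.

All errors derive from :class:`ASLPowerError` and, where natural, from the
matching builtin so that callers may catch either.
"""


class ASLPowerError(Exception):
    """Base class for all aslpower errors."""


class InvalidParameterError(ASLPowerError, ValueError):
    """A parameter violates its documented domain (e.g. negative CBF)."""


class DimensionError(ASLPowerError, ValueError):
    """Arrays that must share a voxel grid do not."""


class MalformedSeriesError(ASLPowerError, ValueError):
    """A label/control series cannot be split into pairs (odd volume count)."""


class InsufficientDataError(ASLPowerError, ValueError):
    """Too few observations for the requested statistic (e.g. t-test with n < 2)."""


class EmptyMaskError(ASLPowerError, ValueError):
    """An operation that requires a nonempty voxel mask received an empty one."""


class EmptyMaskWarning(UserWarning):
    """A segmentation step produced an empty mask (warned, not raised)."""
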