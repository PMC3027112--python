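"""Exception hierarchy shared across the package."""


class ShortCourseError(Exception):
    """Base class for all errors raised by shortcourse."""


class FormatError(ShortCourseError):
    """A file does not conform to the tab-delimited input format."""


class ValidationError(ShortCourseError):
    """Parsed content violates a semantic invariant (duplicate ids, mismatched designs...)."""


class UsageError(ShortCourseError):
    """An operation was requested on data that does not support it."""


class ParameterError(ShortCourseError, ValueError):
    """An argument value is outside the operation's domain."""


class RangeError(ParameterError):
    """A query time falls outside the observed time range (no extrapolation)."""
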