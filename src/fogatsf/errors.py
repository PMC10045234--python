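"""Exception hierarchy for the fogatsf package."""


class FogatsfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(FogatsfError):
    """A file does not conform to the expected dialect (missing columns, bad intervals)."""


class DataError(FogatsfError):
    """The file parsed but its contents are inconsistent (non-monotonic or jittery clocks)."""


class UsageError(FogatsfError):
    """An operation was called with arguments that violate its contract."""


class UndefinedMetricError(FogatsfError):
    """A metric has no defined value on this input (e.g. no active samples)."""
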