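"""Package-specific error types.

All inherit from ValueError so that callers treating parameter problems
generically keep working.
"""


class SignalQualityError(ValueError):
    """Raised when a signal segment fails a quality gate (e.g. too many
    corrected RR intervals) and must be excluded from analysis."""


class EmptyResultError(ValueError):
    """Raised when a detector finds nothing usable (e.g. no R peaks)."""


class WindowError(ValueError):
    """Raised when a phase is too short for the requested analysis window."""
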