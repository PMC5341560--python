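"""Exception hierarchy shared across the pipeline stages."""


class HysemafiError(Exception):
    """Base class for all package errors."""


class FormatError(HysemafiError, ValueError):
    """A file or record violates its format contract (named invariant)."""


class ConsistencyError(HysemafiError, ValueError):
    """Cross-record bookkeeping broke (unknown id, length mismatch, ...)."""


class UnsupportedInputError(HysemafiError, ValueError):
    """Input is syntactically valid but lacks information we require."""


class ResourceBudgetError(HysemafiError, RuntimeError):
    """A computation would exceed its configured budget."""


class UsageError(HysemafiError, ValueError):
    """Caller passed an argument outside its documented domain."""
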