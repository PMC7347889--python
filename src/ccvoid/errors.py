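"""Exception types shared across the package."""


class CCVoidError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(CCVoidError, ValueError):
    """A synthetic-data specification violates its invariants."""


class FormatError(CCVoidError, ValueError):
    """An input file is not in the expected format."""


class ValidationError(CCVoidError, ValueError):
    """A result or table violates its declared invariants."""


class EmptyRegionError(CCVoidError, ValueError):
    """An operation was asked to work on an empty analyzed region."""


class UsageError(CCVoidError, ValueError):
    """An operation was called with arguments outside its contract."""
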