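"""Exception types shared across the package."""


class ImmunopanelError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ImmunopanelError, ValueError):
    """A file could not be parsed (message names the offending line)."""


class ValidationError(ImmunopanelError, ValueError):
    """Input data violates a documented invariant."""
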