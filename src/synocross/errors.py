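"""Exception types shared across the package."""


class SynocrossError(Exception):
    """Base class for all package errors."""


class ValidationError(SynocrossError):
    """A configuration or data object violates an invariant.

    ``field`` names the offending field so callers (and the CLI) can point
    the user at exactly what to fix.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class FormatError(SynocrossError):
    """An input file does not conform to the documented dialect."""
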