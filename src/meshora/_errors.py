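"""Exception types shared across the package."""


class MeshoraError(Exception):
    """Base class for all package errors."""


class ValidationError(MeshoraError, ValueError):
    """Invalid user input: bad ids, malformed values, violated invariants."""


class StoreFormatError(ValidationError):
    """A store file failed to parse; message carries file and line number."""
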