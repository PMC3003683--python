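"""Exception hierarchy shared by all sagemine modules."""


class SagemineError(Exception):
    """Base class for every error this package raises on bad data or usage."""


class ParseError(SagemineError):
    """A file does not conform to its declared text dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f"{path}"
            if line is not None:
                loc += f":{line}"
            loc = f" [{loc}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(SagemineError):
    """A value violates a domain invariant (bad tag, bad count, bad enum)."""


class DomainError(SagemineError):
    """An operation was asked for outside its mathematical domain."""


class IncompatibleLibrariesError(SagemineError):
    """Libraries with mixed tag types or enzymes cannot be merged."""


class ConfigurationError(SagemineError):
    """A condition pool or run configuration is unusable as given."""
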