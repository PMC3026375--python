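"""Exception hierarchy shared across the package."""


class IntroviewError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(IntroviewError):
    """A file could not be parsed.

    Carries the offending line number (1-based) when known.
    """

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ValidationError(IntroviewError):
    """Input parsed but violates a semantic constraint."""
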