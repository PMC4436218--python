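"""Exception types shared across nucmap."""


class NucmapError(Exception):
    """Base class for all nucmap errors."""


class FormatError(NucmapError, ValueError):
    """A file does not conform to its declared format."""


class ParseError(FormatError):
    """A specific line of an input file could not be parsed."""

    def __init__(self, message: str, path=None, line_number: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line_number is not None:
            loc += f":{line_number}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line_number = line_number


class ValidationError(NucmapError, ValueError):
    """A value violates a documented contract."""


class FitError(NucmapError, RuntimeError):
    """A model fit could not be carried out."""


class ConfigError(NucmapError, ValueError):
    """A simulation or pipeline configuration is invalid."""
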