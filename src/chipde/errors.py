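"""Exception hierarchy shared across the pipeline.

Everything derives from :class:`ChipdeError` so callers can catch one base;
parsers raise subclasses that carry enough context (file, line) to fix the
offending input rather than silently clamping it.
"""


class ChipdeError(Exception):
    """Base class for all package errors."""


class ValidationError(ChipdeError, ValueError):
    """A value or configuration violates a documented precondition."""


class SizingError(ValidationError):
    """A requested size cannot be satisfied (genome too small, pool exhausted)."""


class ParseError(ChipdeError, ValueError):
    """A file could not be parsed as its declared format."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class CoordinateError(ParseError):
    """A genomic coordinate lies outside its chromosome bounds."""


class FormatError(ParseError):
    """Structurally invalid records (e.g. overlapping bedGraph intervals)."""
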