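"""Exception types shared across the package."""


class BelhierError(Exception):
    """Base class for package errors."""


class BELParseError(BelhierError):
    """Malformed BEL statement text (unbalanced parentheses, stray tokens)."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (offset {offset})"
        super().__init__(message)


class UnsupportedRelationError(BelhierError):
    """Relation keyword outside the supported causal set, or a nested relation."""


class MalformedSequenceError(BelhierError):
    """Node sequence whose arity bookkeeping does not yield exactly one tree."""


class RenderError(BelhierError):
    """Statement rendering failed (unresolvable placeholder or 'or' root)."""


class FormatError(BelhierError):
    """Malformed external file (CoNLL-U, TSV, tag file)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class TagGenerationError(BelhierError):
    """Instance cannot be hierarchically tagged (unaligned node, overlap)."""
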