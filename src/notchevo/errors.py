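"""Exception hierarchy shared by all pipeline stages.

``ParseError`` means the bytes could not be interpreted as the declared
format; ``ValidationError`` means the file parsed but violates a domain
invariant (duplicate ids, negative expression, impossible coordinates).
The CLI maps these to distinct exit codes.
"""


class NotchevoError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NotchevoError):
    """Input could not be parsed as the declared format."""


class ValidationError(NotchevoError):
    """Parsed input violates a domain invariant."""


class PlantError(NotchevoError):
    """A requested synthetic mutation cannot be planted at the given site."""


class AmbiguousClassificationError(ValidationError):
    """Two equally specific family signatures match the same gene."""

    def __init__(self, gene_id: str, families: list):
        self.gene_id = gene_id
        self.families = list(families)
        super().__init__(
            f"gene {gene_id!r}: equally specific signatures matched: "
            + ", ".join(sorted(self.families))
        )
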