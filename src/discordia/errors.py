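"""Exception hierarchy shared across the package."""


class TreeError(Exception):
    """Base class for all tree-related errors."""


class NewickParseError(TreeError):
    """Malformed Newick input; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class TreeValidationError(TreeError):
    """Structurally valid input that violates a domain invariant."""


class UnrootableError(TreeError):
    """No outgroup taxon present, or every candidate clade spans the tree."""


class DegenerateTreeError(TreeError):
    """Operation requires more tips than the tree provides."""


class EmptyProfileError(TreeError):
    """All gene trees were removed by the active filters."""
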