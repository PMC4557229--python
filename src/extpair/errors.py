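"""Exception hierarchy shared across the package."""


class ExtpairError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(ExtpairError):
    """Malformed PDB input; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(ExtpairError):
    """Input contained no nucleotide residues."""


class IncompleteBaseError(ExtpairError):
    """A residue lacks the atoms required for a geometric operation."""


class FormatError(ExtpairError):
    """Malformed secondary-structure text (dot-bracket, BPSEQ, CT)."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class EvaluationError(ExtpairError):
    """Incompatible or insufficient inputs to an accuracy computation."""
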