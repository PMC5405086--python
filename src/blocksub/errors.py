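"""Named error types for BLOCK validation and parameter computation.

Every malformed input maps to exactly one of these; nothing is silently
repaired.
"""


class BlockSubError(Exception):
    """Base class for all blocksub errors."""


class BlockValidationError(BlockSubError):
    """Base class for BLOCK input-contract violations."""


class UnequalLengthError(BlockValidationError):
    """Sequences differ in length — the input is not a gap-free block."""


class GapPresentError(BlockValidationError):
    """A gap character ('-' or '.') was found; blocks are gap-free."""


class IllegalResidueError(BlockValidationError):
    """A character outside the 20 standard one-letter codes was found."""

    def __init__(self, residue: str, seq_id: str, column: int):
        self.residue = residue
        self.seq_id = seq_id
        self.column = column
        super().__init__(
            f"illegal residue {residue!r} in sequence {seq_id!r} "
            f"at column {column + 1}"
        )


class DuplicateIdError(BlockValidationError):
    """Two records share the same identifier."""


class EmptyInputError(BlockValidationError):
    """Fewer than two sequences — not an alignment."""


class InvalidSchemeError(BlockSubError):
    """A residue class scheme violates the partition invariants."""


class NoHeteroPairsError(BlockSubError):
    """Every column is invariant; hetero-pair statistics are undefined."""


class NoConservativeSubstitutionsError(BlockSubError):
    """Hetero-pairs exist but none are within-class; R is undefined."""


class DegenerateSpecError(BlockSubError):
    """Synthetic block specification cannot yield a valid block."""


class InsufficientDataError(BlockSubError):
    """Too few blocks for a cross-block statistic."""


class ZeroVarianceError(BlockSubError):
    """A correlation input has zero variance."""
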