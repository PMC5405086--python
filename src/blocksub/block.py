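"""Reading, validating and writing BLOCK-FASTA files.

A *block* is a gap-free multiple alignment of orthologous protein
sequences: every record has identical length, every character is one of
the 20 standard amino-acid one-letter codes, and every column is a fixed
homologous position (sensu Henikoff & Henikoff).  The block is the unit
of analysis for every statistic in this package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateIdError,
    EmptyInputError,
    GapPresentError,
    IllegalResidueError,
    UnequalLengthError,
)

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical by one-letter code.
RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"
RESIDUE_SET = frozenset(RESIDUES)
#: Index of each residue in :data:`RESIDUES` (matrix ordering everywhere).
RESIDUE_INDEX = {aa: i for i, aa in enumerate(RESIDUES)}

GAP_CHARS = frozenset("-.")
#: Ambiguity / non-standard codes that may appear in real FASTA files.
AMBIGUOUS_RESIDUES = frozenset("XBZUOJ")


@dataclass(frozen=True)
class Block:
    """A validated gap-free, equal-length set of aligned protein sequences.

    Parameters
    ----------
    ids
        Record identifiers, unique, in file order.
    sequences
        Upper-case residue strings, all of identical length.
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        validate_records(list(zip(self.ids, self.sequences)))

    @property
    def depth(self) -> int:
        """Number of sequences."""
        return len(self.sequences)

    @property
    def width(self) -> int:
        """Number of alignment columns."""
        return len(self.sequences[0])

    def column(self, j: int) -> str:
        """Residues of column ``j`` (0-based), one per sequence."""
        return "".join(seq[j] for seq in self.sequences)

    def columns(self) -> Iterator[str]:
        """Iterate over columns as depth-length residue strings."""
        for j in range(self.width):
            yield self.column(j)


def validate_records(records: list[tuple[str, str]]) -> None:
    """Check the block invariants, raising the first named violation.

    Order of checks: emptiness, duplicate ids, equal length, gaps,
    residue alphabet.  Raises one of the ``errors`` module exceptions.
    """
    if len(records) < 2:
        raise EmptyInputError(
            f"a block needs at least 2 sequences, got {len(records)}"
        )
    seen: set[str] = set()
    for rid, _ in records:
        if rid in seen:
            raise DuplicateIdError(f"duplicate identifier {rid!r}")
        seen.add(rid)
    width = len(records[0][1])
    if width < 1:
        raise EmptyInputError("sequences are empty")
    for rid, seq in records:
        if len(seq) != width:
            raise UnequalLengthError(
                f"sequence {rid!r} has length {len(seq)}, expected {width}"
            )
    for rid, seq in records:
        for j, ch in enumerate(seq):
            if ch in GAP_CHARS:
                raise GapPresentError(
                    f"gap character {ch!r} in sequence {rid!r} at column {j + 1}"
                )
            if ch not in RESIDUE_SET:
                raise IllegalResidueError(ch, rid, j)


def _drop_bad_columns(records: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Remove every column containing a non-standard residue code."""
    width = len(records[0][1])
    bad = set()
    for rid, seq in records:
        for j, ch in enumerate(seq):
            if ch not in RESIDUE_SET and ch not in GAP_CHARS:
                bad.add(j)
    if bad:
        logger.info(
            "dropping %d column(s) with non-standard residues: %s",
            len(bad),
            ", ".join(str(j + 1) for j in sorted(bad)),
        )
        keep = [j for j in range(width) if j not in bad]
        records = [
            (rid, "".join(seq[j] for j in keep)) for rid, seq in records
        ]
    return records


def read_block_fasta(path: str | Path, drop_bad_columns: bool = False) -> Block:
    """Read a BLOCK-FASTA file into a validated :class:`Block`.

    Sequences are normalised to upper case; identifiers are the header
    text up to the first whitespace.  With ``drop_bad_columns`` every
    column containing a non-standard residue (X, B, Z, U, O, J) is
    removed (and logged) instead of raising ``IllegalResidueError``.
    """
    records = [
        (rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if len(records) < 2:
        raise EmptyInputError(
            f"{path}: a block needs at least 2 sequences, got {len(records)}"
        )
    if drop_bad_columns:
        # length and gap checks still apply before column surgery
        width = len(records[0][1])
        for rid, seq in records:
            if len(seq) != width:
                raise UnequalLengthError(
                    f"sequence {rid!r} has length {len(seq)}, expected {width}"
                )
        records = _drop_bad_columns(records)
    return Block(
        ids=tuple(rid for rid, _ in records),
        sequences=tuple(seq for _, seq in records),
    )


def write_block_fasta(block: Block, path: str | Path) -> None:
    """Write ``block`` as standard multi-FASTA with 60-column wrapping.

    ``read_block_fasta(write_block_fasta(b))`` reproduces ``b`` exactly.
    """
    records = [
        SeqRecord(Seq(seq), id=rid, description="")
        for rid, seq in zip(block.ids, block.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
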