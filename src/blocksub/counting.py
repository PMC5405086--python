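"""Column-wise substitution-pair counting.

Every column of a block contributes one residue pair per unordered pair
of sequences — the BLOSUM counting convention.  A depth-n block of
width w therefore yields exactly w·C(n,2) pair observations, split
between 20 homo-pair types (identical residues, the matrix diagonal)
and 190 hetero-pair types (the folded off-diagonal).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from .block import Block, RESIDUE_INDEX, RESIDUES


def pair_label(a: str, b: str) -> str:
    """Canonical two-letter label of an unordered pair, e.g. 'AV'."""
    return a + b if a <= b else b + a


@dataclass(frozen=True)
class PairCounts:
    """Symmetric 20×20 tally of residue pairs over a whole block.

    ``counts[i, j] == counts[j, i]`` holds the number of (unordered)
    sequence-pair observations of residues ``RESIDUES[i]`` and
    ``RESIDUES[j]``; the diagonal holds homo-pair counts.
    """

    counts: np.ndarray  # (20, 20) int64, symmetric
    n_columns: int
    n_sequences: int

    def __post_init__(self) -> None:
        c = self.counts
        if c.shape != (20, 20):
            raise ValueError("counts must be 20x20")
        if not np.array_equal(c, c.T):
            raise ValueError("counts must be symmetric")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        """All pair observations: width × C(depth, 2)."""
        return int(np.triu(self.counts).sum())

    @property
    def homo_total(self) -> int:
        return int(self.counts.diagonal().sum())

    @property
    def hetero_total(self) -> int:
        return self.total - self.homo_total

    def count(self, a: str, b: str) -> int:
        """Observations of the unordered pair {a, b}."""
        return int(self.counts[RESIDUE_INDEX[a], RESIDUE_INDEX[b]])

    def __add__(self, other: "PairCounts") -> "PairCounts":
        if self.n_sequences != other.n_sequences:
            raise ValueError("can only add counts over equal-depth slices")
        return PairCounts(
            counts=self.counts + other.counts,
            n_columns=self.n_columns + other.n_columns,
            n_sequences=self.n_sequences,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PairCounts):
            return NotImplemented
        return (
            self.n_columns == other.n_columns
            and self.n_sequences == other.n_sequences
            and np.array_equal(self.counts, other.counts)
        )


def count_pairs(block: Block) -> PairCounts:
    """Tally all substitution pairs of a block.

    For each column with residue multiplicities ``c``, the pair counts
    are ``C(c_a, 2)`` on the diagonal and ``c_a · c_b`` off-diagonal —
    algebraically identical to enumerating every unordered sequence
    pair, but linear in depth per column.
    """
    # residue occurrence matrix: columns × 20
    idx = np.array(
        [[RESIDUE_INDEX[ch] for ch in seq] for seq in block.sequences],
        dtype=np.int64,
    )  # depth × width
    occ = np.zeros((block.width, 20), dtype=np.int64)
    for j in range(block.width):
        np.add.at(occ[j], idx[:, j], 1)
    cross = occ.T @ occ  # ordered-pair totals
    counts = cross.copy()
    homo = (cross.diagonal() - occ.sum(axis=0)) // 2
    np.fill_diagonal(counts, homo)
    return PairCounts(
        counts=counts, n_columns=block.width, n_sequences=block.depth
    )


def hetero_frequencies(pc: PairCounts) -> tuple[dict[str, int], int]:
    """Folded off-diagonal counts for all 190 hetero-pair types.

    Returns a map from the two-letter pair label (alphabetical order of
    labels) to its count — zero-count types included — together with
    the total hetero count.
    """
    freqs = {
        pair_label(a, b): pc.count(a, b) for a, b in combinations(RESIDUES, 2)
    }
    return freqs, pc.hetero_total


def write_counts_tsv(pc: PairCounts, path: str | Path) -> None:
    """Export the symmetric 20×20 matrix as TSV, residues alphabetical."""
    lines = ["\t".join(["res", *RESIDUES])]
    for i, aa in enumerate(RESIDUES):
        lines.append("\t".join([aa, *map(str, pc.counts[i])]))
    Path(path).write_text("\n".join(lines) + "\n")
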