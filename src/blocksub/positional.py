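"""Per-column conservation and class typing.

Columns are scored by Shannon entropy (bits) of their residue
proportions and typed by an ordered eight-way decision list on class
membership: INV (invariant), HB (hydrophobic-only), Ac (acidic-only),
Bs (basic-only), PC (polar-charged mixed), ST (Ser/Thr-only), HB+HL
(mixed sides) and PU+PC (any other hydrophilic-only mix).  A column is
*conserved* when its entropy does not exceed a threshold, 1.0 bit by
default — roughly two equiprobable residues.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .block import Block
from .classes import ClassScheme

#: Column categories in report order.
CATEGORIES = ("INV", "HB", "Ac", "Bs", "PC", "ST", "HB_HL", "PU_PC")

DEFAULT_ENTROPY_THRESHOLD = 1.0  # bits


def shannon_entropy(column: str) -> float:
    """Shannon entropy H = −Σ pᵢ log₂ pᵢ of a column's residues, in bits."""
    counts = np.array(list(Counter(column).values()), dtype=float)
    return float(_scipy_entropy(counts, base=2))


def column_category(column: str, scheme: ClassScheme) -> str:
    """Type a column by the first matching rule of the decision list.

    (1) single residue type → INV; (2) all hydrophobic → HB; (3) all
    acidic → Ac; (4) all basic → Bs; (5) all polar-charged with both
    acidic and basic present → PC; (6) all Ser/Thr → ST; (7) both sides
    present → HB_HL; (8) anything else (hydrophilic-only mixes) →
    PU_PC.  The precedence makes the categories exclusive.
    """
    residues = set(column)
    if len(residues) == 1:
        return "INV"
    if residues <= scheme.hydrophobic:
        return "HB"
    if residues <= scheme.acidic:
        return "Ac"
    if residues <= scheme.basic:
        return "Bs"
    if (
        residues <= scheme.polar_charged
        and residues & scheme.acidic
        and residues & scheme.basic
    ):
        return "PC"
    if residues <= scheme.ser_thr:
        return "ST"
    if residues & scheme.hydrophobic and residues & scheme.hydrophilic:
        return "HB_HL"
    return "PU_PC"


@dataclass(frozen=True)
class PositionProfile:
    """Entropy, conservation and category of a single column."""

    column_index: int  # 0-based
    entropy_bits: float
    invariant: bool
    conserved: bool
    category: str


@dataclass(frozen=True)
class PositionalSummary:
    """Aggregate of all column profiles of one block.

    ``category_percent`` partitions (sums to 100 up to rounding);
    ``percent_conserved`` overlaps the categories and is reported
    separately, as is ``percent_invariant`` (== the INV category).
    """

    profiles: tuple[PositionProfile, ...]
    category_percent: dict[str, float]
    percent_invariant: float
    percent_conserved: float
    entropy_threshold: float


def profile_columns(
    block: Block,
    scheme: ClassScheme,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
) -> tuple[PositionProfile, ...]:
    """Profile every column of a block."""
    profiles = []
    for j, col in enumerate(block.columns()):
        h = shannon_entropy(col)
        cat = column_category(col, scheme)
        profiles.append(
            PositionProfile(
                column_index=j,
                entropy_bits=h,
                invariant=(cat == "INV"),
                conserved=(h <= entropy_threshold),
                category=cat,
            )
        )
    return tuple(profiles)


def positional_summary(
    block: Block,
    scheme: ClassScheme,
    entropy_threshold: float = DEFAULT_ENTROPY_THRESHOLD,
) -> PositionalSummary:
    """Percent of columns per category plus %invariant and %conserved."""
    profiles = profile_columns(block, scheme, entropy_threshold)
    n = len(profiles)
    cat_pct = {
        cat: 100.0 * sum(p.category == cat for p in profiles) / n
        for cat in CATEGORIES
    }
    return PositionalSummary(
        profiles=profiles,
        category_percent=cat_pct,
        percent_invariant=cat_pct["INV"],
        percent_conserved=100.0 * sum(p.conserved for p in profiles) / n,
        entropy_threshold=entropy_threshold,
    )
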