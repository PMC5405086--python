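"""Block-level evolutionary parameters derived from pair counts.

All parameters are frequency shares of the observed hetero-pairs:

* ``E`` — hetero-pair *type usage*: the percentage of the 190 possible
  hetero-pair types observed at least once.  0 means no substitution at
  all; 100 means every type occurs.
* ``R`` — the non-conservative to conservative substitution ratio,
  ``100 · f(HB-HL) / (f(HB-HB) + f(HL-HL))``, the parameter that tracks
  a family's divergence rate.
* ``D`` — the dominant hetero-pair: the type of maximal observed
  frequency, with its share of the hetero total.
* ``RD`` — residue diversity: each residue's share of hetero-pair
  occurrences (each occurrence has two members, so ΣRD = 200).  ``MDR``
  is its argmax (the maximally diverse residue), ``RDmin`` its argmin.
* ``CD`` — class-specific diversity: the share of hetero-pair
  occurrences with at least one member in a class.  CD over the
  hydrophobic and hydrophilic sides over-counts cross-class pairs,
  which yields the identity
  ``R = 100 · (CD_HB + CD_HL − 100) / (200 − CD_HB − CD_HL)``.

Occurrence-weighted (frequency-share) definitions are used throughout:
they are the ones consistent with the published family tables through
the R↔CD identity above.  Percentages are computed from exact integer
counts; rounding happens only at reporting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable

import numpy as np

from .block import RESIDUES, RESIDUE_INDEX
from .classes import ClassScheme, PairCategory
from .counting import PairCounts, pair_label
from .errors import NoConservativeSubstitutionsError, NoHeteroPairsError

N_HETERO_TYPES = 190


def compute_E(pc: PairCounts) -> float:
    """Hetero-pair type usage as a percent of the 190 possible types."""
    off = pc.counts.copy()
    np.fill_diagonal(off, 0)
    used = int(np.count_nonzero(np.triu(off, 1)))
    return 100.0 * used / N_HETERO_TYPES


def category_frequencies(
    pc: PairCounts, scheme: ClassScheme
) -> dict[PairCategory, int]:
    """Total observations per pair category (HOMO, HB_HB, HL_HL, HB_HL)."""
    out = {cat: 0 for cat in PairCategory}
    out[PairCategory.HOMO] = pc.homo_total
    for a, b in combinations(RESIDUES, 2):
        out[scheme.pair_category(a, b)] += pc.count(a, b)
    return out


def compute_R(pc: PairCounts, scheme: ClassScheme) -> float:
    """Non-conservative / conservative substitution ratio, in percent.

    Raises ``NoConservativeSubstitutionsError`` when hetero-pairs exist
    but all are cross-class; returns 0.0 for a fully invariant block
    (no hetero-pairs at all — flagged in :class:`BlockSummary`).
    """
    if pc.hetero_total == 0:
        return 0.0
    freqs = category_frequencies(pc, scheme)
    conservative = freqs[PairCategory.HB_HB] + freqs[PairCategory.HL_HL]
    if conservative == 0:
        raise NoConservativeSubstitutionsError(
            "all hetero-pairs are cross-class; R is undefined"
        )
    return 100.0 * freqs[PairCategory.HB_HL] / conservative


def r_from_class_diversity(cd_hb: float, cd_hl: float) -> float:
    """Recover R from the hydrophobic/hydrophilic class diversities.

    Since CD_HB + CD_HL counts cross-class occurrences twice,
    ``CD_HB + CD_HL − 100`` is the cross-class share and
    ``200 − CD_HB − CD_HL`` the within-class share, so

        R = 100 · (CD_HB + CD_HL − 100) / (200 − CD_HB − CD_HL).

    Useful for auditing published family tables that print CD but whose
    underlying alignments are unavailable.
    """
    return 100.0 * (cd_hb + cd_hl - 100.0) / (200.0 - cd_hb - cd_hl)


def dominant_pair(pc: PairCounts) -> tuple[str, float]:
    """The hetero-pair type of maximal observed frequency and its share.

    Share is the percent of the total hetero count; ties break on the
    alphabetical order of the two-letter pair label.
    """
    if pc.hetero_total == 0:
        raise NoHeteroPairsError("block has no hetero-pairs")
    best_label, best_count = None, -1
    for a, b in combinations(RESIDUES, 2):
        c = pc.count(a, b)
        if c > best_count:  # first hit wins ties: labels are alphabetical
            best_label, best_count = pair_label(a, b), c
    return best_label, 100.0 * best_count / pc.hetero_total


def residue_diversity(pc: PairCounts) -> tuple[dict[str, float], str, str]:
    """Per-residue share of hetero-pair occurrences (RD), MDR and RDmin.

    RD(x) = 100 × (hetero occurrences involving x) / total hetero
    occurrences.  Each occurrence involves two residues, so the RD map
    sums to 200.  MDR is the argmax, RDmin the argmin, both with
    alphabetical tie-breaks.
    """
    if pc.hetero_total == 0:
        raise NoHeteroPairsError("block has no hetero-pairs")
    off = pc.counts.copy()
    np.fill_diagonal(off, 0)
    involvement = off.sum(axis=1)  # hetero occurrences touching residue i
    rd = {
        aa: 100.0 * int(involvement[i]) / pc.hetero_total
        for i, aa in enumerate(RESIDUES)
    }
    mdr = max(RESIDUES, key=lambda aa: (rd[aa], ))  # max keeps first on ties
    # max() keeps the first (alphabetically earliest) residue on ties;
    # same for min below.
    rdmin = min(RESIDUES, key=lambda aa: (rd[aa], ))
    return rd, mdr, rdmin


def class_diversity(pc: PairCounts, scheme: ClassScheme) -> dict[str, float]:
    """Per-class share of hetero occurrences with ≥1 member in the class.

    Classes reported: acidic, basic, non_polar, hydrophobic,
    hydrophilic.  Because a cross-class pair touches both sides,
    CD_HB + CD_HL = 100 + (cross-class share).
    """
    if pc.hetero_total == 0:
        raise NoHeteroPairsError("block has no hetero-pairs")
    cd: dict[str, float] = {}
    for name in ClassScheme.CD_CLASSES:
        members = scheme.members(name)
        touched = sum(
            pc.count(a, b)
            for a, b in combinations(RESIDUES, 2)
            if a in members or b in members
        )
        cd[name] = 100.0 * touched / pc.hetero_total
    return cd


@dataclass(frozen=True)
class BlockSummary:
    """One family-table-style record of the derived parameters.

    ``no_hetero`` flags a fully invariant block, for which R/E are 0 and
    the diversity fields are empty.  ``extras`` holds values of user
    plug-in parameters (see :func:`summarize`); no plug-ins are defined
    by default.
    """

    E: float
    R: float
    D: tuple[str, float] | None
    RD: dict[str, float]
    MDR: str | None
    RDmin: str | None
    CD: dict[str, float]
    no_hetero: bool = False
    extras: dict[str, float] = field(default_factory=dict)


def summarize(
    pc: PairCounts,
    scheme: ClassScheme,
    plugins: dict[str, Callable[[PairCounts, ClassScheme], float]] | None = None,
) -> BlockSummary:
    """Compute every block-level parameter in one record.

    ``plugins`` maps extra column names to callables of
    ``(PairCounts, ClassScheme)``; their values land in
    ``BlockSummary.extras``.  This is the hook for ratio parameters
    with no fixed definition here.
    """
    extras = {
        name: fn(pc, scheme) for name, fn in (plugins or {}).items()
    }
    if pc.hetero_total == 0:
        return BlockSummary(
            E=0.0, R=0.0, D=None, RD={aa: 0.0 for aa in RESIDUES},
            MDR=None, RDmin=None, CD={}, no_hetero=True, extras=extras,
        )
    rd, mdr, rdmin = residue_diversity(pc)
    return BlockSummary(
        E=compute_E(pc),
        R=compute_R(pc, scheme),
        D=dominant_pair(pc),
        RD=rd,
        MDR=mdr,
        RDmin=rdmin,
        CD=class_diversity(pc, scheme),
        no_hetero=False,
        extras=extras,
    )
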