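"""Amino-acid physicochemical class partition.

The 20 standard residues split into 9 hydrophobic (HB) and 11
hydrophilic (HL) residues; the hydrophilic side further splits into
acidic, basic and polar-uncharged sub-classes.  Those sizes are forced
by the pair-type combinatorics — C(9,2)=36 HB-HB, C(11,2)=55 HL-HL and
9×11=99 HB-HL hetero-pair types, 190 in total.  Substitutions within a
side (HB-HB or HL-HL) are *conservative*; cross-side (HB-HL)
substitutions are *non-conservative*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from pathlib import Path

from .block import RESIDUE_SET, RESIDUES
from .errors import InvalidSchemeError


class PairCategory(str, Enum):
    HOMO = "HOMO"
    HB_HB = "HB_HB"
    HL_HL = "HL_HL"
    HB_HL = "HB_HL"


#: Hetero-pair categories counted as conservative substitutions.
CONSERVATIVE_CATEGORIES = frozenset({PairCategory.HB_HB, PairCategory.HL_HL})


@dataclass(frozen=True)
class ClassScheme:
    """Partition of the 20 residues driving all class-based statistics.

    ``hydrophobic`` and ``hydrophilic`` must partition the alphabet with
    sizes 9 and 11; ``acidic``, ``basic`` and ``polar_uncharged`` must
    partition the hydrophilic side; ``ser_thr`` is fixed to {S, T};
    ``non_polar`` is the hydrophobic side plus glycine-like residues
    (a class-diversity grouping distinct from hydrophobic).
    """

    hydrophobic: frozenset[str]
    hydrophilic: frozenset[str]
    acidic: frozenset[str]
    basic: frozenset[str]
    polar_uncharged: frozenset[str]
    ser_thr: frozenset[str]
    non_polar: frozenset[str]

    def __post_init__(self) -> None:
        hb, hl = self.hydrophobic, self.hydrophilic
        if hb | hl != RESIDUE_SET or hb & hl:
            raise InvalidSchemeError(
                "hydrophobic/hydrophilic must partition the 20 residues"
            )
        if len(hb) != 9 or len(hl) != 11:
            raise InvalidSchemeError(
                f"sizes must be 9 hydrophobic / 11 hydrophilic, "
                f"got {len(hb)}/{len(hl)}"
            )
        if self.acidic & self.basic:
            raise InvalidSchemeError("acidic and basic must be disjoint")
        for name in ("acidic", "basic", "polar_uncharged"):
            if not getattr(self, name) <= hl:
                raise InvalidSchemeError(f"{name} must be hydrophilic")
        if self.acidic | self.basic | self.polar_uncharged != hl:
            raise InvalidSchemeError(
                "acidic ∪ basic ∪ polar_uncharged must cover the "
                "hydrophilic residues"
            )
        if self.ser_thr != frozenset("ST"):
            raise InvalidSchemeError("ser_thr must be exactly {S, T}")

    @property
    def polar_charged(self) -> frozenset[str]:
        """Acidic plus basic residues."""
        return self.acidic | self.basic

    def side(self, residue: str) -> str:
        """'HB' or 'HL' for a standard residue."""
        return "HB" if residue in self.hydrophobic else "HL"

    def pair_category(self, a: str, b: str) -> PairCategory:
        """Category of the unordered residue pair ``{a, b}``."""
        if a == b:
            return PairCategory.HOMO
        sa, sb = self.side(a), self.side(b)
        if sa != sb:
            return PairCategory.HB_HL
        return PairCategory.HB_HB if sa == "HB" else PairCategory.HL_HL

    def is_conservative(self, a: str, b: str) -> bool:
        """True when the hetero-pair {a, b} stays within one side."""
        return self.pair_category(a, b) in CONSERVATIVE_CATEGORIES

    #: class names exposed for class-specific diversity (CD)
    CD_CLASSES = ("acidic", "basic", "non_polar", "hydrophobic", "hydrophilic")

    def members(self, class_name: str) -> frozenset[str]:
        """Residue set of a named class (any of the scheme's fields)."""
        return getattr(self, class_name)


def default_scheme() -> ClassScheme:
    """The default hydropathy-based partition.

    HB = {A, V, L, I, P, F, M, W, C}; HL = {G, S, T, Y, N, Q, D, E, K,
    R, H}; acidic = {D, E}; basic = {K, R, H}; polar-uncharged = {G, S,
    T, Y, N, Q}; non-polar = HB ∪ {G}.  Histidine is counted basic
    (hence hydrophilic); glycine is hydrophilic but also non-polar.
    """
    hb = frozenset("AVLIPFMWC")
    return ClassScheme(
        hydrophobic=hb,
        hydrophilic=frozenset("GSTYNQDEKRH"),
        acidic=frozenset("DE"),
        basic=frozenset("KRH"),
        polar_uncharged=frozenset("GSTYNQ"),
        ser_thr=frozenset("ST"),
        non_polar=hb | frozenset("G"),
    )


def pair_category(a: str, b: str, scheme: ClassScheme) -> PairCategory:
    """Functional alias for :meth:`ClassScheme.pair_category`."""
    return scheme.pair_category(a, b)


def enumerate_pair_types(
    scheme: ClassScheme,
) -> list[tuple[tuple[str, str], PairCategory]]:
    """All 210 unordered residue-pair types with their categories.

    20 homo-pairs plus 190 hetero-pairs (36 HB-HB, 55 HL-HL, 99 HB-HL),
    in alphabetical order of the pair.
    """
    out: list[tuple[tuple[str, str], PairCategory]] = [
        ((aa, aa), PairCategory.HOMO) for aa in RESIDUES
    ]
    for a, b in combinations(RESIDUES, 2):
        out.append(((a, b), scheme.pair_category(a, b)))
    return out


def load_scheme(path: str | Path) -> ClassScheme:
    """Read a scheme override from a simple config file.

    Each non-comment line is ``class_name = RESIDUESTRING`` (e.g.
    ``hydrophobic = AVLIPFMWC``).  All seven classes must be given; the
    result is validated against the partition invariants.
    """
    fields: dict[str, frozenset[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InvalidSchemeError(f"cannot parse scheme line: {raw!r}")
        key, val = (part.strip() for part in line.split("=", 1))
        fields[key] = frozenset(val.upper())
    expected = {
        "hydrophobic", "hydrophilic", "acidic", "basic",
        "polar_uncharged", "ser_thr", "non_polar",
    }
    missing = expected - fields.keys()
    if missing:
        raise InvalidSchemeError(f"scheme file missing classes: {sorted(missing)}")
    extra = fields.keys() - expected
    if extra:
        raise InvalidSchemeError(f"unknown scheme classes: {sorted(extra)}")
    return ClassScheme(**fields)
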