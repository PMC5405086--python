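"""Published reference values for eight orthologous protein families.

Literature-tabulated block parameters for eight families spanning a
wide range of divergence rates (percent change per 100 Myr), from
ubiquitin (0.1) to kappa-casein (33).  The underlying alignments are
not redistributed here; these printed constants serve as consistency
oracles — notably for the R↔CD identity and for the R-vs-divergence-rate
correlation.

The kappa-casein row is known to be internally inconsistent (its
printed R cannot be recovered from its printed class diversities); see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FamilyRecord:
    """One published family row: rates in %/100 Myr, shares in percent."""

    name: str
    divergence_rate: float
    R: float
    E: float
    cd_hb: float
    cd_hl: float


FAMILIES: tuple[FamilyRecord, ...] = (
    FamilyRecord("Ubiquitin", 0.1, 42, 42, 50.7, 78.6),
    FamilyRecord("G3PDH", 2.2, 53, 46, 69.8, 64.9),
    FamilyRecord("LDH", 3.4, 55, 56, 69.4, 66.1),
    FamilyRecord("Acid-protease", 9, 62, 52, 68.6, 69.6),
    FamilyRecord("Hemoglobin", 12, 63, 52, 81.5, 56.9),
    FamilyRecord("Ribonucleases", 21, 67, 57, 58.2, 81.8),
    FamilyRecord("Somatotropin", 25, 76, 44, 62.8, 80.4),
    FamilyRecord("Kappa-casein", 33, 92, 32, 80.6, 48.8),
)

#: Families whose printed R is recoverable from printed CD values
#: within ±1 (kappa-casein is not; see module docstring).
IDENTITY_CONSISTENT = tuple(
    f.name for f in FAMILIES if f.name != "Kappa-casein"
)


def family(name: str) -> FamilyRecord:
    for rec in FAMILIES:
        if rec.name == name:
            return rec
    raise KeyError(name)
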