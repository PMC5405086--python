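"""Hetero-pair frequency vs observed-probability table.

Each observed hetero-pair type gets a probability equal to its share
of the total hetero count; types are then binned on equal-width
probability intervals.  In diverged families the low-probability bins
are crowded and non-selective while the top bin typically holds only
the dominant pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .counting import PairCounts, hetero_frequencies
from .errors import NoHeteroPairsError


@dataclass(frozen=True)
class ProbabilityBin:
    lo: float
    hi: float
    closed_right: bool  # last bin includes its upper edge
    n_types: int
    total_count: int


@dataclass(frozen=True)
class ProbabilityTable:
    """Observed hetero-pair types with probabilities, plus their binning.

    ``entries`` lists (pair label, count, probability) for every pair
    type with count > 0, alphabetical by label; probabilities sum to 1.
    ``bins`` are ``n_bins`` equal-width intervals on [0, max
    probability], half-open except the last.
    """

    entries: tuple[tuple[str, int, float], ...]
    bins: tuple[ProbabilityBin, ...]


def probability_table(pc: PairCounts, n_bins: int = 10) -> ProbabilityTable:
    """Build the frequency-vs-probability table of a block's hetero-pairs."""
    if pc.hetero_total == 0:
        raise NoHeteroPairsError("block has no hetero-pairs")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    freqs, total = hetero_frequencies(pc)
    entries = tuple(
        (label, count, count / total)
        for label, count in sorted(freqs.items())
        if count > 0
    )
    p_max = max(p for _, _, p in entries)
    width = p_max / n_bins
    bins = []
    for k in range(n_bins):
        lo, hi = k * width, (k + 1) * width
        last = k == n_bins - 1
        members = [
            (c, p) for _, c, p in entries
            if lo <= p < hi or (last and p == hi)
        ]
        bins.append(
            ProbabilityBin(
                lo=lo,
                hi=hi,
                closed_right=last,
                n_types=len(members),
                total_count=sum(c for c, _ in members),
            )
        )
    return ProbabilityTable(entries=entries, bins=tuple(bins))
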