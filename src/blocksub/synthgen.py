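"""Synthetic block generator with controlled substitution structure.

Blocks are simulated on a star phylogeny: one uniform-random ancestral
sequence, from which every sequence of the block derives independently.
Each non-locked position of each sequence mutates with probability
``p_sub``; a mutation is cross-class (hydrophobic ↔ hydrophilic) with
probability ``p_cross``, otherwise it draws a *different* residue of
the same class.  ``p_cross`` therefore dials the non-conservative to
conservative substitution ratio R directly, and ``invariant_fraction``
locks a chosen share of columns to the ancestral residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .block import Block, RESIDUES
from .classes import ClassScheme, default_scheme
from .errors import DegenerateSpecError


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic block.

    All probabilities in [0, 1]; ``width ≥ 1``, ``depth ≥ 2``.
    """

    width: int
    depth: int
    p_sub: float = 0.2
    p_cross: float = 0.25
    invariant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2 or self.width < 1:
            raise DegenerateSpecError(
                f"need width >= 1 and depth >= 2, got "
                f"{self.width}x{self.depth}"
            )
        for name in ("p_sub", "p_cross", "invariant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DegenerateSpecError(f"{name}={v} outside [0, 1]")


def generate_block(spec: SynthSpec, scheme: ClassScheme | None = None) -> Block:
    """Simulate a block; identical spec (incl. seed) → identical block."""
    scheme = scheme or default_scheme()
    rng = np.random.default_rng(spec.seed)
    hb = sorted(scheme.hydrophobic)
    hl = sorted(scheme.hydrophilic)
    same_class = {aa: hb if aa in scheme.hydrophobic else hl for aa in RESIDUES}
    other_class = {aa: hl if aa in scheme.hydrophobic else hb for aa in RESIDUES}

    ancestor = [RESIDUES[i] for i in rng.integers(0, 20, size=spec.width)]
    n_locked = int(round(spec.invariant_fraction * spec.width))
    locked = set(
        rng.choice(spec.width, size=n_locked, replace=False).tolist()
    )

    seqs = []
    for _ in range(spec.depth):
        residues = list(ancestor)
        for j in range(spec.width):
            if j in locked:
                continue
            if rng.random() >= spec.p_sub:
                continue
            old = residues[j]
            if rng.random() < spec.p_cross:
                pool = other_class[old]
                residues[j] = pool[rng.integers(0, len(pool))]
            else:
                pool = [aa for aa in same_class[old] if aa != old]
                residues[j] = pool[rng.integers(0, len(pool))]
        seqs.append("".join(residues))

    ids = tuple(f"synth_{i + 1:03d}" for i in range(spec.depth))
    return Block(ids=ids, sequences=tuple(seqs))
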