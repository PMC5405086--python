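import numpy as np
import pytest

from blocksub import Block, default_scheme
from blocksub.block import RESIDUES


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture
def tiny_block():
    """3 sequences, 1 column: A/A/V — every pair enumerable by hand."""
    return Block(ids=("s1", "s2", "s3"), sequences=("A", "A", "V"))


@pytest.fixture
def invariant_block():
    """All sequences identical: no hetero-pairs, all columns invariant."""
    return Block(ids=("a", "b", "c"), sequences=("ACDE",) * 3)


def make_random_block(seed: int, depth: int, width: int) -> Block:
    """Uniform-random block, deterministic in seed."""
    rng = np.random.default_rng(seed)
    seqs = tuple(
        "".join(RESIDUES[i] for i in rng.integers(0, 20, size=width))
        for _ in range(depth)
    )
    return Block(
        ids=tuple(f"r{k}" for k in range(depth)), sequences=seqs
    )


@pytest.fixture
def random_block():
    return make_random_block(seed=42, depth=6, width=20)
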