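"""Block-level parameters: E, R, D, RD/MDR, CD and their identities."""

from itertools import combinations

import pytest
from hypothesis import given, settings, strategies as st

from blocksub import (
    Block,
    class_diversity,
    compute_E,
    compute_R,
    count_pairs,
    dominant_pair,
    r_from_class_diversity,
    residue_diversity,
    summarize,
)
from blocksub.block import RESIDUES
from blocksub.errors import (
    NoConservativeSubstitutionsError,
    NoHeteroPairsError,
)
from blocksub.reference import FAMILIES, IDENTITY_CONSISTENT, family
from tests.conftest import make_random_block
from tests.test_counting import blocks


def block_with_hetero_types(n_types: int) -> Block:
    """Depth-2 block whose columns realise exactly n distinct hetero types."""
    pairs = list(combinations(RESIDUES, 2))[:n_types]
    return Block(
        ids=("top", "bottom"),
        sequences=(
            "".join(a for a, _ in pairs),
            "".join(b for _, b in pairs),
        ),
    )


class TestComputeE:
    def test_invariant_block_zero(self, invariant_block):
        assert compute_E(count_pairs(invariant_block)) == 0.0

    def test_full_usage_hundred(self):
        block = block_with_hetero_types(190)
        assert compute_E(count_pairs(block)) == 100.0

    def test_eighty_types_gives_42_1(self):
        """100 × 80/190 = 42.1 at table precision."""
        block = block_with_hetero_types(80)
        e = compute_E(count_pairs(block))
        assert e == pytest.approx(100 * 80 / 190)
        assert round(e, 1) == 42.1

    def test_monotone_in_added_types(self):
        es = [
            compute_E(count_pairs(block_with_hetero_types(n)))
            for n in (10, 40, 80, 150)
        ]
        assert es == sorted(es) and len(set(es)) == 4


class TestComputeR:
    def test_within_class_only_is_zero(self, scheme):
        block = Block(("a", "b"), ("L", "V"))  # lone hetero-pair LV
        assert compute_R(count_pairs(block), scheme) == 0.0

    def test_equal_cross_and_within_is_hundred(self, scheme):
        # column 1: L/V within-class; column 2: A/D cross-class
        block = Block(("a", "b"), ("LA", "VD"))
        assert compute_R(count_pairs(block), scheme) == 100.0

    def test_invariant_block_reports_zero_with_flag(self, scheme, invariant_block):
        pc = count_pairs(invariant_block)
        assert compute_R(pc, scheme) == 0.0
        assert summarize(pc, scheme).no_hetero

    def test_all_cross_class_raises(self, scheme):
        block = Block(("a", "b"), ("A", "D"))
        with pytest.raises(NoConservativeSubstitutionsError):
            compute_R(count_pairs(block), scheme)


class TestRFromClassDiversity:
    @pytest.mark.parametrize(
        "name,expected_r",
        [("LDH", 55), ("Ribonucleases", 67)],
    )
    def test_published_rows_recovered(self, name, expected_r):
        rec = family(name)
        assert round(r_from_class_diversity(rec.cd_hb, rec.cd_hl)) == expected_r
        assert rec.R == expected_r

    def test_identity_consistent_within_one_for_seven_families(self):
        """Published R is recoverable (±1) from CD on 7 of 8 families."""
        for rec in FAMILIES:
            recovered = r_from_class_diversity(rec.cd_hb, rec.cd_hl)
            if rec.name in IDENTITY_CONSISTENT:
                assert abs(recovered - rec.R) <= 1.0, rec.name
            else:
                assert abs(recovered - rec.R) > 1.0  # documented outlier


class TestDominantPair:
    def test_single_hetero_type_is_total_share(self, tiny_block):
        pair, pct = dominant_pair(count_pairs(tiny_block))
        assert (pair, pct) == ("AV", 100.0)

    def test_strict_argmax(self, scheme):
        # AV appears in 2 columns, LD in 1
        block = Block(("a", "b"), ("AAL", "VVD"))
        pair, pct = dominant_pair(count_pairs(block))
        assert pair == "AV"
        assert pct == pytest.approx(100 * 2 / 3)

    def test_alphabetical_tie_break(self):
        block = Block(("a", "b"), ("LA", "VD"))  # AD and LV tie at 1
        pair, _ = dominant_pair(count_pairs(block))
        assert pair == "AD"

    def test_no_hetero_raises(self, invariant_block):
        with pytest.raises(NoHeteroPairsError):
            dominant_pair(count_pairs(invariant_block))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_scan(self, seed):
        from blocksub import hetero_frequencies

        block = make_random_block(seed=seed, depth=8, width=30)
        pc = count_pairs(block)
        pair, pct = dominant_pair(pc)
        freqs, total = hetero_frequencies(pc)
        assert freqs[pair] == max(freqs.values())
        assert pct == pytest.approx(100 * freqs[pair] / total)


class TestResidueDiversity:
    def test_single_pair_both_members_100(self):
        block = Block(("a", "b", "c"), ("A", "A", "V"))
        rd, mdr, rdmin = residue_diversity(count_pairs(block))
        assert rd["A"] == 100.0 and rd["V"] == 100.0
        assert all(rd[aa] == 0.0 for aa in RESIDUES if aa not in "AV")
        assert mdr == "A"  # alphabetical tie-break between A and V
        assert rdmin == "C"  # first residue with zero involvement

    def test_sum_is_200(self, random_block):
        rd, _, _ = residue_diversity(count_pairs(random_block))
        assert sum(rd.values()) == pytest.approx(200.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_off_diagonal_row_sums(self, seed):
        import numpy as np

        block = make_random_block(seed=seed, depth=7, width=25)
        pc = count_pairs(block)
        rd, mdr, _ = residue_diversity(pc)
        off = pc.counts.copy()
        np.fill_diagonal(off, 0)
        for i, aa in enumerate(RESIDUES):
            assert rd[aa] == pytest.approx(
                100 * off[i].sum() / pc.hetero_total
            )
        assert rd[mdr] == max(rd.values())


class TestClassDiversity:
    def test_single_ed_pair(self, scheme):
        block = Block(("a", "b"), ("E", "D"))
        cd = class_diversity(count_pairs(block), scheme)
        assert cd["acidic"] == 100.0
        assert cd["hydrophilic"] == 100.0
        assert cd["hydrophobic"] == 0.0
        assert cd["basic"] == 0.0

    def test_cd_identity_reproduces_R(self, scheme):
        """100(CD_HB+CD_HL−100)/(200−CD_HB−CD_HL) == R on any block."""
        for seed in range(5):
            block = make_random_block(seed=seed, depth=6, width=30)
            pc = count_pairs(block)
            cd = class_diversity(pc, scheme)
            assert r_from_class_diversity(
                cd["hydrophobic"], cd["hydrophilic"]
            ) == pytest.approx(compute_R(pc, scheme))


class TestSummaryProperties:
    @given(blocks())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_invariants_on_arbitrary_blocks(self, scheme, block):
        """E bounds, RD conservation, CD bounds and cross-class identity."""
        pc = count_pairs(block)
        s = summarize(pc, scheme)
        assert 0.0 <= s.E <= 100.0
        if not s.no_hetero:
            assert sum(s.RD.values()) == pytest.approx(200.0)
            for v in s.CD.values():
                assert 0.0 <= v <= 100.0 + 1e-9
            cross_share = (
                s.CD["hydrophobic"] + s.CD["hydrophilic"] - 100.0
            )
            assert 0.0 - 1e-9 <= cross_share <= 100.0 + 1e-9

    def test_summary_composes_module_calls(self, scheme, random_block):
        pc = count_pairs(random_block)
        s = summarize(pc, scheme)
        assert s.E == compute_E(pc)
        assert s.R == compute_R(pc, scheme)
        assert s.D == dominant_pair(pc)
        assert s.CD == class_diversity(pc, scheme)

    def test_plugin_hook(self, scheme, random_block):
        pc = count_pairs(random_block)
        s = summarize(pc, scheme, plugins={"half_E": lambda p, _: compute_E(p) / 2})
        assert s.extras["half_E"] == pytest.approx(s.E / 2)
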