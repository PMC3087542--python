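"""Signed gene orders: breakpoints, synteny blocks, translocations."""

from __future__ import annotations

import pytest

from plastarch.architecture import detect_inverted_repeat
from plastarch.errors import DisambiguationError, UndefinedDistanceError, UnsupportedInputError
from plastarch.gene_order import (
    SignedGeneOrder,
    breakpoint_distance,
    extract_signed_order,
    inversion_candidates,
    region_translocations,
    synteny_blocks,
)
from plastarch.model import GeneFeature, PlastomeRecord
from plastarch.simulate import gen_plastome, gen_rearranged_pair


def _order(genome_id, elements, regions=None):
    return SignedGeneOrder(genome_id, elements, regions)


ABCDE = [("a", 1), ("b", 1), ("c", 1), ("d", 1), ("e", 1)]
INVERTED_BC = [("a", 1), ("c", -1), ("b", -1), ("d", 1), ("e", 1)]


class TestExtraction:
    def test_positional_order_and_strands(self):
        feats = [
            GeneFeature("a", 1, ((10, 40),), "CDS"),
            GeneFeature("b", -1, ((50, 80),), "CDS"),
            GeneFeature("c", 1, ((90, 120),), "CDS"),
        ]
        rec = PlastomeRecord("t", "A" * 200, True, feats)
        order = extract_signed_order(rec)
        assert order.elements == [("a", 1), ("b", -1), ("c", 1)]

    def test_ir_duplicate_collapsed_to_single_copy(self):
        rec, _ = gen_plastome(lsc_len=1200, ssc_len=500, ir_len=300, n_genes=8, seed=3)
        st = detect_inverted_repeat(rec, min_length=100)
        order = extract_signed_order(rec, st, collapse_ir=True)
        names = order.symbols()
        assert len(names) == len(set(names))

    def test_duplicate_symbols_rejected(self):
        feats = [
            GeneFeature("a", 1, ((10, 40),), "CDS"),
            GeneFeature("a", 1, ((50, 80),), "CDS"),
        ]
        rec = PlastomeRecord("t", "A" * 100, True, feats)
        with pytest.raises(DisambiguationError):
            extract_signed_order(rec)

    def test_rotation_gives_cyclically_equivalent_order(self):
        feats = [
            GeneFeature("a", 1, ((10, 40),), "CDS"),
            GeneFeature("b", -1, ((50, 80),), "CDS"),
            GeneFeature("c", 1, ((90, 120),), "CDS"),
        ]
        rec = PlastomeRecord("t", "A" * 200, True, feats)
        rotated = rec.rotated(60)
        a = extract_signed_order(rec)
        b = extract_signed_order(rotated)
        assert breakpoint_distance(a, b) == 0


class TestBreakpointDistance:
    def test_identical_orders_zero(self):
        assert breakpoint_distance(_order("x", ABCDE), _order("y", ABCDE)) == 0

    def test_single_inversion_breaks_two_adjacencies(self):
        assert breakpoint_distance(_order("x", ABCDE), _order("y", INVERTED_BC)) == 2

    def test_whole_circle_flip_zero(self):
        a = _order("x", ABCDE)
        assert breakpoint_distance(a, a.flipped()) == 0

    def test_symmetric_and_bounded(self):
        for seed in range(10):
            a, b, _ = gen_rearranged_pair(n_genes=20, k_reversals=2, seed=seed)
            d_ab = breakpoint_distance(a, b)
            d_ba = breakpoint_distance(b, a)
            assert d_ab == d_ba
            assert 0 <= d_ab <= 20

    def test_too_few_shared_genes(self):
        a = _order("x", [("a", 1), ("b", 1)])
        b = _order("y", [("c", 1), ("d", 1)])
        with pytest.raises(UndefinedDistanceError):
            breakpoint_distance(a, b)


class TestSyntenyBlocks:
    def test_inverted_block_identified(self):
        blocks = synteny_blocks(_order("x", ABCDE), _order("y", INVERTED_BC))
        by_orientation = {
            blk.orientation: blk.genes for blk in blocks
        }
        assert by_orientation["inverted"] == ["b", "c"]
        # on the circle the run d,e,a is one maximal co-linear block
        assert sorted(map(tuple, (b.genes for b in blocks))) == [("b", "c"), ("d", "e", "a")]
        assert inversion_candidates(blocks) == [("b", "c")]

    def test_identical_orders_single_block(self):
        blocks = synteny_blocks(_order("x", ABCDE), _order("y", ABCDE))
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert len(blocks[0].genes) == 5

    def test_blocks_tile_the_shared_circle(self):
        for seed in range(10):
            a, b, _ = gen_rearranged_pair(n_genes=30, k_reversals=3, seed=seed)
            blocks = synteny_blocks(a, b)
            assert sum(len(blk.genes) for blk in blocks) == 30

    def test_planted_reversal_endpoints_recovered(self):
        a, b, log = gen_rearranged_pair(n_genes=30, k_reversals=1, seed=4)
        (reversal,) = [r for r in log.rearrangements if r["type"] == "reversal"]
        blocks = synteny_blocks(a, b)
        inverted = [blk for blk in blocks if blk.orientation == "inverted"]
        assert len(inverted) == 1
        assert set(inverted[0].endpoints) == {
            reversal["first_gene"], reversal["last_gene"]
        }

    def test_k_planted_reversals_give_k_inverted_blocks(self):
        for seed in range(20):
            k = 1 + seed % 3
            a, b, _ = gen_rearranged_pair(n_genes=40, k_reversals=k, seed=seed)
            blocks = synteny_blocks(a, b)
            assert sum(1 for blk in blocks if blk.orientation == "inverted") == k


class TestTranslocations:
    def test_label_change_reported(self):
        a = _order("x", [("g", 1), ("h", 1)], {"g": "LSC", "h": "LSC"})
        b = _order("y", [("g", 1), ("h", 1)], {"g": "SSC", "h": "LSC"})
        assert region_translocations(a, b) == [("g", "LSC", "SSC")]

    def test_identical_maps_empty(self):
        a = _order("x", [("g", 1), ("h", 1)], {"g": "LSC", "h": "SSC"})
        assert region_translocations(a, a) == []

    def test_missing_region_map_rejected(self):
        a = _order("x", [("g", 1), ("h", 1)], {"g": "LSC", "h": "SSC"})
        b = _order("y", [("g", 1), ("h", 1)], None)
        with pytest.raises(UnsupportedInputError):
            region_translocations(a, b)

    def test_generator_translocations_recovered(self):
        a, b, log = gen_rearranged_pair(
            n_genes=30, k_reversals=0, n_translocations=2, seed=12
        )
        expected = sorted(
            (r["gene"], r["from"], r["to"])
            for r in log.rearrangements
            if r["type"] == "translocation"
        )
        assert region_translocations(a, b) == expected

    def test_ycf2_like_move_into_ir_partial(self):
        # a large gene moved so its 5' end enters the IR from the SSC side
        a = _order("huperzia", [("ycf2", 1), ("x", 1)], {"ycf2": "LSC", "x": "LSC"})
        b = _order(
            "isoetes", [("ycf2", 1), ("x", 1)], {"ycf2": "IR-partial(SSC)", "x": "LSC"}
        )
        assert region_translocations(a, b) == [("ycf2", "LSC", "IR-partial(SSC)")]
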