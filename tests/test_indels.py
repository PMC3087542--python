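"""Simple indel coding and small-parsimony character classification."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastarch.errors import ReconciliationError
from plastarch.indels import (
    brute_force_steps,
    classify_character,
    classify_matrix,
    code_indels,
    fitch_steps,
    tree_free_autapomorphy_count,
)
from plastarch.io import read_tree_newick
from plastarch.model import Alignment, BinaryMatrix
from plastarch.simulate import gen_indel_alignment
from treeshapes import enumerate_topologies, random_topology


def _aln(rows, excluded=frozenset(), partitions=None):
    return Alignment(
        taxa=list(rows),
        rows=dict(rows),
        partitions=partitions or {},
        excluded=set(excluded),
    )


class TestCoding:
    def test_single_shared_gap(self):
        aln = _aln({"A": "ATGACG", "B": "ATG---", "C": "ATGACG"})
        matrix, chars = code_indels(aln)
        # B's gap 4-6 is terminal (trailing), hence missing, not an event
        assert chars == []

    def test_single_internal_gap(self):
        aln = _aln({"A": "ATGACGT", "B": "ATG---T", "C": "ATGACGT"})
        matrix, chars = code_indels(aln)
        (char,) = chars
        assert (char.start, char.end) == (3, 6)
        assert char.state_map() == {"A": "1", "B": "0", "C": "1"}
        assert char.label == "aln_4"

    def test_nested_gaps_regression(self):
        """A strictly containing gap scores ?, as does a taxon lacking
        nucleotides across the span."""
        aln = _aln({"A": "ATGACGTT", "B": "ATG---TT", "C": "A------T"})
        matrix, chars = code_indels(aln)
        by_span = {(c.start, c.end): c.state_map() for c in chars}
        assert set(by_span) == {(3, 6), (1, 7)}
        assert by_span[(3, 6)] == {"A": "1", "B": "0", "C": "?"}
        assert by_span[(1, 7)] == {"A": "1", "B": "?", "C": "0"}

    def test_excluded_columns_yield_no_characters(self):
        aln = _aln(
            {"A": "ATGACGT", "B": "ATG---T", "C": "ATGACGT"},
            excluded={3, 4, 5},
        )
        matrix, chars = code_indels(aln)
        assert chars == [] and matrix.characters == []

    def test_terminal_gaps_are_missing(self):
        aln = _aln({"A": "--GACGT", "B": "ATGACGT", "C": "ATG--GT"})
        matrix, chars = code_indels(aln)
        (char,) = chars
        assert (char.start, char.end) == (3, 5)
        assert char.state_map()["A"] == "1"  # A's leading gap is elsewhere

    def test_gene_labels_from_partitions(self):
        aln = _aln(
            {"A": "ATGACGTT", "B": "ATGA--TT", "C": "ATGACGTT"},
            partitions={"rbcL": (0, 4), "psbA": (4, 8)},
        )
        _, chars = code_indels(aln)
        assert chars[0].label == "psbA_5"

    def test_taxon_order_insensitive(self):
        rows = {"A": "ATGACGT", "B": "ATG---T", "C": "ATGACGT"}
        m1, _ = code_indels(_aln(rows))
        m2, _ = code_indels(
            Alignment(taxa=["C", "A", "B"], rows=dict(rows))
        )
        for t in "ABC":
            assert m1.cells[t] == m2.cells[t]

    def test_gap_free_alignment_empty_matrix(self):
        matrix, chars = code_indels(_aln({"A": "ACGT", "B": "ACGT"}))
        assert matrix.characters == [] and chars == []


class TestFitch:
    def test_synapomorphy_on_quartet(self, quartet_tree):
        result = classify_character({"A": "1", "B": "1", "C": "0", "D": "0"}, quartet_tree)
        assert result.steps == 1
        assert result.category == "synapomorphic"
        assert result.clade == frozenset({"A", "B"})

    def test_autapomorphy_on_quartet(self, quartet_tree):
        result = classify_character({"A": "1", "B": "0", "C": "0", "D": "0"}, quartet_tree)
        assert result.steps == 1
        assert result.category == "autapomorphic"
        assert result.clade == frozenset({"A"})

    def test_homoplasy_on_quartet(self, quartet_tree):
        result = classify_character({"A": "1", "B": "0", "C": "1", "D": "0"}, quartet_tree)
        assert result.steps == 2
        assert result.category == "homoplastic"

    def test_invariant_character(self, quartet_tree):
        result = classify_character({"A": "1", "B": "1", "C": "1", "D": "?"}, quartet_tree)
        assert result.steps == 0 and result.category == "invariant"

    def test_missing_states_are_free(self, quartet_tree):
        result = classify_character({"A": "1", "B": "?", "C": "0", "D": "0"}, quartet_tree)
        assert result.steps == 1
        assert result.category == "autapomorphic"

    def test_polytomy_star_tree(self):
        tree = read_tree_newick("(A,B,C,D,E);")
        assert fitch_steps(tree, {"A": "1", "B": "1", "C": "0", "D": "0", "E": "0"}) == 2

    def test_exhaustive_against_bruteforce_small_trees(self):
        """Hartigan equals the exhaustive minimum on every topology and
        every binary labeling, up to 5 leaves."""
        for n in (4, 5):
            labels = [f"t{i}" for i in range(n)]
            for newick in enumerate_topologies(labels):
                tree = read_tree_newick(newick)
                for bits in itertools.product("01", repeat=n):
                    states = dict(zip(labels, bits))
                    assert fitch_steps(tree, states) == brute_force_steps(tree, states)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_random_trees_with_missing_data(self, data):
        n = data.draw(st.integers(4, 8))
        labels = [f"t{i}" for i in range(n)]
        rng = random.Random(data.draw(st.integers(0, 10_000)))
        newick = random_topology(labels, rng)
        tree = read_tree_newick(newick)
        states = {
            lab: data.draw(st.sampled_from("01?")) for lab in labels
        }
        assert fitch_steps(tree, states) == brute_force_steps(tree, states)


class TestMatrixClassification:
    def test_toy_matrix_counts(self, quartet_tree):
        matrix = BinaryMatrix(
            taxa=["A", "B", "C", "D"],
            characters=["syn_1", "aut_1", "hom_1"],
            cells={"A": "111", "B": "100", "C": "001", "D": "000"},
        )
        counts, table = classify_matrix(matrix, quartet_tree)
        assert counts["synapomorphic"] == 1
        assert counts["autapomorphic"] == 1
        assert counts["homoplastic"] == 1
        assert sum(counts.values()) == len(matrix.characters)

    def test_tree_free_autapomorphy_agrees_with_tree_based(self, quartet_tree):
        rng = random.Random(8)
        taxa = ["A", "B", "C", "D"]
        nchar = 40
        cells = {t: "".join(rng.choice("01") for _ in range(nchar)) for t in taxa}
        matrix = BinaryMatrix(
            taxa=taxa, characters=[f"c_{i}" for i in range(nchar)], cells=cells
        )
        counts, table = classify_matrix(matrix, quartet_tree)
        assert counts["autapomorphic"] == tree_free_autapomorphy_count(matrix)

    def test_label_map_hook(self, quartet_tree):
        matrix = BinaryMatrix(
            taxa=["taxon_A", "taxon_B", "taxon_C", "taxon_D"],
            characters=["c_1"],
            cells={"taxon_A": "1", "taxon_B": "1", "taxon_C": "0", "taxon_D": "0"},
        )
        label_map = {f"taxon_{x}": x for x in "ABCD"}
        counts, _ = classify_matrix(matrix, quartet_tree, label_map=label_map)
        assert counts["synapomorphic"] == 1

    def test_unmatched_taxa_listed(self, quartet_tree):
        matrix = BinaryMatrix(
            taxa=["A", "B", "X"], characters=["c_1"],
            cells={"A": "1", "B": "0", "X": "0"},
        )
        with pytest.raises(ReconciliationError, match="X"):
            classify_matrix(matrix, quartet_tree)


class TestEndToEndTruthRecovery:
    def test_planted_categories_recovered(self):
        tree = read_tree_newick("(((A,B),(C,D)),((E,F),(G,H)));")
        for seed in range(5):
            aln, log = gen_indel_alignment(
                tree, n_genes=3, events_per_branch_rate=0.4, seed=seed
            )
            matrix, chars = code_indels(aln)
            assert len(chars) == len(log.indel_events)
            counts, table = classify_matrix(matrix, tree)
            assert counts["homoplastic"] == 0
            truth = {e["label"]: e["true_category"] for e in log.indel_events}
            for label, cls in table:
                assert cls.category == truth[label]
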