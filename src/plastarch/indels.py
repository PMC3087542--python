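"""Binary indel coding and tree-based character classification.

Gap events in per-gene alignments are scored with simple indel coding:
every distinct gap span (identical start and end columns) observed in at
least one taxon defines one presence/absence character. A taxon scores 0
when it carries exactly that gap, 1 when it has nucleotides at every
column of the span, and ? otherwise (in particular when its own gap
strictly contains the span, or the span falls in a terminal-gap region).

Each character is then mapped onto a reference tree with small parsimony
(Hartigan's generalization of Fitch, so polytomies are handled): one step
on a pendant edge is an autapomorphy, one step on an internal edge a
synapomorphy, two or more steps homoplasy. Missing states (?) are free:
they take whichever state minimizes the step count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy

from .errors import ReconciliationError
from .model import Alignment, BinaryMatrix

CATEGORY_INVARIANT = "invariant"
CATEGORY_AUTAPOMORPHIC = "autapomorphic"
CATEGORY_SYNAPOMORPHIC = "synapomorphic"
CATEGORY_HOMOPLASTIC = "homoplastic"

_GAP = "-"
_MISSING = "?"


@dataclass(frozen=True)
class IndelCharacter:
    """One coded gap span: columns [start, end) of the alignment."""

    gene: str
    start: int
    end: int
    states: tuple[tuple[str, str], ...]  # (taxon, state) pairs
    label: str

    def state_map(self) -> dict[str, str]:
        return dict(self.states)


@dataclass(frozen=True)
class CharacterClassification:
    steps: int
    category: str
    clade: frozenset[str] | None = None


# ---------------------------------------------------------------------------
# Coding


def _terminal_mask(row: str) -> tuple[int, int]:
    """(head, tail): lengths of leading/trailing gap runs (missing data)."""
    head = len(row) - len(row.lstrip(_GAP))
    tail = len(row) - len(row.rstrip(_GAP))
    if head == len(row):
        return head, 0
    return head, tail


def _gap_runs(row: str, head: int, tail: int) -> list[tuple[int, int]]:
    runs = []
    i = head
    limit = len(row) - tail
    while i < limit:
        if row[i] == _GAP:
            j = i
            while j < limit and row[j] == _GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def code_indels(alignment: Alignment) -> tuple[BinaryMatrix, list[IndelCharacter]]:
    """Simple indel coding of an alignment into a binary matrix.

    Spans overlapping the alignment's excluded columns yield no characters;
    leading/trailing terminal gaps are treated as missing data, not events.
    Characters with no 0 or no 1 among non-missing states are dropped.
    """
    masks = {t: _terminal_mask(alignment.rows[t]) for t in alignment.taxa}
    runs = {
        t: _gap_runs(alignment.rows[t], *masks[t]) for t in alignment.taxa
    }
    spans = sorted({span for taxon_runs in runs.values() for span in taxon_runs})
    characters: list[IndelCharacter] = []
    labels_seen: set[str] = set()
    for s, e in spans:
        if any(c in alignment.excluded for c in range(s, e)):
            continue
        states: list[tuple[str, str]] = []
        for t in alignment.taxa:
            row = alignment.rows[t]
            head, tail = masks[t]
            if s < head or e > len(row) - tail:
                state = _MISSING
            elif (s, e) in runs[t]:
                state = "0"
            elif all(row[c] not in (_GAP, _MISSING) for c in range(s, e)):
                state = "1"
            else:
                state = _MISSING
            states.append((t, state))
        observed = {st for _, st in states if st != _MISSING}
        if observed != {"0", "1"}:
            continue
        gene = alignment.gene_of_column(s) or "aln"
        label = f"{gene}_{s + 1}"
        if label in labels_seen:
            label = f"{gene}_{s + 1}_{e}"
        labels_seen.add(label)
        characters.append(IndelCharacter(gene, s, e, tuple(states), label))
    matrix = BinaryMatrix(
        taxa=list(alignment.taxa),
        characters=[c.label for c in characters],
        cells={
            t: "".join(c.state_map()[t] for c in characters) for t in alignment.taxa
        },
    )
    return matrix, characters


# ---------------------------------------------------------------------------
# Small parsimony


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def fitch_steps(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Minimum number of binary state changes on the tree (Hartigan).

    Leaves absent from ``states`` or marked ? are free to take either state.
    """
    steps = 0
    sets: dict[int, set[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            s = states.get(node.taxon.label, _MISSING)
            sets[id(node)] = {0, 1} if s == _MISSING else {int(s)}
        else:
            votes = {0: 0, 1: 0}
            children = node.child_nodes()
            for child in children:
                for st in sets[id(child)]:
                    votes[st] += 1
            best = max(votes.values())
            sets[id(node)] = {s for s in (0, 1) if votes[s] == best}
            steps += len(children) - best
    return steps


def brute_force_steps(tree: dendropy.Tree, states: Mapping[str, str]) -> int:
    """Exhaustive oracle: minimize changes over all internal labelings."""
    from itertools import product

    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    leaves = [n for n in tree.leaf_node_iter()]
    best = None
    leaf_choices = []
    for leaf in leaves:
        s = states.get(leaf.taxon.label, _MISSING)
        leaf_choices.append((0, 1) if s == _MISSING else (int(s),))
    for internal_assign in product((0, 1), repeat=len(internals)):
        assign = {id(n): v for n, v in zip(internals, internal_assign)}
        for leaf_assign in product(*leaf_choices):
            for leaf, v in zip(leaves, leaf_assign):
                assign[id(leaf)] = v
            changes = 0
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    if assign[id(node)] != assign[id(child)]:
                        changes += 1
            if best is None or changes < best:
                best = changes
    return best or 0


def _separating_splits(
    tree: dendropy.Tree, ones: set[str], zeros: set[str]
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Edges whose leaf bipartition puts all 1-leaves on one side and all
    0-leaves on the other (missing leaves unconstrained). Returned as
    (below, other) label sets, deduplicated by split.
    """
    all_leaves = set(_leaf_labels(tree))
    seen: set[frozenset[frozenset[str]]] = set()
    out = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        other = frozenset(all_leaves - below)
        if not other:
            continue
        key = frozenset((below, other))
        if key in seen:
            continue
        seen.add(key)
        if (ones <= below and not zeros & below) or (
            zeros <= below and not ones & below
        ):
            out.append((below, other))
    return out


def classify_character(
    states: Mapping[str, str], tree: dendropy.Tree
) -> CharacterClassification:
    """Classify a binary character against a reference tree.

    One parsimony step on a pendant edge is autapomorphic, on an internal
    edge synapomorphic; two or more steps homoplastic; a character whose
    non-missing states are all identical is invariant. For single-step
    characters the change edge's smaller leaf set is reported (ties broken
    toward the side carrying state 1, then lexicographically).
    """
    non_missing = {t: s for t, s in states.items() if s != _MISSING}
    tree_leaves = set(_leaf_labels(tree))
    unknown = set(non_missing) - tree_leaves
    if unknown:
        raise ReconciliationError(f"taxa absent from tree: {sorted(unknown)}")
    observed = set(non_missing.values())
    if len(observed) < 2:
        return CharacterClassification(steps=0, category=CATEGORY_INVARIANT)
    steps = fitch_steps(tree, states)
    if steps >= 2:
        return CharacterClassification(steps=steps, category=CATEGORY_HOMOPLASTIC)
    ones = {t for t, s in non_missing.items() if s == "1"}
    zeros = {t for t, s in non_missing.items() if s == "0"}
    splits = _separating_splits(tree, ones, zeros)

    def reported_side(split: tuple[frozenset[str], frozenset[str]]) -> frozenset[str]:
        below, other = split
        if len(below) != len(other):
            return min(below, other, key=len)
        return below if below & ones else other

    sides = [reported_side(sp) for sp in splits]
    clade = min(sides, key=lambda s: (len(s), tuple(sorted(s))))
    chosen = splits[sides.index(clade)]
    pendant = min(len(chosen[0]), len(chosen[1])) == 1
    category = CATEGORY_AUTAPOMORPHIC if pendant else CATEGORY_SYNAPOMORPHIC
    return CharacterClassification(steps=1, category=category, clade=clade)


# ---------------------------------------------------------------------------
# Matrix-level classification


def tree_free_autapomorphy_count(matrix: BinaryMatrix) -> int:
    """Characters whose minority state occurs in exactly one taxon."""
    count = 0
    for i in range(len(matrix.characters)):
        col = [s for s in matrix.column(i).values() if s != _MISSING]
        n0, n1 = col.count("0"), col.count("1")
        if min(n0, n1) == 1:
            count += 1
    return count


def classify_matrix(
    matrix: BinaryMatrix,
    tree: dendropy.Tree,
    label_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, int], list[tuple[str, CharacterClassification]]]:
    """Classify every character of a matrix; return counts and a table.

    ``label_map`` maps matrix taxon labels onto tree leaf labels (the hook
    for reconciling spellings between data files). Unmatched non-missing
    taxa raise :class:`ReconciliationError` listing the offenders.
    """
    label_map = dict(label_map or {})
    tree_leaves = set(_leaf_labels(tree))
    mapped = {t: label_map.get(t, t) for t in matrix.taxa}
    unmatched = sorted(t for t, m in mapped.items() if m not in tree_leaves)
    if unmatched:
        raise ReconciliationError(f"matrix taxa not found in tree: {unmatched}")
    counts = {
        CATEGORY_INVARIANT: 0,
        CATEGORY_AUTAPOMORPHIC: 0,
        CATEGORY_SYNAPOMORPHIC: 0,
        CATEGORY_HOMOPLASTIC: 0,
    }
    table: list[tuple[str, CharacterClassification]] = []
    for i, label in enumerate(matrix.characters):
        states = {mapped[t]: s for t, s in matrix.column(i).items()}
        result = classify_character(states, tree)
        counts[result.category] += 1
        table.append((label, result))
    return counts, table
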