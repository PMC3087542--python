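"""Signed circular gene orders and their comparison.

A genome's gene order is the circular sequence of oriented gene symbols.
Comparisons work on the genes shared by both genomes: breakpoint counts
(signed adjacencies of one order missing from the other), maximal oriented
synteny blocks (inverted blocks are inversion candidates, reported with
their endpoint genes), and between-region translocations read off the two
region maps. Inverted blocks are descriptive candidates; no minimal
reversal scenario is reconstructed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .architecture import QuadripartiteStructure, classify_gene_regions
from .errors import DisambiguationError, UndefinedDistanceError, UnsupportedInputError
from .model import PlastomeRecord

logger = logging.getLogger(__name__)

SignedGene = tuple[str, int]


@dataclass
class SignedGeneOrder:
    """Circular ordered list of (gene symbol, orientation) pairs."""

    genome_id: str
    elements: list[SignedGene]
    regions: dict[str, str] | None = None
    ir_collapsed: bool = False

    def symbols(self) -> list[str]:
        return [g for g, _ in self.elements]

    def restricted(self, keep: set[str]) -> "SignedGeneOrder":
        return SignedGeneOrder(
            self.genome_id,
            [(g, s) for g, s in self.elements if g in keep],
            self.regions,
            self.ir_collapsed,
        )

    def flipped(self) -> "SignedGeneOrder":
        """Whole-molecule strand flip: reverse order, negate orientations."""
        return SignedGeneOrder(
            self.genome_id,
            [(g, -s) for g, s in reversed(self.elements)],
            self.regions,
            self.ir_collapsed,
        )


@dataclass
class SyntenyBlock:
    """A maximal run of shared genes co-linear in both genomes."""

    genes: list[str]
    orientation: str  # "same" | "inverted"
    endpoints: tuple[str, str] = field(default=("", ""))

    def __post_init__(self) -> None:
        if not self.endpoints[0]:
            self.endpoints = (self.genes[0], self.genes[-1])


def extract_signed_order(
    record: PlastomeRecord,
    structure: QuadripartiteStructure | None = None,
    collapse_ir: bool = True,
    include_trnas: bool = True,
) -> SignedGeneOrder:
    """Genes of a record in circular positional order with orientations.

    With ``collapse_ir`` and a detected structure, only the IRA copy of each
    fully-IR duplicated gene is retained. Remaining duplicate symbols make a
    signed order ill-defined and raise :class:`DisambiguationError`.
    """
    feats = list(record.features)
    if not include_trnas:
        feats = [f for f in feats if f.kind != "tRNA"]
    regions: dict[str, str] | None = None
    if structure is not None:
        assignment = classify_gene_regions(record, structure)
        regions = {}
        if collapse_ir:
            n = len(record.sequence)
            ira_s, ira_e = structure.ira
            kept = []
            for f in feats:
                idx = record.features.index(f)
                label = assignment.regions[idx]
                if label == "IR" and not _within(f, ira_s, ira_e, n):
                    continue  # drop the IRB copy
                kept.append(f)
            feats = kept
        for f in feats:
            regions[f.name] = assignment.regions[record.features.index(f)]
    feats.sort(key=lambda f: f.intervals[0][0])
    elements = [(f.name, f.strand) for f in feats]
    names = [g for g, _ in elements]
    dupes = sorted({g for g in names if names.count(g) > 1})
    if dupes:
        raise DisambiguationError(f"duplicate gene symbols in order: {dupes}")
    return SignedGeneOrder(
        genome_id=record.identifier,
        elements=elements,
        regions=regions,
        ir_collapsed=collapse_ir and structure is not None,
    )


def _within(feat, start: int, end: int, n: int) -> bool:
    segs = [(start, min(end, n))] + ([(0, end - n)] if end > n else [])
    return all(
        any(gs <= s and e <= ge for gs, ge in segs) for s, e in feat.intervals
    )


def _shared(a: SignedGeneOrder, b: SignedGeneOrder) -> tuple[SignedGeneOrder, SignedGeneOrder]:
    sa, sb = set(a.symbols()), set(b.symbols())
    shared = sa & sb
    dropped = (sa | sb) - shared
    if dropped:
        logger.info("restricting to %d shared genes; dropped %s", len(shared), sorted(dropped))
    if len(shared) < 2:
        raise UndefinedDistanceError("fewer than 2 shared genes")
    return a.restricted(shared), b.restricted(shared)


def _adjacencies(order: SignedGeneOrder) -> list[tuple[SignedGene, SignedGene]]:
    els = order.elements
    return [(els[i], els[(i + 1) % len(els)]) for i in range(len(els))]


def breakpoint_distance(a: SignedGeneOrder, b: SignedGeneOrder) -> int:
    """Signed adjacencies of ``a`` absent from ``b`` (shared genes only).

    The adjacency (x -> y) matches (x -> y) or its mirror (-y -> -x), so
    the distance is 0 exactly when the orders agree up to rotation and
    whole-circle flip, and it is symmetric.
    """
    ra, rb = _shared(a, b)
    b_adj: set[tuple[SignedGene, SignedGene]] = set()
    for (x, sx), (y, sy) in _adjacencies(rb):
        b_adj.add(((x, sx), (y, sy)))
        b_adj.add(((y, -sy), (x, -sx)))
    return sum(1 for adj in _adjacencies(ra) if adj not in b_adj)


def synteny_blocks(a: SignedGeneOrder, b: SignedGeneOrder) -> list[SyntenyBlock]:
    """Maximal co-linear runs of shared genes, labeled same or inverted.

    Inverted blocks are inversion candidates ("inversion involving X to Y").
    Blocks partition the shared-gene circle.
    """
    ra, rb = _shared(a, b)
    els = ra.elements
    n = len(els)
    pos_b = {g: i for i, (g, _) in enumerate(rb.elements)}
    sign_b = {g: s for g, s in rb.elements}
    sign_a = {g: s for g, s in els}

    def edge_type(x: str, y: str) -> str | None:
        if (
            pos_b[y] == (pos_b[x] + 1) % n
            and sign_b[x] == sign_a[x]
            and sign_b[y] == sign_a[y]
        ):
            return "same"
        if (
            pos_b[y] == (pos_b[x] - 1) % n
            and sign_b[x] == -sign_a[x]
            and sign_b[y] == -sign_a[y]
        ):
            return "inverted"
        return None

    edges = [edge_type(els[i][0], els[(i + 1) % n][0]) for i in range(n)]
    if all(e is not None for e in edges) and len(set(edges)) == 1:
        return [SyntenyBlock(genes=[g for g, _ in els], orientation=edges[0])]
    # open the circle at a breakpoint
    start = next(i for i, e in enumerate(edges) if e is None) + 1
    blocks: list[SyntenyBlock] = []
    current = [els[start % n][0]]
    for k in range(n):
        i = (start + k) % n
        e = edges[i]
        nxt = els[(i + 1) % n][0]
        if e is None or k == n - 1:
            genes = current
            if len(genes) == 1:
                g = genes[0]
                orientation = "same" if sign_b[g] == sign_a[g] else "inverted"
            else:
                orientation = next(
                    edge_type(genes[t], genes[t + 1]) for t in range(len(genes) - 1)
                )
            blocks.append(SyntenyBlock(genes=genes, orientation=orientation))
            if k != n - 1:
                current = [nxt]
        else:
            current.append(nxt)
    return blocks


def inversion_candidates(blocks: list[SyntenyBlock]) -> list[tuple[str, str]]:
    """Endpoint genes of every inverted block ("inversion involving X to Y")."""
    return [blk.endpoints for blk in blocks if blk.orientation == "inverted"]


def region_translocations(
    a: SignedGeneOrder, b: SignedGeneOrder
) -> list[tuple[str, str, str]]:
    """Shared genes whose region label differs between the two genomes."""
    if a.regions is None or b.regions is None:
        raise UnsupportedInputError("both orders need region maps")
    shared = set(a.symbols()) & set(b.symbols())
    out = []
    for g in sorted(shared):
        ra, rb = a.regions.get(g), b.regions.get(g)
        if ra is not None and rb is not None and ra != rb:
            out.append((g, ra, rb))
    return out
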