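"""Ground-truthed synthetic plastome data.

Every generator takes an explicit integer seed (Python's Mersenne-Twister
``random.Random``; no global RNG state) and returns its output together
with a :class:`TruthLog` recording exactly what was planted, so each
analysis stage can be scored against known truth. Outputs are
byte-identical across runs for identical (parameters, seed).

The quadripartite generator plants an exact inverted-repeat pair in a
circular genome whose flanks are kept repeat-free by rejection sampling
(no incidental inverted repeat of 50 bp or more, and the planted pair is
not extendable at any junction), so the detector's maximal exact pair is
the planted one by construction.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field

import dendropy

from .architecture import _pairs_of_length
from .codon import codon_families
from .errors import CapacityError
from .gene_order import SignedGeneOrder
from .model import Alignment, GeneFeature, Interval, PlastomeRecord, revcomp

INCIDENTAL_IR_THRESHOLD = 50  # bp; smallest repeat the rejection step forbids


@dataclass
class TruthLog:
    """What a generator planted, sufficient to score the analysis exactly."""

    generator: str
    seed: int
    params: dict = field(default_factory=dict)
    ir_intervals: tuple[Interval, Interval] | None = None
    region_intervals: dict[str, Interval] = field(default_factory=dict)
    genes: list[dict] = field(default_factory=list)
    rearrangements: list[dict] = field(default_factory=list)
    indel_events: list[dict] = field(default_factory=list)
    codon_bias: float | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True, default=list)


# ---------------------------------------------------------------------------
# Sequence helpers


def _random_seq(rng: random.Random, length: int, gc: float) -> str:
    """Random sequence with G+C count exactly round(gc * length)."""
    n_gc = round(gc * length)
    bases = [rng.choice("GC") for _ in range(n_gc)]
    bases += [rng.choice("AT") for _ in range(length - n_gc)]
    rng.shuffle(bases)
    return "".join(bases)


_NONSTOP = None


def _nonstop_codons() -> list[str]:
    global _NONSTOP
    if _NONSTOP is None:
        fams = codon_families(1)
        _NONSTOP = sorted(c for codons in fams.values() for c in codons)
    return _NONSTOP


def _random_cds(rng: random.Random, n_codons: int, start: str = "ATG") -> str:
    """In-frame CDS: start codon, stop-free interior, one terminal stop."""
    interior = [rng.choice(_nonstop_codons()) for _ in range(n_codons - 2)]
    return start + "".join(interior) + "TAA"


def gen_codon_seq(
    n_codons: int, bias: float, code_id: int = 1, seed: int = 0
) -> str:
    """An in-frame CDS with tunable within-family codon bias.

    ``bias`` interpolates between uniform synonymous usage (0) and a single
    preferred codon per amino acid (1). The output has an ATG start, a
    stop-free interior, and a single terminal stop; its length is exactly
    3 * n_codons.
    """
    if n_codons < 3:
        raise ValueError("n_codons must be >= 3")
    if not 0.0 <= bias <= 1.0:
        raise ValueError("bias must be in [0, 1]")
    rng = random.Random(seed)
    fams = codon_families(code_id)
    amino_acids = sorted(fams)
    codons = []
    for _ in range(n_codons - 2):
        aa = rng.choice(amino_acids)
        family = sorted(fams[aa])
        if rng.random() < bias:
            codons.append(family[0])  # the deterministic preferred codon
        else:
            codons.append(rng.choice(family))
    return "ATG" + "".join(codons) + "TAA"


# ---------------------------------------------------------------------------
# Quadripartite genomes


def _incidental_pairs(seq: str, planted: tuple[Interval, Interval] | None) -> bool:
    """True if any inverted-repeat pair >= threshold exists outside the
    planted IR pair."""
    pairs = _pairs_of_length(seq, INCIDENTAL_IR_THRESHOLD)
    if planted is None:
        return bool(pairs)
    (a0, a1), (b0, b1) = planted
    L = INCIDENTAL_IR_THRESHOLD

    def inside(x: int, lo: int, hi: int) -> bool:
        return lo <= x and x + L <= hi

    for i, j in pairs:
        ok = (inside(i, a0, a1) and inside(j, b0, b1)) or (
            inside(j, a0, a1) and inside(i, b0, b1)
        )
        if not ok:
            return True
    return False


def _extendable(seq: str, ira: Interval, irb: Interval) -> bool:
    """True if the planted IR pair could be extended by one base."""
    n = len(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    before_a = seq[(ira[0] - 1) % n]
    after_b = seq[irb[1] % n]
    after_a = seq[ira[1] % n]
    before_b = seq[(irb[0] - 1) % n]
    return comp[before_a] == after_b or comp[after_a] == before_b


def gen_plastome(
    lsc_len: int = 4000,
    ssc_len: int = 1500,
    ir_len: int = 1000,
    n_genes: int = 20,
    gc_target: float = 0.35,
    seed: int = 0,
    straddle_junctions: int = 0,
    acg_start_genes: int = 0,
) -> tuple[PlastomeRecord, TruthLog]:
    """A circular genome LSC + IRA + SSC + revcomp(IRA) with planted truth.

    Genes are non-overlapping intact CDSs (ATG start, clean interior, TAA
    stop); genes fully inside IRA get an annotated mirror copy in IRB;
    ``straddle_junctions`` genes are placed across the LSC/IRA and IRA/SSC
    boundaries; ``acg_start_genes`` genes get an ACG start codon instead of
    ATG (planted RNA-editing hints). Genome-wide G/C lands within one
    point of ``gc_target`` (intergenic composition compensates for gene
    content). Rejection sampling keeps the planted IR the unique maximal
    exact inverted repeat.
    """
    if min(lsc_len, ssc_len) <= 0 or ir_len < 0:
        raise ValueError("region lengths must be positive (ir_len >= 0)")
    if lsc_len < ssc_len:
        raise ValueError("lsc_len must be >= ssc_len")
    if 0 < ir_len < INCIDENTAL_IR_THRESHOLD:
        raise ValueError(f"ir_len must be 0 or >= {INCIDENTAL_IR_THRESHOLD}")
    rng = random.Random(seed)
    total = lsc_len + ssc_len + 2 * ir_len
    ira = (lsc_len, lsc_len + ir_len)
    ssc = (lsc_len + ir_len, lsc_len + ir_len + ssc_len)
    irb = (lsc_len + ir_len + ssc_len, total)
    planted = (ira, irb) if ir_len else None

    failures = 0
    for _attempt in range(60):
        try:
            gene_plan, features = _plan_genes(
                rng, lsc_len, ssc_len, ir_len, n_genes, straddle_junctions,
                acg_start_genes,
            )
        except CapacityError:
            failures += 1
            if failures >= 10:
                raise
            continue
        seq = _assemble_sequence(rng, gene_plan, lsc_len, ssc_len, ir_len, gc_target)
        if ir_len and _extendable(seq, ira, irb):
            continue
        if _incidental_pairs(seq, planted):
            continue
        record = PlastomeRecord(
            identifier=f"synthetic-{seed}",
            sequence=seq,
            circular=True,
            features=features,
            source="synthetic",
        )
        log = TruthLog(
            generator="gen_plastome",
            seed=seed,
            params={
                "lsc_len": lsc_len,
                "ssc_len": ssc_len,
                "ir_len": ir_len,
                "n_genes": n_genes,
                "gc_target": gc_target,
                "straddle_junctions": straddle_junctions,
                "acg_start_genes": acg_start_genes,
            },
            ir_intervals=planted,
            region_intervals={"LSC": (0, lsc_len), "IRA": ira, "SSC": ssc, "IRB": irb},
            genes=gene_plan,
        )
        return record, log
    raise CapacityError("could not build a repeat-free genome; relax parameters")


def _plan_genes(
    rng: random.Random,
    lsc_len: int,
    ssc_len: int,
    ir_len: int,
    n_genes: int,
    straddle_junctions: int,
    acg_start_genes: int,
) -> tuple[list[dict], list[GeneFeature]]:
    total = lsc_len + ssc_len + 2 * ir_len
    placeable_end = lsc_len + ir_len + ssc_len  # keep IRB as a pure mirror
    plan: list[dict] = []
    occupied: list[Interval] = []

    def fits(s: int, e: int) -> bool:
        return all(e <= os or oe <= s for os, oe in occupied)

    straddle_points = []
    if ir_len:
        straddle_points = [lsc_len, lsc_len + ir_len][:straddle_junctions]
    for idx, point in enumerate(straddle_points):
        length = 3 * rng.randint(40, 60)
        s = point - length // 2
        s -= s % 3
        e = s + length
        if s < 0 or e > placeable_end or not fits(s, e):
            raise CapacityError("cannot place junction-straddling gene")
        occupied.append((s, e))
        plan.append(
            {"name": f"jnc{idx + 1}", "start": s, "end": e, "strand": 1, "acg": False}
        )
    # cap gene length so the requested count has room to pack
    max_codons = max(31, min(80, placeable_end // (4 * max(n_genes, 1) * 3)))
    placed = 0
    attempts = 0
    while placed < n_genes:
        attempts += 1
        if attempts > 200 * max(n_genes, 1):
            raise CapacityError(f"could not place {n_genes} genes without overlap")
        length = 3 * rng.randint(30, max_codons)
        s = rng.randrange(0, max(1, placeable_end - length))
        e = s + length
        if not fits(s - 2, e + 2):
            continue
        # genes must not touch region boundaries unless deliberately straddling
        boundaries = [lsc_len, lsc_len + ir_len, placeable_end]
        if any(s < b < e for b in boundaries):
            continue
        occupied.append((s, e))
        placed += 1
        plan.append(
            {
                "name": f"g{placed:03d}",
                "start": s,
                "end": e,
                "strand": rng.choice((1, -1)),
                "acg": placed <= acg_start_genes,
            }
        )
    features = []
    for g in plan:
        features.append(
            GeneFeature(
                name=g["name"],
                strand=g["strand"],
                intervals=((g["start"], g["end"]),),
                kind="CDS",
            )
        )
        # mirror annotation for genes fully inside IRA
        if ir_len and lsc_len <= g["start"] and g["end"] <= lsc_len + ir_len:
            # IRB = revcomp(IRA): position p in IRA mirrors to
            # irb_start + (ira_end - 1 - p)
            ms = lsc_len + ir_len + ssc_len + (lsc_len + ir_len - g["end"])
            me = ms + (g["end"] - g["start"])
            features.append(
                GeneFeature(
                    name=g["name"],
                    strand=-g["strand"],
                    intervals=((ms, me),),
                    kind="CDS",
                )
            )
    return plan, features


def _assemble_sequence(
    rng: random.Random,
    gene_plan: list[dict],
    lsc_len: int,
    ssc_len: int,
    ir_len: int,
    gc_target: float,
) -> str:
    total = lsc_len + ssc_len + 2 * ir_len
    core_len = lsc_len + ir_len + ssc_len
    seq = [""] * core_len
    gene_gc = 0
    for g in gene_plan:
        cds = _random_cds(
            rng, (g["end"] - g["start"]) // 3, start="ACG" if g["acg"] else "ATG"
        )
        placed = cds if g["strand"] == 1 else revcomp(cds)
        for i, ch in enumerate(placed):
            seq[g["start"] + i] = ch
        gene_gc += placed.count("G") + placed.count("C")
    free = [i for i in range(core_len) if not seq[i]]
    # intergenic composition compensates so genome-wide G/C hits the target;
    # IRB mirrors IRA (reverse complement preserves G/C), so IRA positions
    # count twice toward the genome-wide total
    weight = [2 if lsc_len <= i < lsc_len + ir_len else 1 for i in free]
    target_gc_total = round(gc_target * total)
    ira_gene_gc = sum(
        1 for i in range(lsc_len, lsc_len + ir_len) if seq[i] and seq[i] in "GC"
    )
    need = target_gc_total - gene_gc - ira_gene_gc
    capacity = sum(weight)
    need = max(0, min(need, capacity))
    # greedily assign GC to free positions until the weighted budget is met
    order = list(range(len(free)))
    rng.shuffle(order)
    assigned = 0
    for k in order:
        i = free[k]
        if assigned + weight[k] <= need:
            seq[i] = rng.choice("GC")
            assigned += weight[k]
        else:
            seq[i] = rng.choice("AT")
    core = "".join(seq)
    ira_seq = core[lsc_len : lsc_len + ir_len]
    return core + revcomp(ira_seq)


# ---------------------------------------------------------------------------
# Rearranged gene-order pairs


def gen_rearranged_pair(
    n_genes: int = 30,
    k_reversals: int = 1,
    n_translocations: int = 0,
    seed: int = 0,
) -> tuple[SignedGeneOrder, SignedGeneOrder, TruthLog]:
    """Two signed circular orders differing by planted, non-overlapping
    reversals and region relabelings (translocations)."""
    if n_genes < 4:
        raise ValueError("n_genes must be >= 4")
    rng = random.Random(seed)
    names = [f"g{i:03d}" for i in range(1, n_genes + 1)]
    signs = [rng.choice((1, -1)) for _ in range(n_genes)]
    lsc_end = max(2, int(n_genes * 0.6))
    ir_end = max(lsc_end + 1, int(n_genes * 0.75))
    regions = {}
    for i, name in enumerate(names):
        regions[name] = "LSC" if i < lsc_end else ("IR" if i < ir_end else "SSC")
    order_a = SignedGeneOrder("sim_A", list(zip(names, signs)), dict(regions))

    elements_b = list(order_a.elements)
    log = TruthLog(
        generator="gen_rearranged_pair",
        seed=seed,
        params={
            "n_genes": n_genes,
            "k_reversals": k_reversals,
            "n_translocations": n_translocations,
        },
    )
    # place non-overlapping, non-adjacent reversal segments away from index 0
    used: set[int] = set()
    for _ in range(k_reversals):
        for _try in range(500):
            length = rng.randint(1, max(1, n_genes // 4))
            start = rng.randint(1, n_genes - length - 1)
            span = set(range(start - 1, start + length + 1))
            if span & used:
                continue
            used |= set(range(start, start + length))
            segment = elements_b[start : start + length]
            elements_b[start : start + length] = [
                (g, -s) for g, s in reversed(segment)
            ]
            log.rearrangements.append(
                {
                    "type": "reversal",
                    "first_gene": segment[0][0],
                    "last_gene": segment[-1][0],
                    "positions": (start, start + length),
                }
            )
            break
        else:
            raise CapacityError("cannot place non-overlapping reversals")

    regions_b = dict(regions)
    reversal_genes = {
        g
        for r in log.rearrangements
        for g in names[r["positions"][0] : r["positions"][1]]
    }
    movable = [g for g in names if g not in reversal_genes]
    rng.shuffle(movable)
    region_cycle = {"LSC": "SSC", "SSC": "LSC", "IR": "LSC"}
    for t in range(n_translocations):
        if not movable:
            raise CapacityError("no genes left to translocate")
        gene = movable.pop()
        target = region_cycle[regions[gene]]
        regions_b[gene] = target
        log.rearrangements.append(
            {"type": "translocation", "gene": gene, "from": regions[gene], "to": target}
        )
    order_b = SignedGeneOrder("sim_B", elements_b, regions_b)
    return order_a, order_b, log


# ---------------------------------------------------------------------------
# Indel alignments on a tree


def gen_indel_alignment(
    tree: dendropy.Tree,
    n_genes: int = 3,
    events_per_branch_rate: float = 0.5,
    frame_preserving: bool = True,
    seed: int = 0,
    gene_codons: int = 60,
) -> tuple[Alignment, TruthLog]:
    """Per-gene alignments whose gaps arise from indel events on branches.

    Each non-root branch receives a Poisson(rate) number of deletion
    events; an event removes a span (length a multiple of 3 when
    ``frame_preserving``, starting on a codon boundary) from every leaf
    below the branch. Spans are globally disjoint with distinct
    boundaries, so simple indel coding recovers exactly one character per
    event, and the planted category is autapomorphic for pendant branches
    and synapomorphic for internal ones.
    """
    rng = random.Random(seed)
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    gene_len = gene_codons * 3
    ncol = n_genes * gene_len
    root_seq = "".join(
        _random_cds(rng, gene_codons) for _ in range(n_genes)
    )
    rows = {t: list(root_seq) for t in leaves}
    partitions = {
        f"gene{i + 1}": (i * gene_len, (i + 1) * gene_len) for i in range(n_genes)
    }
    log = TruthLog(
        generator="gen_indel_alignment",
        seed=seed,
        params={
            "n_genes": n_genes,
            "events_per_branch_rate": events_per_branch_rate,
            "frame_preserving": frame_preserving,
            "gene_codons": gene_codons,
            "n_leaves": len(leaves),
        },
    )
    taken: list[Interval] = []

    def disjoint(s: int, e: int) -> bool:
        return all(e < os or oe < s for os, oe in taken)  # keep a 1-col gap

    edges = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = sorted(leaf.taxon.label for leaf in node.leaf_iter())
        if len(below) == len(leaves):
            continue
        edges.append((node, below))
    for node, below in edges:
        n_events = _poisson(rng, events_per_branch_rate)
        for _ in range(n_events):
            for _try in range(300):
                gene_idx = rng.randrange(n_genes)
                gs, ge = partitions[f"gene{gene_idx + 1}"]
                if frame_preserving:
                    length = 3 * rng.randint(1, 4)
                    start = gs + 3 * rng.randint(1, gene_codons - 2 - length // 3)
                else:
                    length = rng.randint(2, 10)
                    start = rng.randint(gs + 3, ge - 3 - length)
                end = start + length
                if not disjoint(start, end):
                    continue
                taken.append((start, end))
                for t in below:
                    for c in range(start, end):
                        rows[t][c] = "-"
                pendant = len(below) == 1
                log.indel_events.append(
                    {
                        "branch_leaves": below,
                        "gene": f"gene{gene_idx + 1}",
                        "span": (start, end),
                        "length": length,
                        "true_category": "autapomorphic" if pendant else "synapomorphic",
                        "label": f"gene{gene_idx + 1}_{start + 1}",
                    }
                )
                break
            else:
                raise CapacityError("indel spans collide; lower the event rate")
    alignment = Alignment(
        taxa=list(leaves),
        rows={t: "".join(rows[t]) for t in leaves},
        partitions=partitions,
    )
    return alignment, log


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's Poisson sampler on the generator's own integer-state RNG."""
    if lam <= 0:
        return 0
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


# ---------------------------------------------------------------------------
# Flat-file output so fixtures exercise the real parsers


def write_flatfile(record: PlastomeRecord, path) -> None:
    """Write a record as a GenBank flat file (via Biopython)."""
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord

    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.identifier,
        name=record.identifier.replace("-", "_")[:16],
        description="synthetic plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for feat in record.features:
        locs = [
            SimpleLocation(s, e, strand=feat.strand) for s, e in feat.intervals
        ]
        location = locs[0] if len(locs) == 1 else CompoundLocation(locs)
        ftype = feat.kind if feat.kind in ("CDS", "tRNA", "rRNA") else "gene"
        qualifiers = {"gene": [feat.name]}
        if feat.pseudo:
            qualifiers["pseudo"] = [""]
        seqrec.features.append(
            SeqFeature(location, type=ftype, qualifiers=qualifiers)
        )
    from Bio import SeqIO

    SeqIO.write([seqrec], str(path), "genbank")
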