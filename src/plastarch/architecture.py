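"""Quadripartite plastome architecture.

Detects the inverted-repeat (IR) pair of a circular genome as the maximal
pair of disjoint intervals whose sequences are exact reverse complements,
partitions the circle into LSC / SSC / IRA / IRB, computes per-region
statistics, classifies genes by region, and diffs gene content between two
annotated genomes.

Conventions: the larger single-copy segment is the LSC; IRA is the IR copy
that immediately follows the LSC going clockwise, so the canonical
linearization reads LSC, IRA, SSC, IRB. Region intervals are reported as
``(start, end)`` with ``end`` possibly exceeding the sequence length to
denote wrapping past the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import IntegrityError, UnsupportedInputError
from .model import GeneFeature, Interval, PlastomeRecord, revcomp

REGION_LSC = "LSC"
REGION_SSC = "SSC"
REGION_IR = "IR"
REGION_IR_PARTIAL_LSC = "IR-partial(LSC)"
REGION_IR_PARTIAL_SSC = "IR-partial(SSC)"

DEFAULT_MIN_IR_LENGTH = 1000


@dataclass(frozen=True)
class QuadripartiteStructure:
    """The LSC / IRA / SSC / IRB tiling of a circular genome."""

    ira: Interval
    irb: Interval
    lsc: Interval
    ssc: Interval
    ir_length: int
    lsc_length: int
    ssc_length: int
    total_length: int

    def __post_init__(self) -> None:
        if self.lsc_length + self.ssc_length + 2 * self.ir_length != self.total_length:
            raise IntegrityError("regions do not tile the circle")
        if self.lsc_length < self.ssc_length:
            raise IntegrityError("LSC must be at least as long as SSC")

    def regions(self) -> dict[str, Interval]:
        return {"LSC": self.lsc, "IRA": self.ira, "SSC": self.ssc, "IRB": self.irb}


def region_sequence(sequence: str, interval: Interval) -> str:
    """Extract a (possibly origin-wrapping) region from a circular sequence."""
    n = len(sequence)
    s, e = interval
    if e <= n:
        return sequence[s:e]
    return sequence[s:] + sequence[: e - n]


def quadripartite_total(lsc_length: int, ssc_length: int, ir_length: int) -> int:
    """Total genome length implied by region lengths: LSC + SSC + 2*IR."""
    return lsc_length + ssc_length + 2 * ir_length


# ---------------------------------------------------------------------------
# IR detection


def _circularly_disjoint(i: int, j: int, length: int, n: int) -> bool:
    return (j - i) % n >= length and (i - j) % n >= length


def _pairs_of_length(seq: str, length: int) -> list[tuple[int, int]]:
    """All disjoint interval pairs (i, j) with circular seq[i:i+L] equal to
    the reverse complement of circular seq[j:j+L]; each unordered pair once.
    """
    n = len(seq)
    if length < 1 or 2 * length > n:
        return []
    dbl = seq + seq
    rcd = revcomp(seq) * 2
    base, mod = 1_000_003, (1 << 61) - 1

    def rolling(s: str) -> list[int]:
        h = 0
        for ch in s[:length]:
            h = (h * base + ord(ch)) % mod
        out = [h]
        pw = pow(base, length - 1, mod)
        for i in range(1, n):
            h = ((h - ord(s[i - 1]) * pw) * base + ord(s[i + length - 1])) % mod
            out.append(h)
        return out

    table: dict[int, list[int]] = {}
    for i, h in enumerate(rolling(dbl)):
        table.setdefault(h, []).append(i)
    seen: set[frozenset[int]] = set()
    pairs: list[tuple[int, int]] = []
    for jr, h in enumerate(rolling(rcd)):
        for i in table.get(h, ()):
            j = (n - jr - length) % n
            key = frozenset((i, j))
            if key in seen or len(key) == 1:
                continue
            if not _circularly_disjoint(i, j, length, n):
                continue
            if dbl[i : i + length] != rcd[jr : jr + length]:
                continue  # hash collision
            seen.add(key)
            pairs.append((i, j))
    return pairs


def _structure_from_pair(i: int, j: int, length: int, n: int) -> QuadripartiteStructure:
    gap_ij = (j - i - length) % n  # gap after copy at i, before copy at j
    gap_ji = (i - j - length) % n
    # the larger gap is the LSC; IRA is the copy that follows the LSC
    if gap_ij > gap_ji or (gap_ij == gap_ji and i > j):
        lsc_start, lsc_len = (i + length) % n, gap_ij
        ira_start, ssc_len = j, gap_ji
        irb_start = (j + length + gap_ji) % n
    else:
        lsc_start, lsc_len = (j + length) % n, gap_ji
        ira_start, ssc_len = i, gap_ij
        irb_start = (i + length + gap_ij) % n

    def unwrap(start: int, seg_len: int) -> Interval:
        return (start, start + seg_len)

    ssc_start = (ira_start + length) % n
    return QuadripartiteStructure(
        ira=unwrap(ira_start, length),
        irb=unwrap(irb_start, length),
        lsc=unwrap(lsc_start, lsc_len),
        ssc=unwrap(ssc_start, ssc_len),
        ir_length=length,
        lsc_length=lsc_len,
        ssc_length=ssc_len,
        total_length=n,
    )


def detect_inverted_repeat(
    record: PlastomeRecord, min_length: int = DEFAULT_MIN_IR_LENGTH
) -> QuadripartiteStructure | None:
    """Find the maximal exact inverted-repeat pair of a circular genome.

    Returns the quadripartite structure induced by the longest pair of
    disjoint intervals whose sequences are exact reverse complements of one
    another, or None when no pair of length >= ``min_length`` exists. Among
    equally long pairs the one whose IRA start is smallest wins.
    """
    if not record.circular:
        raise UnsupportedInputError("IR detection requires a circular record")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    seq = record.sequence
    n = len(seq)
    lo, hi = min_length, n // 2
    if lo > hi or not _pairs_of_length(seq, lo):
        return None
    # invariant: a valid pair of length `lo` exists; none of length `hi`+1
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if _pairs_of_length(seq, mid):
            lo = mid
        else:
            hi = mid - 1
    candidates = [
        _structure_from_pair(i, j, lo, n) for i, j in _pairs_of_length(seq, lo)
    ]
    return min(candidates, key=lambda st: st.ira[0])


def brute_force_ir_pair(
    seq: str, min_length: int
) -> tuple[int, int, int] | None:
    """Quadratic all-pairs oracle for small circles: (i, j, length) of the
    maximal disjoint exact reverse-complement pair, smallest-start tie-break.
    Intended for testing; O(n^2 log n).
    """
    n = len(seq)
    dbl = seq + seq
    best_hits: list[tuple[int, int]] = []
    best_len = 0
    for length in range(min_length, n // 2 + 1):
        hits = []
        for i in range(n):
            a = dbl[i : i + length]
            for j in range(n):
                if not _circularly_disjoint(i, j, length, n):
                    continue
                if revcomp(dbl[j : j + length]) == a:
                    hits.append((i, j))
        if not hits:
            break
        best_hits, best_len = hits, length
    if not best_hits:
        return None
    structs = [(_structure_from_pair(i, j, best_len, n), i, j) for i, j in best_hits]
    _st, i, j = min(structs, key=lambda t: t[0].ira[0])
    return (i, j, best_len)


# ---------------------------------------------------------------------------
# Region statistics


@dataclass(frozen=True)
class RegionReport:
    """Per-region lengths and G/C fractions of a quadripartite genome."""

    lsc_length: int
    ssc_length: int
    ir_length: int
    total_length: int
    gc_lsc: float
    gc_ssc: float
    gc_ir: float
    gc_total: float


def _gc_fraction(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / acgt


def region_stats(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> RegionReport:
    """Lengths and G/C per region; N is excluded from G/C denominators."""
    if structure.total_length != len(record.sequence):
        raise IntegrityError("structure does not match record length")
    seq = record.sequence
    lsc = region_sequence(seq, structure.lsc)
    ssc = region_sequence(seq, structure.ssc)
    ira = region_sequence(seq, structure.ira)
    return RegionReport(
        lsc_length=structure.lsc_length,
        ssc_length=structure.ssc_length,
        ir_length=structure.ir_length,
        total_length=quadripartite_total(
            structure.lsc_length, structure.ssc_length, structure.ir_length
        ),
        gc_lsc=_gc_fraction(lsc),
        gc_ssc=_gc_fraction(ssc),
        gc_ir=_gc_fraction(ira),
        gc_total=_gc_fraction(seq),
    )


# ---------------------------------------------------------------------------
# Gene-region classification


@dataclass
class GeneRegionAssignment:
    """Per-feature region labels, copy counts, and junction gene lists."""

    regions: dict[int, str]  # feature index -> region label
    copy_counts: dict[str, int]  # gene symbol -> copies fully in IR
    junctions: dict[str, list[tuple[str, bool]]] = field(default_factory=dict)

    def label(self, record: PlastomeRecord, feature: GeneFeature) -> str:
        return self.regions[record.features.index(feature)]


def _overlap_bp(intervals: tuple[Interval, ...], region: Interval, n: int) -> int:
    """Overlap in bp between feature intervals and a circular region."""
    rs, re_ = region
    segments = [(rs, min(re_, n))] + ([(0, re_ - n)] if re_ > n else [])
    total = 0
    for fs, fe in intervals:
        for gs, ge in segments:
            total += max(0, min(fe, ge) - max(fs, gs))
    return total


def classify_gene_regions(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> GeneRegionAssignment:
    """Assign every feature to LSC, SSC, IR or an IR-partial class.

    A feature is IR-partial when it overlaps an IR/single-copy junction; the
    label names the single-copy side it reaches into. Copy count 2 is given
    to genes with two features fully inside the IRs. Junction gene lists
    (the four IR boundaries, in canonical LSC->IRA->SSC->IRB order) report
    the flanking gene on each side, partial overlaps flagged.
    """
    n = len(record.sequence)
    regs = structure.regions()
    labels: dict[int, str] = {}
    fully_ir: dict[str, int] = {}
    for idx, feat in enumerate(record.features):
        ov = {name: _overlap_bp(feat.intervals, iv, n) for name, iv in regs.items()}
        ir = ov["IRA"] + ov["IRB"]
        if ir == feat.length:
            labels[idx] = REGION_IR
            fully_ir[feat.name] = fully_ir.get(feat.name, 0) + 1
        elif ir > 0 and ov["LSC"] > 0:
            labels[idx] = REGION_IR_PARTIAL_LSC
        elif ir > 0 and ov["SSC"] > 0:
            labels[idx] = REGION_IR_PARTIAL_SSC
        elif ov["LSC"] >= ov["SSC"]:
            labels[idx] = REGION_LSC
        else:
            labels[idx] = REGION_SSC
    junctions = _junction_tables(record, structure)
    return GeneRegionAssignment(regions=labels, copy_counts=fully_ir, junctions=junctions)


def _junction_tables(
    record: PlastomeRecord, structure: QuadripartiteStructure
) -> dict[str, list[tuple[str, bool]]]:
    n = len(record.sequence)
    points = {
        "LSC/IRA": structure.ira[0] % n,
        "IRA/SSC": structure.ssc[0] % n,
        "SSC/IRB": structure.irb[0] % n,
        "IRB/LSC": structure.lsc[0] % n,
    }
    def covers(feat: GeneFeature, pos: int) -> bool:
        return any(s <= pos < e for s, e in feat.intervals)

    out: dict[str, list[tuple[str, bool]]] = {}
    for name, point in points.items():
        entries: list[tuple[str, bool, int]] = []
        for feat in record.features:
            # a feature straddles the junction iff it covers both flanking bases
            if covers(feat, (point - 1) % n) and covers(feat, point % n):
                entries.append((feat.name, True, 0))
        # nearest gene strictly before and strictly after the junction
        before = min(
            (f for f in record.features),
            key=lambda f: (point - f.intervals[-1][1]) % n,
            default=None,
        )
        after = min(
            (f for f in record.features),
            key=lambda f: (f.intervals[0][0] - point) % n,
            default=None,
        )
        ordered: list[tuple[str, bool]] = []
        if before is not None:
            ordered.append((before.name, any(before.name == e[0] for e in entries)))
        for name_, _flag, _ in entries:
            if all(name_ != g for g, _ in ordered):
                ordered.append((name_, True))
        if after is not None and all(after.name != g for g, _ in ordered):
            ordered.append((after.name, False))
        out[name] = ordered
    return out


# ---------------------------------------------------------------------------
# Gene-content comparison


@dataclass
class ContentDiff:
    """Differences in gene content between two annotated genomes."""

    only_in_a: list[str]
    only_in_b: list[str]
    pseudo_in_exactly_one: list[str]
    intron_diffs: dict[str, tuple[int, int]]
    copy_number_diffs: dict[str, tuple[int, int]]


def _inventory(record: PlastomeRecord) -> dict[str, list[GeneFeature]]:
    inv: dict[str, list[GeneFeature]] = {}
    for f in record.features:
        inv.setdefault(f.name, []).append(f)
    return inv


def gene_content_diff(a: PlastomeRecord, b: PlastomeRecord) -> ContentDiff:
    """Set differences, pseudo-status, intron-count and copy-number diffs."""
    if not a.features or not b.features:
        warnings.warn("empty feature table; content diff is empty", stacklevel=2)
        return ContentDiff([], [], [], {}, {})
    inv_a, inv_b = _inventory(a), _inventory(b)
    only_a = sorted(set(inv_a) - set(inv_b))
    only_b = sorted(set(inv_b) - set(inv_a))
    shared = sorted(set(inv_a) & set(inv_b))
    pseudo_one = [
        g
        for g in shared
        if any(f.pseudo for f in inv_a[g]) != any(f.pseudo for f in inv_b[g])
    ]
    intron_diffs = {}
    copy_diffs = {}
    for g in shared:
        ia = max(f.intron_count for f in inv_a[g])
        ib = max(f.intron_count for f in inv_b[g])
        if ia != ib:
            intron_diffs[g] = (ia, ib)
        if len(inv_a[g]) != len(inv_b[g]):
            copy_diffs[g] = (len(inv_a[g]), len(inv_b[g]))
    return ContentDiff(only_a, only_b, pseudo_one, intron_diffs, copy_diffs)
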