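"""Pseudogene screening and RNA-editing hints.

A candidate region is screened against an intact reference CDS by global
affine-gap alignment: percent identity (identical columns over all
alignment columns, gaps included in the denominator), indel events
(maximal gap runs in either row), and stop-codon structure with the
reading frame projected from the reference through the alignment — a
degraded region has no trustworthy frame of its own.

Annotated coding genes are separately scanned for hints of RNA editing:
non-canonical start codons, non-stop final codons, and in-frame internal
stops, all read directly off the genomic sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import Align

from .errors import FrameError
from .model import PlastomeRecord, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}
DEFAULT_START_CODONS = frozenset({"ATG"})

HINT_UNDETERMINED_START = "undetermined-start"
HINT_UNDETERMINED_STOP = "undetermined-stop"
HINT_INTERNAL_STOP = "internal-stop"


@dataclass(frozen=True)
class PairwiseScreenReport:
    percent_identity: float
    indel_events: int
    internal_stop_count: int
    start_codon_present: bool
    stop_codon_present: bool
    alignment_length: int


@dataclass(frozen=True)
class EditHint:
    gene: str
    kind: str
    position: int  # 0-based codon index within the spliced CDS


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def gap_events(row_a: str, row_b: str) -> int:
    """Maximal '-' runs summed over both rows of a pairwise alignment."""
    count = 0
    for row in (row_a, row_b):
        in_gap = False
        for ch in row:
            if ch == "-" and not in_gap:
                count += 1
            in_gap = ch == "-"
    return count


def pairwise_screen(
    query: str,
    reference_cds: str,
    aligner: Align.PairwiseAligner | None = None,
    alignment: tuple[str, str] | None = None,
) -> PairwiseScreenReport:
    """Screen a candidate region against an intact reference CDS.

    ``alignment`` may supply a precomputed (query_row, reference_row) pair
    (e.g. a published alignment); otherwise a global alignment is computed
    with the default parameters (match +1, mismatch -1, gap open -5,
    extend -1). Internal stops are counted in the reference-projected
    frame, excluding the final reference codon; the start/stop flags test
    the query codons projected onto the first and last reference codons.
    """
    reference_cds = reference_cds.upper()
    if len(reference_cds.replace("-", "")) % 3 != 0:
        raise FrameError("reference CDS length is not a multiple of 3")
    if alignment is not None:
        qrow, rrow = alignment[0].upper(), alignment[1].upper()
        if len(qrow) != len(rrow):
            raise FrameError("precomputed alignment rows differ in length")
    else:
        result = (aligner or _default_aligner()).align(query.upper(), reference_cds)[0]
        qrow, rrow = str(result[0]), str(result[1])
    ncol = len(qrow)
    identical = sum(
        1 for a, b in zip(qrow, rrow) if a == b and a != "-"
    )
    # project the reference frame onto the query: group query bases by the
    # reference codon index of the column they sit in
    ref_len = len(rrow.replace("-", ""))
    n_ref_codons = ref_len // 3
    codon_bases: dict[int, list[str]] = {}
    ref_pos = 0
    for a, b in zip(qrow, rrow):
        if b != "-":
            if a != "-":
                codon_bases.setdefault(ref_pos // 3, []).append(a)
            ref_pos += 1
    internal_stops = 0
    for idx, bases in codon_bases.items():
        if idx == 0 or idx == n_ref_codons - 1:
            continue
        if len(bases) == 3 and "".join(bases) in STOP_CODONS:
            internal_stops += 1
    first = "".join(codon_bases.get(0, []))
    last = "".join(codon_bases.get(n_ref_codons - 1, []))
    return PairwiseScreenReport(
        percent_identity=100.0 * identical / ncol,
        indel_events=gap_events(qrow, rrow),
        internal_stop_count=internal_stops,
        start_codon_present=first in DEFAULT_START_CODONS,
        stop_codon_present=last in STOP_CODONS,
        alignment_length=ncol,
    )


def edit_hint_scan(
    record: PlastomeRecord,
    start_codons: frozenset[str] = DEFAULT_START_CODONS,
) -> tuple[list[EditHint], dict[str, int]]:
    """Scan annotated (non-pseudo) CDS genes for RNA-editing hints.

    Returns the hint list plus a summary with per-kind locus counts and
    the number of distinct genes carrying at least one hint.
    """
    hints: list[EditHint] = []
    for feat in record.features:
        if feat.kind != "CDS" or feat.pseudo:
            continue
        cds = record.feature_sequence(feat)
        if len(cds) < 6:
            warnings.warn(f"{feat.name}: CDS shorter than 6 nt skipped", stacklevel=2)
            continue
        usable = len(cds) - len(cds) % 3
        codons = [cds[i : i + 3] for i in range(0, usable, 3)]
        if codons[0] not in start_codons:
            hints.append(EditHint(feat.name, HINT_UNDETERMINED_START, 0))
        if codons[-1] not in STOP_CODONS:
            hints.append(EditHint(feat.name, HINT_UNDETERMINED_STOP, len(codons) - 1))
        for i, codon in enumerate(codons[1:-1], start=1):
            if codon in STOP_CODONS:
                hints.append(EditHint(feat.name, HINT_INTERNAL_STOP, i))
    summary = {
        HINT_UNDETERMINED_START: sum(
            1 for h in hints if h.kind == HINT_UNDETERMINED_START
        ),
        HINT_UNDETERMINED_STOP: sum(
            1 for h in hints if h.kind == HINT_UNDETERMINED_STOP
        ),
        HINT_INTERNAL_STOP: sum(1 for h in hints if h.kind == HINT_INTERNAL_STOP),
        "genes_with_hints": len({h.gene for h in hints}),
        "loci": len(hints),
    }
    return hints, summary


def find_orfs(
    region: str, min_length: int, both_strands: bool = True
) -> list[tuple[int, int, int, int]]:
    """Maximal ATG-to-stop open reading frames of at least ``min_length`` nt.

    Returns (start, end, strand, frame) tuples in forward-region
    coordinates, end-exclusive and including the stop codon.
    """
    region = region.upper()
    n = len(region)
    results: list[tuple[int, int, int, int]] = []
    strands = [(region, 1)] + ([(revcomp(region), -1)] if both_strands else [])
    for seq, strand in strands:
        for frame in range(3):
            start: int | None = None
            for i in range(frame, n - 2, 3):
                codon = seq[i : i + 3]
                if codon in STOP_CODONS:
                    if start is not None and (i + 3 - start) >= min_length:
                        s, e = start, i + 3
                        if strand == -1:
                            s, e = n - e, n - s
                        results.append((s, e, strand, frame))
                    start = None
                elif codon == "ATG" and start is None:
                    start = i
    return sorted(results)
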