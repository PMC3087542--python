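"""Shared data model for annotated circular plastomes and alignments.

Coordinates are 0-based half-open throughout the package; the GenBank
1-based inclusive convention exists only at the I/O boundary. A feature
interval never wraps the origin: an origin-spanning gene is represented by
two (or more) intervals in transcript-precursor order.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

from .errors import IntegrityError

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Spelling variants seen across GenBank records, mapped to one symbol space.
GENE_ALIASES = {
    "trnfm": "trnfM-CAU",
    "trnfm-cau": "trnfM-CAU",
    "rrn4.5": "rrn4.5",
    "rrn4.5s": "rrn4.5",
    "4.5srrna": "rrn4.5",
    "5srrna": "rrn5",
    "16srrna": "rrn16",
    "23srrna": "rrn23",
}


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_gene_name(raw: str) -> str:
    """Normalize a gene symbol into the package's single symbol space.

    tRNAs become ``trnX-NNN`` (amino-acid letter upper-case, anticodon
    upper-case); other genes get a lower-case three-letter stem with any
    trailing letter upper-cased (``PsbA`` -> ``psbA``, ``RPS7`` -> ``rps7``).
    A small alias table catches ribosomal-RNA spelling variants.
    """
    s = raw.strip().strip("\"'").replace(" ", "")
    key = s.lower()
    if key in GENE_ALIASES:
        return GENE_ALIASES[key]
    if key.startswith("trn"):
        m = re.match(r"^trn([a-z])(?:[-_]?\(?([acgut]{3})\)?)?$", s, re.I)
        if m:
            aa = m.group(1).upper()
            anticodon = m.group(2)
            if anticodon:
                return f"trn{aa}-{anticodon.upper().replace('U', 'U')}"
            return f"trn{aa}"
    m = re.match(r"^([a-z]{3})([a-z0-9.]*)$", s, re.I)
    if m:
        stem = m.group(1).lower()
        rest = m.group(2)
        if rest and rest[-1].isalpha():
            rest = rest[:-1].lower() + rest[-1].upper()
        else:
            rest = rest.lower()
        return stem + rest
    return s


@dataclass(frozen=True)
class GeneFeature:
    """An annotated gene with one or more exon intervals.

    ``intervals`` are stored in precursor (plus-strand transcript) order;
    for a minus-strand feature the spliced sequence is the reverse
    complement of the concatenated interval sequences.
    """

    name: str
    strand: int
    intervals: tuple[Interval, ...]
    kind: str = "other"  # CDS | tRNA | rRNA | other
    pseudo: bool = False

    def __post_init__(self) -> None:
        if not self.intervals:
            raise IntegrityError(f"feature {self.name!r} has no intervals")
        if self.strand not in (1, -1):
            raise IntegrityError(f"feature {self.name!r}: strand must be +1/-1")
        for s, e in self.intervals:
            if e <= s:
                raise IntegrityError(
                    f"feature {self.name!r}: empty interval [{s},{e})"
                )

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    @property
    def intron_count(self) -> int:
        return len(self.intervals) - 1


@dataclass
class PlastomeRecord:
    """A circular annotated genome: sequence plus gene features."""

    identifier: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise IntegrityError(f"{self.identifier}: empty sequence")
        seq = self.sequence.upper()
        if re.search(r"[^ACGTN]", seq):
            warnings.warn(
                f"{self.identifier}: ambiguity codes other than N mapped to N",
                stacklevel=2,
            )
            seq = re.sub(r"[^ACGTN]", "N", seq)
        self.sequence = seq
        n = len(seq)
        for feat in self.features:
            for s, e in feat.intervals:
                if not (0 <= s < e <= n):
                    raise IntegrityError(
                        f"{self.identifier}: feature {feat.name!r} interval "
                        f"[{s},{e}) outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature_sequence(self, feature: GeneFeature) -> str:
        """Spliced sequence of a feature, 5'->3' on its coding strand."""
        precursor = "".join(self.sequence[s:e] for s, e in feature.intervals)
        return revcomp(precursor) if feature.strand == -1 else precursor

    def rotated(self, k: int) -> "PlastomeRecord":
        """Return a copy with the circular origin moved to position ``k``."""
        if not self.circular:
            raise IntegrityError("cannot rotate a linear record")
        n = len(self.sequence)
        k %= n
        seq = self.sequence[k:] + self.sequence[:k]
        feats = []
        for f in self.features:
            intervals: list[Interval] = []
            for s, e in f.intervals:
                intervals.extend(_shift_interval(s, e, k, n))
            feats.append(
                GeneFeature(f.name, f.strand, tuple(intervals), f.kind, f.pseudo)
            )
        return PlastomeRecord(self.identifier, seq, True, feats, self.source)


def _shift_interval(s: int, e: int, k: int, n: int) -> list[Interval]:
    """Map [s,e) under an origin rotation by k; split if it now wraps."""
    ns, ne = (s - k) % n, (e - k) % n or n
    if ns < ne:
        return [(ns, ne)]
    return [(ns, n), (0, ne)]


@dataclass
class Alignment:
    """A multiple alignment with per-gene partitions and excluded columns."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, Interval] = field(default_factory=dict)
    excluded: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise IntegrityError("duplicate taxon labels in alignment")
        lengths = {len(self.rows[t]) for t in self.taxa}
        if len(lengths) > 1:
            raise IntegrityError(f"ragged alignment rows: lengths {sorted(lengths)}")
        ncol = self.ncol
        if any(c < 0 or c >= ncol for c in self.excluded):
            raise IntegrityError("excluded column index out of range")
        claimed: set[int] = set()
        for gene, (s, e) in self.partitions.items():
            cols = set(range(s, e))
            if cols & claimed:
                raise IntegrityError(f"partition {gene!r} overlaps another")
            claimed |= cols

    @property
    def ncol(self) -> int:
        return len(self.rows[self.taxa[0]]) if self.taxa else 0

    def gene_of_column(self, col: int) -> str | None:
        for gene, (s, e) in self.partitions.items():
            if s <= col < e:
                return gene
        return None


@dataclass
class BinaryMatrix:
    """Presence/absence characters (states 0/1/?) across taxa."""

    taxa: list[str]
    characters: list[str]
    cells: dict[str, str]  # taxon -> string over {0,1,?}

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise IntegrityError("duplicate taxon labels in matrix")
        if len(set(self.characters)) != len(self.characters):
            raise IntegrityError("duplicate character labels in matrix")
        nchar = len(self.characters)
        for t in self.taxa:
            row = self.cells[t]
            if len(row) != nchar:
                raise IntegrityError(f"row {t!r} has {len(row)} cells, expected {nchar}")
            if set(row) - set("01?"):
                raise IntegrityError(f"row {t!r} has states outside 0/1/?")

    def column(self, index: int) -> dict[str, str]:
        return {t: self.cells[t][index] for t in self.taxa}


def spliced_length(feature: GeneFeature) -> int:
    """Sum of interval lengths (the coordinate law companion)."""
    return feature.length


def iter_positions(intervals: Iterable[Interval]) -> Iterable[int]:
    for s, e in intervals:
        yield from range(s, e)
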