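"""Nucleotide composition and codon-usage bias (Wright's ENc).

The effective number of codons (ENc) summarizes how far synonymous codon
usage departs from uniformity, from 20 (exactly one codon per amino acid)
to 61 (all synonyms used equally). For an amino acid with n observed
codons at frequencies p_i the codon homozygosity is

    F = (n * sum(p_i^2) - 1) / (n - 1),

F-hat_k averages F over the amino-acid families of synonymy degree k, and

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

under the universal code (9 twofold families, 1 threefold, 5 fourfold,
3 sixfold; Met and Trp contribute the constant 2). Values above 61 due to
sampling are capped at 61. Families observed fewer than twice are left out
of their class average; an unestimable threefold class falls back to
(F2 + F4) / 2; any other unestimable class makes ENc undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import pandas as pd
from Bio.Data import CodonTable

from .errors import FrameError, UndefinedValueError
from .model import Alignment

_BASES = "TCAG"
ALL_CODONS = ["".join(c) for c in product(_BASES, repeat=3)]


def codon_families(code_id: int = 1) -> dict[str, list[str]]:
    """Synonymous codon families of a genetic code, keyed by amino acid."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            continue
        fams.setdefault(table.forward_table[codon], []).append(codon)
    return fams


@dataclass
class CodonUsageProfile:
    """64-codon count vector with genetic-code metadata."""

    counts: dict[str, int] = field(default_factory=dict)
    code_id: int = 1

    def __post_init__(self) -> None:
        bad = set(self.counts) - set(ALL_CODONS)
        if bad:
            raise ValueError(f"not codons: {sorted(bad)}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def add(self, codon: str, n: int = 1) -> None:
        self.counts[codon] = self.counts.get(codon, 0) + n


def count_codons(seq: str, code_id: int = 1) -> CodonUsageProfile:
    """Codon counts of an in-frame CDS; codons containing N are skipped."""
    if len(seq) % 3 != 0:
        raise FrameError(f"sequence length {len(seq)} is not a multiple of 3")
    profile = CodonUsageProfile(code_id=code_id)
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if set(codon) <= set("ACGT"):
            profile.add(codon)
    return profile


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N and gaps ignored entirely."""
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise UndefinedValueError("no unambiguous bases in sequence")
    return (counts["G"] + counts["C"]) / denom


def family_homozygosity(counts: list[int]) -> float | None:
    """F = (n * sum(p^2) - 1) / (n - 1) for one family; None when n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p_sq = sum((c / n) ** 2 for c in counts)
    return (n * p_sq - 1) / (n - 1)


def enc(profile: CodonUsageProfile) -> float:
    """Wright's effective number of codons for a codon-usage profile."""
    if profile.total == 0:
        raise UndefinedValueError("empty codon profile")
    fams = codon_families(profile.code_id)
    by_degree: dict[int, list[float]] = {}
    singleton_aas = 0
    for codons in fams.values():
        k = len(codons)
        if k == 1:
            singleton_aas += 1
            continue
        f = family_homozygosity([profile.counts.get(c, 0) for c in codons])
        if f is not None:
            by_degree.setdefault(k, []).append(f)
    degree_counts = {}
    for codons in fams.values():
        k = len(codons)
        if k > 1:
            degree_counts[k] = degree_counts.get(k, 0) + 1

    def class_average(k: int) -> float | None:
        vals = by_degree.get(k)
        if not vals:
            return None
        avg = sum(vals) / len(vals)
        return avg if avg > 0 else None

    averages: dict[int, float] = {}
    for k in sorted(degree_counts):
        avg = class_average(k)
        if avg is None and k == 3:
            f2, f4 = class_average(2), class_average(4)
            if f2 is not None and f4 is not None:
                avg = (f2 + f4) / 2
        if avg is None:
            raise UndefinedValueError(f"no estimable family of degree {k}")
        averages[k] = avg
    value = singleton_aas + sum(degree_counts[k] / averages[k] for k in degree_counts)
    return min(value, 61.0)


# ---------------------------------------------------------------------------
# Per-taxon reports


def _concatenated_cds(alignment: Alignment, taxon: str, use_exclusions: bool) -> str:
    """A taxon's coding columns, exclusions and gaps removed, in frame."""
    row = alignment.rows[taxon]
    if alignment.partitions:
        cols: list[int] = []
        for _, (s, e) in sorted(alignment.partitions.items(), key=lambda kv: kv[1]):
            cols.extend(range(s, e))
    else:
        cols = list(range(alignment.ncol))
    if use_exclusions:
        cols = [c for c in cols if c not in alignment.excluded]
    seq = "".join(row[c] for c in cols)
    return seq.replace("-", "").replace("?", "")


def taxon_codon_report(
    alignment: Alignment,
    taxa: list[str] | None = None,
    code_id: int = 1,
    use_exclusions: bool = True,
) -> pd.DataFrame:
    """Per-taxon G/C (%) and ENc from concatenated coding columns.

    ENc is computed from the pooled codon counts of all genes, one value
    per taxon. A taxon whose gap-free concatenation is not a whole number
    of codons raises :class:`FrameError` naming it.
    """
    rows = []
    for taxon in taxa or alignment.taxa:
        seq = _concatenated_cds(alignment, taxon, use_exclusions)
        if len(seq) % 3 != 0:
            raise FrameError(
                f"{taxon}: concatenated CDS length {len(seq)} not divisible by 3"
            )
        profile = count_codons(seq, code_id=code_id)
        try:
            enc_value = round(enc(profile), 2)
        except UndefinedValueError:
            enc_value = float("nan")  # ENc undefined for this profile
        rows.append(
            {
                "taxon": taxon,
                "n_codons": profile.total,
                "gc_percent": round(100 * gc_content(seq), 2),
                "enc": enc_value,
            }
        )
    return pd.DataFrame(rows)
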