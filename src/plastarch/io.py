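"""Readers and writers for the formats the pipeline touches.

GenBank flat files, FASTA and NEXUS alignments are parsed with Biopython;
Newick trees with DendroPy. The NEXUS binary-matrix dialect (FORMAT
symbols="01" with CHARSTATELABELS) is written here and must round-trip
bit-exactly, so both directions live in this module.
"""

from __future__ import annotations

import re
from pathlib import Path

import dendropy
from Bio import SeqIO
from Bio.Nexus import Nexus

from .errors import FormatError, IntegrityError
from .model import Alignment, BinaryMatrix, GeneFeature, PlastomeRecord

Tree = dendropy.Tree

_KIND_MAP = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_name(biofeat) -> str | None:
    for key in ("gene", "locus_tag", "product"):
        if key in biofeat.qualifiers:
            return biofeat.qualifiers[key][0]
    return None


def read_plastome_flatfile(path) -> PlastomeRecord:
    """Read an annotated GenBank flat file into a :class:`PlastomeRecord`.

    Compound locations (``join``/``complement``, including origin-spanning
    joins) become multi-interval features; ``/pseudo`` qualifiers set the
    pseudo flag; coordinates are converted to 0-based half-open.
    """
    from .model import normalize_gene_name

    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises bare ValueError on bad input
        raise FormatError(f"{path}: not a readable GenBank flat file: {exc}") from exc
    topology = rec.annotations.get("topology", "circular")
    seqlen = len(rec.seq)
    features: list[GeneFeature] = []
    claimed: list[tuple[str, int, int]] = []  # (name, min, max) of typed feats
    typed = [f for f in rec.features if f.type in _KIND_MAP]
    genes_only = [f for f in rec.features if f.type == "gene"]
    for biofeat in typed + genes_only:
        name = _feature_name(biofeat)
        if name is None:
            continue
        name = normalize_gene_name(name)
        parts = biofeat.location.parts
        intervals = tuple((int(p.start), int(p.end)) for p in parts)
        for s, e in intervals:
            if not (0 <= s < e <= seqlen):
                raise IntegrityError(
                    f"{path}: feature {name!r} interval [{s},{e}) outside "
                    f"sequence of length {seqlen}"
                )
        strand = biofeat.location.strand or 1
        if biofeat.type == "gene":
            lo = min(s for s, _ in intervals)
            hi = max(e for _, e in intervals)
            if any(n == name and s < hi and lo < e for n, s, e in claimed):
                continue  # already represented by a CDS/tRNA/rRNA feature
            kind = "other"
        else:
            kind = _KIND_MAP[biofeat.type]
            lo = min(s for s, _ in intervals)
            hi = max(e for _, e in intervals)
            claimed.append((name, lo, hi))
        pseudo = "pseudo" in biofeat.qualifiers or "pseudogene" in biofeat.qualifiers
        features.append(GeneFeature(name, strand, intervals, kind, pseudo))
    return PlastomeRecord(
        identifier=rec.id or rec.name or path.stem,
        sequence=str(rec.seq).upper(),
        circular=(topology == "circular"),
        features=features,
        source=str(path),
    )


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {identifier: sequence} mapping."""
    try:
        return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    except Exception as exc:
        raise FormatError(f"{path}: not readable FASTA: {exc}") from exc


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


_EXSET_RE = re.compile(r"EXSET\s+\*?\s*\S+?\s*=\s*([^;]+);", re.I)


def _parse_exset_columns(spec: str) -> set[int]:
    """Parse a NEXUS EXSET body ('4-6 10 12-15') into 0-based indices."""
    cols: set[int] = set()
    for token in spec.split():
        m = re.match(r"^(\d+)(?:-(\d+))?$", token)
        if not m:
            raise FormatError(f"unsupported EXSET token {token!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) else lo
        cols.update(range(lo - 1, hi))
    return cols


def read_alignment_nexus(path) -> Alignment:
    """Read a NEXUS alignment (interleave supported) with charsets/exsets.

    Interleaved blocks are concatenated per taxon; CHARSET statements become
    per-gene partitions; EXSET statements become the excluded-column set
    (1-based inclusive in the file, 0-based half-open in memory).
    """
    path = Path(path)
    text = path.read_text()
    try:
        nex = Nexus.Nexus(text)
    except Exception as exc:
        raise FormatError(f"{path}: NEXUS parse failure: {exc}") from exc
    if len(set(nex.taxlabels)) != len(nex.taxlabels):
        raise IntegrityError(f"{path}: duplicate taxon labels")
    rows = {t: str(nex.matrix[t]).upper() for t in nex.taxlabels}
    lengths = {len(r) for r in rows.values()}
    if len(lengths) > 1:
        raise FormatError(f"{path}: ragged rows (lengths {sorted(lengths)})")
    partitions: dict[str, tuple[int, int]] = {}
    for gene, cols in (nex.charsets or {}).items():
        cols = sorted(cols)
        if cols and cols == list(range(cols[0], cols[-1] + 1)):
            partitions[gene] = (cols[0], cols[-1] + 1)
    excluded: set[int] = set()
    for m in _EXSET_RE.finditer(text):
        excluded |= _parse_exset_columns(m.group(1))
    return Alignment(
        taxa=list(nex.taxlabels), rows=rows, partitions=partitions, excluded=excluded
    )


def write_alignment_nexus(alignment: Alignment, path, interleave_width: int = 0) -> None:
    """Write an alignment as NEXUS with CHARSET partitions and an EXSET.

    ``interleave_width`` > 0 writes interleaved blocks of that many columns.
    """
    ncol = alignment.ncol
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(alignment.taxa)} NCHAR={ncol};\n")
        inter = " INTERLEAVE=YES" if interleave_width else ""
        fh.write(f"FORMAT DATATYPE=DNA MISSING=? GAP=-{inter};\n")
        fh.write("MATRIX\n")
        width = max((len(_quote(t)) for t in alignment.taxa), default=0) + 2
        step = interleave_width or ncol
        for lo in range(0, max(ncol, 1), step):
            for t in alignment.taxa:
                fh.write(f"{_quote(t):<{width}}{alignment.rows[t][lo:lo + step]}\n")
            fh.write("\n")
        fh.write(";\nEND;\n")
        if alignment.partitions:
            fh.write("BEGIN SETS;\n")
            for gene, (s, e) in sorted(alignment.partitions.items(), key=lambda kv: kv[1]):
                fh.write(f"CHARSET {gene} = {s + 1}-{e};\n")
            fh.write("END;\n")
        if alignment.excluded:
            ranges = _ranges_1based(sorted(alignment.excluded))
            fh.write("BEGIN ASSUMPTIONS;\n")
            fh.write(f"EXSET * excluded = {' '.join(ranges)};\n")
            fh.write("END;\n")


def _ranges_1based(cols: list[int]) -> list[str]:
    out: list[str] = []
    i = 0
    while i < len(cols):
        j = i
        while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
            j += 1
        lo, hi = cols[i] + 1, cols[j] + 1
        out.append(str(lo) if lo == hi else f"{lo}-{hi}")
        i = j + 1
    return out


def read_tree_newick(path_or_string) -> Tree:
    """Read a Newick tree; polytomies are preserved, labels must be unique."""
    src = str(path_or_string)
    kwargs = {"schema": "newick", "preserve_underscores": True}
    try:
        if Path(src).exists() and not src.lstrip().startswith("("):
            tree = dendropy.Tree.get(path=src, **kwargs)
        else:
            tree = dendropy.Tree.get(data=src, **kwargs)
    except Exception as exc:
        raise FormatError(f"Newick parse failure: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise FormatError("duplicate leaf labels in tree")
    if len(labels) < 2:
        raise FormatError("tree must have at least 2 leaves")
    return tree


def _quote(label: str) -> str:
    if re.search(r"[\s;(){}\[\]'\"=,]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_binary_matrix_nexus(matrix: BinaryMatrix, path) -> None:
    """Write a binary matrix as NEXUS with CHARSTATELABELS (round-trip safe)."""
    nchar = len(matrix.characters)
    with open(path, "w") as fh:
        fh.write("#NEXUS\n")
        fh.write("BEGIN DATA;\n")
        fh.write(f"DIMENSIONS NTAX={len(matrix.taxa)} NCHAR={nchar};\n")
        fh.write('FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        if nchar:
            labels = ", ".join(
                f"{i + 1} {_quote(lab)}" for i, lab in enumerate(matrix.characters)
            )
            fh.write(f"CHARSTATELABELS {labels};\n")
        fh.write("MATRIX\n")
        width = max((len(t) for t in matrix.taxa), default=0) + 2
        for t in matrix.taxa:
            fh.write(f"{_quote(t):<{width}}{matrix.cells[t]}\n")
        fh.write(";\nEND;\n")


def read_binary_matrix_nexus(path) -> BinaryMatrix:
    """Read a NEXUS standard-datatype 0/1 matrix with CHARSTATELABELS."""
    path = Path(path)
    text = path.read_text()
    m = re.search(r"NCHAR\s*=\s*(\d+)", text, re.I)
    if m and int(m.group(1)) == 0:
        # degenerate matrix; Bio.Nexus cannot parse an empty MATRIX block
        body = re.search(r"MATRIX\s*(.*?);", text, re.S | re.I)
        taxa = [
            line.split()[0].strip("'")
            for line in (body.group(1) if body else "").splitlines()
            if line.strip()
        ]
        return BinaryMatrix(taxa=taxa, characters=[], cells={t: "" for t in taxa})
    try:
        nex = Nexus.Nexus(text)
    except Exception as exc:
        raise FormatError(f"{path}: NEXUS parse failure: {exc}") from exc
    if len(set(nex.taxlabels)) != len(nex.taxlabels):
        raise IntegrityError(f"{path}: duplicate taxon labels")
    nchar = nex.nchar or 0
    if nex.charlabels:
        characters = [nex.charlabels.get(i, f"char_{i + 1}") for i in range(nchar)]
    else:
        characters = [f"char_{i + 1}" for i in range(nchar)]
    cells = {t: str(nex.matrix[t]) if nchar else "" for t in nex.taxlabels}
    return BinaryMatrix(taxa=list(nex.taxlabels), characters=characters, cells=cells)
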