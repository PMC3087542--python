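"""End-to-end report generation over genomes + alignment + tree.

Given a validated configuration, runs each analysis stage independently
and writes TSV tables (with a header comment naming units: bp, %,
0-based spans) plus a machine-readable JSON run log. A failure in one
stage is recorded and does not corrupt the outputs of completed stages;
report content is deterministic for identical inputs and configuration.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .architecture import (
    DEFAULT_MIN_IR_LENGTH,
    classify_gene_regions,
    detect_inverted_repeat,
    gene_content_diff,
    region_stats,
)
from .codon import taxon_codon_report
from .errors import PlastarchError
from .gene_order import (
    breakpoint_distance,
    extract_signed_order,
    inversion_candidates,
    region_translocations,
    synteny_blocks,
)
from .indels import classify_matrix, code_indels, tree_free_autapomorphy_count
from .io import (
    read_alignment_nexus,
    read_binary_matrix_nexus,
    read_plastome_flatfile,
    read_tree_newick,
    write_binary_matrix_nexus,
)
from .screen import edit_hint_scan

_KNOWN_KEYS = {
    "genomes",
    "alignment",
    "indel_matrix",
    "tree",
    "outdir",
    "collapse_ir",
    "include_trnas",
    "genetic_code",
    "min_ir_length",
    "start_codons",
    "label_map",
    "seed",
}


@dataclass
class PipelineConfig:
    genomes: list[str] = field(default_factory=list)
    alignment: str | None = None
    indel_matrix: str | None = None
    tree: str | None = None
    outdir: str = "plastarch_out"
    collapse_ir: bool = True
    include_trnas: bool = True
    genetic_code: int = 1
    min_ir_length: int = DEFAULT_MIN_IR_LENGTH
    start_codons: list[str] = field(default_factory=lambda: ["ATG"])
    label_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - _KNOWN_KEYS
        if unknown:
            raise PlastarchError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in list(self.genomes) + [self.alignment, self.indel_matrix, self.tree]:
            if p is not None and not Path(p).exists():
                raise PlastarchError(f"input path does not exist: {p}")


def _write_tsv(df: pd.DataFrame, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_report(config: PipelineConfig) -> dict:
    """Run every stage the configuration enables; return the run log."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "config": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "stages": {},
    }
    records = {}
    structures = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
            log["stages"][name] = {"status": "ok"}
        except Exception as exc:  # isolate stage failures
            log["stages"][name] = {"status": "failed", "error": str(exc)}
        log["stages"][name]["seconds"] = round(time.perf_counter() - t0, 3)

    def load_genomes():
        for path in config.genomes:
            rec = read_plastome_flatfile(path)
            records[rec.identifier] = rec
            structures[rec.identifier] = detect_inverted_repeat(
                rec, min_length=config.min_ir_length
            )

    def architecture_stage():
        rows = []
        junction_rows = []
        for gid, rec in records.items():
            st = structures[gid]
            if st is None:
                rows.append(
                    {"genome": gid, "total_bp": len(rec.sequence), "ir": "not detected"}
                )
                continue
            rep = region_stats(rec, st)
            rows.append(
                {
                    "genome": gid,
                    "total_bp": rep.total_length,
                    "lsc_bp": rep.lsc_length,
                    "ssc_bp": rep.ssc_length,
                    "ir_bp": rep.ir_length,
                    "gc_total_pct": round(100 * rep.gc_total, 2),
                    "gc_lsc_pct": round(100 * rep.gc_lsc, 2),
                    "gc_ssc_pct": round(100 * rep.gc_ssc, 2),
                    "gc_ir_pct": round(100 * rep.gc_ir, 2),
                }
            )
            assignment = classify_gene_regions(rec, st)
            for junction, genes in assignment.junctions.items():
                junction_rows.append(
                    {
                        "genome": gid,
                        "junction": junction,
                        "genes": ",".join(
                            f"[{g}]" if partial else g for g, partial in genes
                        ),
                    }
                )
        _write_tsv(
            pd.DataFrame(rows),
            outdir / "architecture.tsv",
            "per-genome region lengths (bp) and G/C (%)",
        )
        _write_tsv(
            pd.DataFrame(junction_rows),
            outdir / "junctions.tsv",
            "IR junction gene content; [gene] = partially in IR",
        )

    def gene_order_stage():
        ids = list(records)
        orders = {
            gid: extract_signed_order(
                records[gid],
                structures[gid],
                collapse_ir=config.collapse_ir,
                include_trnas=config.include_trnas,
            )
            for gid in ids
        }
        dist_rows, block_rows, trans_rows = [], [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                dist_rows.append(
                    {
                        "genome_a": a,
                        "genome_b": b,
                        "breakpoints": breakpoint_distance(orders[a], orders[b]),
                    }
                )
                blocks = synteny_blocks(orders[a], orders[b])
                for blk in blocks:
                    block_rows.append(
                        {
                            "genome_a": a,
                            "genome_b": b,
                            "orientation": blk.orientation,
                            "n_genes": len(blk.genes),
                            "endpoints": f"{blk.endpoints[0]}..{blk.endpoints[1]}",
                        }
                    )
                for gene, ra, rb in region_translocations(orders[a], orders[b]):
                    trans_rows.append(
                        {"gene": gene, "region_a": ra, "region_b": rb}
                    )
                _ = inversion_candidates(blocks)
        _write_tsv(
            pd.DataFrame(dist_rows),
            outdir / "gene_order_distances.tsv",
            "pairwise signed breakpoint distances (shared genes)",
        )
        _write_tsv(
            pd.DataFrame(block_rows),
            outdir / "synteny_blocks.tsv",
            "maximal co-linear blocks; inverted blocks are inversion candidates",
        )
        _write_tsv(
            pd.DataFrame(trans_rows),
            outdir / "translocations.tsv",
            "shared genes whose region label differs between genomes",
        )

    def indel_stage():
        if config.indel_matrix:
            matrix = read_binary_matrix_nexus(config.indel_matrix)
        else:
            alignment = read_alignment_nexus(config.alignment)
            matrix, _chars = code_indels(alignment)
            write_binary_matrix_nexus(matrix, outdir / "indel_matrix.nex")
        tree = read_tree_newick(config.tree)
        counts, table = classify_matrix(matrix, tree, label_map=config.label_map)
        counts["total"] = len(matrix.characters)
        counts["tree_free_autapomorphies"] = tree_free_autapomorphy_count(matrix)
        rows = [
            {
                "character": label,
                "steps": cls.steps,
                "category": cls.category,
                "clade": ";".join(sorted(cls.clade)) if cls.clade else "",
            }
            for label, cls in table
        ]
        _write_tsv(
            pd.DataFrame(rows),
            outdir / "indel_classification.tsv",
            "per-character parsimony steps and category on the input tree",
        )
        _write_tsv(
            pd.DataFrame([counts]),
            outdir / "indel_summary.tsv",
            "character counts per category",
        )

    def codon_stage():
        alignment = read_alignment_nexus(config.alignment)
        df = taxon_codon_report(alignment, code_id=config.genetic_code)
        _write_tsv(
            df,
            outdir / "codon_usage.tsv",
            "per-taxon G/C (%) and effective number of codons (ENc)",
        )

    def screen_stage():
        rows = []
        for gid, rec in records.items():
            hints, summary = edit_hint_scan(
                rec, start_codons=frozenset(config.start_codons)
            )
            for h in hints:
                rows.append(
                    {"genome": gid, "gene": h.gene, "hint": h.kind, "codon": h.position}
                )
        _write_tsv(
            pd.DataFrame(rows),
            outdir / "edit_hints.tsv",
            "RNA-editing hints from annotated CDS genes (codon index, 0-based)",
        )

    def content_stage():
        ids = list(records)
        rows = []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                diff = gene_content_diff(records[a], records[b])
                rows.append(
                    {
                        "genome_a": a,
                        "genome_b": b,
                        "only_in_a": ",".join(diff.only_in_a),
                        "only_in_b": ",".join(diff.only_in_b),
                        "pseudo_in_one": ",".join(diff.pseudo_in_exactly_one),
                        "intron_diffs": ";".join(
                            f"{g}:{x}/{y}" for g, (x, y) in diff.intron_diffs.items()
                        ),
                        "copy_diffs": ";".join(
                            f"{g}:{x}/{y}"
                            for g, (x, y) in diff.copy_number_diffs.items()
                        ),
                    }
                )
        _write_tsv(
            pd.DataFrame(rows),
            outdir / "gene_content_diff.tsv",
            "pairwise gene content differences",
        )

    if config.genomes:
        stage("load_genomes", load_genomes)
        stage("architecture", architecture_stage)
        if len(records) >= 2:
            stage("gene_order", gene_order_stage)
            stage("gene_content", content_stage)
        stage("screen", screen_stage)
    if (config.alignment or config.indel_matrix) and config.tree:
        stage("indels", indel_stage)
    if config.alignment:
        stage("codon", codon_stage)

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    return log


__all__ = ["PipelineConfig", "run_report"]
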