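# plastarch

Comparative analysis of plastid genome (plastome) architecture for
phylogenetics and molecular evolution. The package targets the kinds of
questions raised by early-diverging land-plant plastomes (horsetails,
quillworts, mosses, liverworts): how the quadripartite structure varies,
which rearrangements and indels mark which lineages, and how codon usage
and base composition differ across taxa.

It provides, as a tested library plus a `plastarch` command-line tool:

- **Quadripartite structure detection.** The inverted repeat (IR) pair of a
  circular genome is found as the maximal pair of disjoint intervals whose
  sequences are exact reverse complements; the two gaps between the copies
  are the large and small single-copy regions (LSC, SSC, larger = LSC), so
  the circle reads LSC–IRA–SSC–IRB and LSC + SSC + 2·IR = genome length.
  Per-region lengths and G/C follow, along with gene-by-region
  classification (including genes partially encoded in the IR) and the
  gene content of all four IR junctions.
- **Gene-order comparison.** Circular signed gene orders are compared by
  signed breakpoint distance (adjacency x→y matches x→y or −y→−x) and by
  maximal oriented synteny blocks; every inverted block is an inversion
  candidate reported with its endpoint genes ("inversion involving X to Y").
  Genes whose region label changes between genomes are reported as
  translocations.
- **Indel coding and character classification.** Alignment gaps are scored
  with simple indel coding: each distinct gap span is one binary
  presence/absence character (identical gap → 0, nucleotides across the
  span → 1, anything else → ?). Each character is mapped onto a reference
  tree with small parsimony (Hartigan's generalization of Fitch, so
  polytomies are fine): one step on a terminal branch is an autapomorphy,
  one step on an internal branch a synapomorphy, two or more steps
  homoplasy.
- **Codon-usage bias.** Wright's effective number of codons,
  `ENc = 2 + 9/F̂₂ + 1/F̂₃ + 5/F̂₄ + 3/F̂₆`, where
  `F = (n·Σpᵢ² − 1)/(n − 1)` is the codon homozygosity of an amino-acid
  family and F̂ₖ averages over families of synonymy degree k. ENc runs
  from 20 (one codon per amino acid) to 61 (uniform synonymous usage).
- **Pseudogene and RNA-editing screens.** Candidate regions are screened
  against intact reference genes (percent identity, indel events, internal
  stops in the reference-projected frame); annotated coding genes are
  scanned for non-ATG starts, missing stops and internal stops — the
  genomic footprints of RNA editing — and regions can be scanned for open
  reading frames.
- **Ground-truthed synthetic data.** Generators plant an exact IR pair in a
  repeat-free circular genome, signed rearrangements with known endpoints,
  indel events on known tree branches, and coding sequences with a tunable
  codon-bias dial — each with a machine-readable truth log, so every
  analysis stage is testable end to end without downloads.

## Worked example

```python
from plastarch.simulate import gen_plastome, gen_rearranged_pair, gen_codon_seq
from plastarch.architecture import detect_inverted_repeat, region_stats
from plastarch.gene_order import synteny_blocks, inversion_candidates
from plastarch.codon import count_codons, enc

record, truth = gen_plastome(lsc_len=4000, ssc_len=1500, ir_len=1000,
                             n_genes=20, gc_target=0.3336, seed=11)
structure = detect_inverted_repeat(record, min_length=500)
report = region_stats(record, structure)
print(f"total={report.total_length} LSC={report.lsc_length} "
      f"SSC={report.ssc_length} IR={report.ir_length} "
      f"GC={100 * report.gc_total:.2f}%")
print("planted == detected:", truth.ir_intervals == (structure.ira, structure.irb))

a, b, log = gen_rearranged_pair(n_genes=30, k_reversals=1, seed=11)
print("inversion candidates:", inversion_candidates(synteny_blocks(a, b)))

profile = count_codons(gen_codon_seq(4000, bias=0.7, seed=11))
print(f"ENc at bias 0.7: {enc(profile):.2f}")
```

prints

```
total=7500 LSC=4000 SSC=1500 IR=1000 GC=33.36%
planted == detected: True
inversion candidates: [('g023', 'g023')]
ENc at bias 0.7: 28.34
```

The detector recovered exactly the planted IR pair of a 7.5 kb synthetic
plastome whose composition was dialed to 33.36% G/C; the single planted
reversal (here a one-gene segment, g023) is returned as the only inversion
candidate; and a moderately biased coding sequence lands between the ENc
extremes of 20 and 61.

The same analyses run from the shell:

```bash
plastarch simulate --seed 11 --out genome.gb     # + genome.truth.json
plastarch architecture --genome genome.gb --min-ir-length 500
plastarch report --config run.yaml               # full TSV report bundle
```

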