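# Methods

This note documents the models and procedures implemented in `plastarch`,
the parameters that matter, the numerical conventions, and what the
synthetic-data generators do and do not emulate.

## Coordinates and the data model

All coordinates are 0-based half-open; the GenBank 1-based inclusive
convention is converted exactly once, at the flat-file boundary. A gene is
a set of exon intervals in precursor order plus a strand; its spliced
sequence is the concatenation of interval sequences, reverse-complemented
for minus-strand genes. An origin-spanning gene on a circular record is
two intervals, never a wrapped one, so interval arithmetic stays ordinary.
Gene symbols are normalized into one symbol space (lower-case stem with an
upper-cased trailing letter, `trnX-NNN` for tRNAs, a small alias table for
ribosomal-RNA spelling variants) because cross-genome comparisons are set
operations on symbols. Ambiguity codes other than N are mapped to N with a
warning; every downstream statistic defines behavior only over
{A, C, G, T, N}.

## Inverted-repeat detection

The IR pair is defined as the maximal-length pair of disjoint intervals on
the circle whose sequences are exact reverse complements. Exactness (no
mismatch tolerance) makes "maximal" well defined and matches how a single
molecule's two IR copies are reported as one length. The search binary
searches the length (validity is monotone: any valid pair of length L
yields one of length L−1) and tests each candidate length with a rolling
hash over the doubled sequence against the doubled reverse complement,
verifying candidate matches literally to rule out hash collisions. Among
equally long pairs, the structure whose IRA start is smallest wins —
purely a determinism rule. The larger single-copy gap is the LSC; IRA is
the copy that follows the LSC, giving the canonical LSC–IRA–SSC–IRB
linearization used by the junction tables. The default minimum IR length
is 1,000 bp; genomes with no pair that long are reported "IR not
detected" rather than forced into a quadripartite model. A quadratic
all-pairs oracle (`brute_force_ir_pair`) exists solely to verify the
detector on small circles.

G/C fractions count G+C over A+C+G+T; N is excluded from numerator and
denominator so undetermined sequence does not dilute composition.

## Gene order

Signed orders are circular sequences of (symbol, orientation). IR
duplicates are collapsed to the IRA copy before comparison (duplicate
symbols otherwise make the order ill-defined and raise an error). All
comparisons first restrict both genomes to their shared symbols, logging
what was dropped, since lineage-specific gains/losses are not
rearrangements. The breakpoint distance counts signed adjacencies of one
order missing from the other, with (x→y) matching (−y→−x); it is
symmetric and zero exactly on rotation/flip equivalence classes. Synteny
blocks are maximal runs co-linear in both genomes on the *circle* — a run
that continues across the arbitrary sequence origin is one block — and a
block is "inverted" when its genes appear in the partner genome in
reversed order with flipped orientations. Inverted blocks are reported
descriptively as inversion candidates with their endpoint genes; no
minimal reversal scenario (sorting by reversals) is attempted, because the
analyses this package supports identify individual shared inversions, not
rearrangement distances. Translocations are shared genes whose region
label (LSC, SSC, IR, or an IR-partial class) differs between genomes.

## Indel coding and classification

Simple indel coding: every distinct internal gap span (identical start and
end columns) observed in at least one taxon is one character. A taxon
scores 0 with exactly that gap, 1 with nucleotides at every column of the
span, and ? otherwise — in particular when its own gap strictly contains
the span, which makes nested gaps well defined. Leading and trailing
terminal gaps are missing data, not events. Spans intersecting the
alignment's excluded-column set yield no characters, and characters
lacking both a 0 and a 1 among non-missing states are dropped. Labels are
`<gene>_<1-based start column>` from the alignment's partitions.

Classification uses Hartigan's generalization of Fitch small parsimony
(correct on multifurcating trees): at each internal node the state votes
of the children are tallied and the shortfall from unanimity is the added
step count; ? states are free. Steps are root-invariant. For single-step
characters the change edge is located as a leaf bipartition separating all
definite-1 from all definite-0 leaves; with missing data several edges can
qualify and the one with the smallest reported side is chosen (ties:
lexicographic). The reported "clade" is one side of an unrooted split —
either side names the same edge. A pendant change edge means
autapomorphic, an internal one synapomorphic, ≥2 steps homoplastic, and a
character with only one observed state is invariant. A tree-free
autapomorphy count (minority state in exactly one taxon) is provided as a
cross-check; it equals the tree-based count for characters without
missing data on any tree containing all taxa. Taxon labels are reconciled
to tree leaves through an explicit label map rather than guessed.

## Codon usage

ENc uses the per-family codon homozygosity F = (n·Σpᵢ² − 1)/(n − 1) and
class averages F̂ₖ over families of synonymy degree k; under the universal
code (the default; the bacterial/plastid code 11 is configurable and
changes the family structure) ENc = 2 + 9/F̂₂ + 1/F̂₃ + 5/F̂₄ + 3/F̂₆,
capped at 61. Families observed fewer than twice are left out of their
class average; an empty threefold class falls back to (F̂₂ + F̂₄)/2; any
other empty class leaves ENc undefined (reported as NaN in tables).
These fallbacks follow the conventions long used by codon-usage tools.
Exactly uniform usage gives finite-sample F below 1/k, hence a raw value
above 61, hence the cap; a single codon per amino acid gives F = 1 in
every family and ENc = 20 exactly. Per-taxon reports pool codon counts
over all genes of the concatenation (one value per taxon, not a per-gene
average), remove excluded columns and gaps first, skip codons containing
N, and insist the remainder is a whole number of codons.

## Pseudogene and editing screens

The pairwise screen aligns a candidate region to an intact reference CDS
globally with affine gaps (match +1, mismatch −1, open −5, extend −1 —
stated because published descriptions rarely pin these down; a
precomputed alignment can be supplied verbatim instead). Percent identity
divides identical columns by *all* alignment columns, gaps included — a
deliberate, logged choice since "similarity" is ambiguous otherwise.
Indel events are maximal gap runs summed over both rows. Stop-codon
statistics use the reading frame projected from the reference through the
alignment, because a degraded region has no trustworthy frame of its own:
query bases are grouped by the reference codon they align to, complete
triplets are translated, and stops strictly between the first and last
reference codons are "internal". The editing scan flags annotated,
non-pseudo CDS genes whose first codon is outside the accepted start set
(default {ATG}; GTG acceptance is a flag), whose final codon is not a
stop, or which contain in-frame internal stops; summaries report both
hint loci and distinct genes with hints, since the two counts differ.
ORF finding is a straightforward maximal ATG-to-stop scan over three or
six frames with coordinates in forward-region space.

## Synthetic data

The generators exist to give every stage a known answer. All take explicit
integer seeds into Python's Mersenne-Twister `random.Random` (integer
state, platform-independent), and identical parameters + seed reproduce
byte-identical output.

- `gen_plastome` assembles LSC + IRA + SSC + revcomp(IRA). Rejection
  sampling enforces that no incidental inverted repeat of ≥ 50 bp exists
  outside the planted pair and that the planted pair cannot be extended at
  any junction, so the detector's maximal pair equals the planted one *by
  construction* — detector tests are exact, not statistical. Genes are
  non-overlapping intact CDSs; genes inside IRA get mirrored IRB
  annotations; optional genes straddle the LSC/IRA and IRA/SSC junctions;
  optional genes carry ACG starts as planted editing hints. Intergenic
  composition compensates gene content so genome-wide G/C lands within one
  point of the target. Defaults (LSC 4000 / SSC 1500 / IR 1000 bp, 20
  genes, G/C 0.35) keep the region-size ratios of real plastomes at a
  scale where the whole suite runs in seconds.
- `gen_rearranged_pair` applies non-overlapping, non-adjacent signed block
  reversals and region relabelings to a random signed circular order,
  recording endpoints; non-adjacency guarantees k reversals produce
  exactly k inverted blocks.
- `gen_indel_alignment` drops Poisson-distributed deletion events on
  non-root branches of a supplied tree; each event removes a span (a
  multiple of 3 starting on a codon boundary in frame-preserving mode,
  mirroring the 3-bp indels typical of coding genes) from all leaves below
  the branch. Spans are globally disjoint with distinct boundaries, so
  simple coding yields exactly one character per event and the planted
  category (pendant → autapomorphic, internal → synapomorphic) is
  recoverable without ambiguity.
- `gen_codon_seq` interpolates codon sampling between uniform-within-family
  (bias 0) and a single preferred codon per amino acid (bias 1), with an
  ATG start, stop-free interior and one terminal stop. Bias 1 forces
  F = 1 in every observed family, hence ENc = 20 exactly.

What the generators do *not* emulate: realistic substitution processes
(flanks are i.i.d. sequence), overlapping or nested rearrangements,
recombination-driven IR boundary shifts, genuine RNA editing, or the
length and gene-density of real 130–160 kb plastomes. Passing the
recovery tests therefore shows the algorithms are correct on their own
definitions, not that annotation noise, near-identical repeats, or
alignment error in real data are handled gracefully.

## Verification scale and budgets

The parsimony implementation is checked exhaustively against a
brute-force minimum over all internal labelings for every unrooted
topology and every binary leaf labeling through 6 leaves (1 + 3 + 15 +
105 topologies), and on sampled topologies and labelings at 7–8 leaves;
exhausting all 10,395 8-leaf topologies is beyond a reasonable test
budget in pure Python and adds no distinct structure. Planted-IR and
planted-reversal recovery are asserted at 100/100 seeds. Simulation sizes
throughout the suite (1–2 kb regions for oracle comparisons, 7.5 kb
genomes, 8-taxon trees, 3 × 60-codon gene sets) were chosen so the whole
suite completes in well under a minute while every check remains exact.

## Known limitations

- IR detection assumes exact repeat identity; real IR copies occasionally
  differ by a few substitutions, which would shorten the detected maximal
  exact pair relative to an annotation-based IR. When the two disagree,
  both values should be reported (the detector gives the exact-repeat
  answer only).
- Simple indel coding is one of several published coding schemes; counts
  from multi-state or complex coding will differ, particularly for
  overlapping gaps.
- The single-step clade report is relative to the one supplied tree;
  characters mapping differently on rival topologies are the caller's
  concern.
- Percent identity and ENc both have convention choices (denominator,
  included sites) that shift values by fractions of a unit; the
  implementations state theirs and keep them configurable where it
  matters.
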