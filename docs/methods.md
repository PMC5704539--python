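# Methods

This note documents the models and procedures `baitsfinder` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic data can and cannot demonstrate.

## Homology search engine

All searches in the pipeline are desk-scale (tens to a few thousand
sequences), so an internal engine replaces an external BLAST binary; BLAST
remains pluggable, since every downstream stage accepts 12-column
`outfmt 6` tabular input.

**Programs.** `blastx_like` translates nucleotide queries in all six
reading frames and compares them against protein subjects (alignment
lengths, mismatch counts and subject coordinates in amino acids; query
coordinates in nucleotides on the forward strand). `blastn_like` compares
nucleotides on both query strands. Reverse-frame/strand hits are flagged by
`s_start > s_end`; query coordinates always ascend.

**Seeding.** Subjects are indexed by exact k-mers (k = 3 for protein,
k = 11 for nucleotide). A query/subject pair becomes a candidate when it
shares at least three 3-mers on one diagonal (protein) or one 11-mer
(nucleotide). The three-on-one-diagonal rule matters: almost every random
protein pair shares one or two 3-mers somewhere, whereas any hit that can
pass the downstream thresholds (≥ 100 aligned aa at ≥ 40 % identity) is
expected to carry ~6 exact 3-mer matches on its alignment diagonal, so the
rule prunes noise without costing reportable hits. The engine therefore has
a sensitivity floor: pairs whose only similarity is far below the reporting
thresholds may be missed, which is irrelevant to the pipeline's decisions.

**Alignment and scores.** Candidate pairs are aligned in full by an
affine-gap local alignment (gapped mode) or with a prohibitive gap cost
(ungapped mode), which reduces the optimum to the best ungapped segment
pair. The actual dynamic programming is delegated to Biopython's
`PairwiseAligner`; exhaustive textbook Smith–Waterman and
best-ungapped-segment implementations live in the test suite and verify the
engine's scores on seeded pairs. Scoring defaults are BLAST-like: BLOSUM62
with gap open 11 / extend 1 for protein, match +2 / mismatch −3 with gap
open 5 / extend 2 for nucleotide. Bit scores use a single fixed
Karlin–Altschul pair (λ = 0.318, K = 0.13) and
E = m·n·2^(−bit) with n the summed subject length. These statistics make
E-values comparable within a run; they are not calibrated to NCBI BLAST's
composition-adjusted values. The search reporting cutoff is E ≤ 1e-10; the
stricter 1e-20 is applied later at COS assignment, mirroring the two-stage
search-then-parse flow.

**Identity.** Percent identity counts exact residue matches over all
alignment columns (gap columns included); IUPAC ambiguity codes never count
as matches — a conservative choice that only ever pushes a sequence below a
keep-threshold, never above.

## Reference build

Thresholds for the single-match screen, the self-deduplication and the
two-species merge default to the same triple used for COS assignment
(identity ≥ 40 %, E ≤ 1e-20, ≥ 100 aa), keeping one coherent stringency
ledger; each is configurable. Self-deduplication removes *both* members of
a similar pair rather than keeping a representative: retaining either would
risk keeping a gene with a hidden paralog, and the goal of the reference is
orthology certainty, not completeness.

## COS assignment and screens

Best hit = maximum bit score, with deterministic tie-breaking (lower
E-value, longer alignment, lexicographically smaller subject id). All three
thresholds are inclusive bounds.

The paralog screen works on subject (reference protein) coordinates:
fragments of one transcript occupy disjoint parts of the reference and are
tolerated, whereas two same-taxon transcripts covering the same reference
region by more than the cutoff (default 30 aa) indicate duplication, and
the whole (taxon, gene) group is removed. The locus may persist through
other taxa. Removal is group-wise, not best-member retention — strictness
over yield.

The host screen removes assignments with any blastn-like hit at ≥ 95 %
identity against the host database, with no minimum alignment length. It
runs *before* the paralog screen so that a host transcript and a genuine
ortholog assigned to the same gene are not mistaken for a paralog pair.

## Locus alignment

The reference CDS is inserted as the first row of every locus alignment:
exon projection needs the reference's gap structure, so the anchor row is
structural, not optional. Members whose retained hit is on the reverse
strand/frame are reverse-complemented before alignment (transcriptome
assemblies are unstranded).

Two backends: external MAFFT (`--genafpair --maxiterate 1000`, the E-INS-i
settings suited to long internal gaps) and an internal reference-anchored
star aligner, which pairwise-aligns each member to the reference CDS
(local, affine gaps) and merges members on reference coordinates, placing
unaligned member overhangs as insertions. The star construction guarantees
that degapping any row reproduces its input exactly, and is accurate at the
divergences the pipeline operates at (members are by construction
threshold-passing homologs of the reference). MAFFT remains the recommended
backend for real data with complex gap structure; insertions from different
members are left-packed rather than sub-aligned by the star merge.

## Exon projection

Exon boundaries come from GFF3 **CDS features**, not `exon` features: the
aligned sequences are CDS, and UTR-bearing exons would misalign. For genes
with several mRNAs the longest CDS is chosen (a deterministic rule; the
choice is reported via per-locus exon counts so users can audit the
assumption that focal gene structure matches the reference). Cumulative
exon ends are mapped to alignment columns by counting non-gap reference
characters; the final exon absorbs trailing insertion columns. Slices are
degapped per member, and sequences shorter than the bait length (120 bp)
are dropped individually — one taxon's short fragment does not cost the
exon for other taxa. Splitting before alignment (useful when focal
exon–intron boundaries are known) is not implemented; only the
reference-projection path exists.

## Bait tiling

Baits of 120 bp are laid at starts 0, 60, 120, … while they fit; if the
last lattice bait does not reach the 3′ end, one terminal bait flush with
the end is added iff its overlap with the last lattice bait is ≤ 80 bp.
Consequences, all asserted in tests: a 160-bp fragment yields two baits
overlapping by exactly 80 bp; the smallest lengths yielding 1–4 baits are
120, 160, 220 and 280 bp; hence the fewer-than-four-baits locus filter is
equivalently a 280-bp minimum on single-exon loci. The four-bait count is
taken per anchor taxon per locus (summed over exons); with no anchor
configured the filter is disabled.

Redundancy clustering is greedy in cd-hit style: baits sorted
deterministically (locus, exon, taxon, start, member), each joining the
first cluster whose representative it matches at ≥ 90 % — counted as exact
position-wise matches over the 120 columns, in the better of forward and
reverse-complement orientation. Equal-length probes make this alignment-free
comparison sound. The organelle screen runs on the clustered baits but
removes whole loci: one bait at ≥ 90 % identity to a plastid (or, with a
different database, mitochondrial) genome discards its locus, because
organelle DNA is vastly overrepresented in total-DNA extracts and such a
locus would dominate the capture.

## Synthetic data: what it emulates, and what it does not

The generator plants, per configuration: `n_scg` true single-copy genes
(each echoed at ~5 % divergence in the SCG protein database), duplicated
pairs at ~5 % intra-pair divergence that must die in self-deduplication,
host genes built as ~10 %-diverged copies of reference genes (host plants
are plants: their conserved transcripts *do* hit the reference, which is
exactly why the 95 % host screen exists) with contaminant unigenes ≤ 2 %
from the host genes, and plastid transcripts copied from a toy plastid
genome. Focal taxa differ in substitution divergence, codon-multiple indel
rate (indels are planted in multiples of 3 at codon boundaries, isolating
the gapped/ungapped contrast from frameshift handling, which the pipeline
does not model) and fragmentation (which controls N50; the anchor taxon is
unfragmented). Unigenes are emitted on a random strand. Exon layouts are
resampled until the gene is recoverable in principle (total CDS ≥ 300 bp
and a default-tiling yield of ≥ 4 baits), so planted-truth recovery is a
property of the pipeline, not of unlucky gene sizes.

Defaults are desk-scale — 50 SCGs, 5 duplicated pairs, 4 taxa, 1–4 exons of
120–600 bp per gene — so a full run takes well under a minute. What passing
tests show: the decision logic (thresholds, screens, projection, tiling) is
exact, and the gapped-vs-ungapped contrast has the expected direction. What
they do not show: behaviour on real assemblies with sequencing error,
chimeric contigs, alternative splicing, expression dropout, or divergences
near the 40 % identity floor, none of which the generator models.

The "average locus length" statistic reported per run is the mean, over
loci in the final bait set, of the longest matched region (hit query span)
among the locus's assignments. Matched-region length is the quantity that
responds to the search mode: ungapped search truncates matches at indels,
so it recovers shorter COS regions (and consequently fewer baits), while
full-unigene length is mode-independent by construction.

## Numerical and degenerate-input choices

Inclusive threshold readings everywhere ("at least 40" → ≥ 40; "better than
1e-20" → ≤ 1e-20; overlap strictly greater than the cutoff triggers paralog
removal). Empty optional databases (host, organelle) leave the input
unchanged with a warning; an empty transcriptome or reference yields empty
results, not errors; malformed tabular lines and inconsistent GFF3 models
raise with the offending line or gene named. Floating-point output in the
tabular writer uses `repr`, so write → parse is exact. All randomness lives
in the generator, seeded explicitly; the pipeline itself is deterministic,
and rerunning an identical configuration reproduces its outputs
byte-for-byte.

## Known limitations

No thermodynamic bait QC (Tm, GC, hairpins) — pair with a dedicated bait QC
tool if needed. No translated-subject (tblastn-like) or reciprocal-best-hit
scheme. The internal engine is not bit-compatible with NCBI BLAST scores.
The star aligner does not sub-align insertions shared by several members.
Trans-splicing and focal-side intron discovery are out of scope.
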