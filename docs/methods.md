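# Methods

## Signature extraction and calling model

A structural variant leaves one of three footprints in a long-read
alignment: a gapped CIGAR operation (`I`/`D` of at least 100 bp), a pair
of split-alignment segments of the same read, or a long (≥ 500 bp)
unresolved soft clip. The 100 bp floor reflects the indel-error profile
of nanopore-class reads: per-base insertion/deletion errors are frequent
but essentially never produce runs approaching 100 bp, so gaps above the
floor are almost always genuine.

Split segments are reconstructed from `SA` tags of the primary record
(hard-clipped supplementaries therefore need no special handling). For
each adjacent pair of segments along the read: different chromosomes
give an inter-chromosomal breakend pair; opposite strands an inversion
junction; same-strand segments whose reference order contradicts their
read order a duplication-type junction (the footprint a read leaves when
crossing a tandem-duplication boundary); colinear segments with a
reference gap of 100 bp–100 kb a deletion, and with a read gap ≥ 100 bp
an insertion. Same-strand colinear gaps over 100 kb are treated as
intra-chromosomal translocation breakends. Read-interval overlaps of up
to 20 bp between segments are trimmed as alignment fuzz; pairs
overlapping by more than half of the shorter segment, and groups of
split signatures in which every read shares the identical read-coordinate
junction and strand, are dropped as chimeric-ligation artifacts (a real
junction is sampled at random read offsets).

Calling proceeds in window-based stages with these defaults:

| stage | parameter | default |
|---|---|---|
| signature floor | min indel / min clip | 100 bp / 500 bp |
| clustering | window (indel / other) | 50 bp / 100 bp |
| candidacy | reads with MAPQ ≥ 20 | ≥ 2 |
| merging | window (INS / other); reciprocal overlap | 300 / 1000 bp; ≥ 0.8 |
| support | DEL 100–500 / 501–1000 / >1000 bp | ≥ 4 / ≥ 3 / ≥ 2 reads |
| support | INS ≤ 1000 / > 1000 bp | ≥ 3 / ≥ 2 reads (or ≥ 2 clips each side) |
| support | INV / duplication / translocation | ≥ 2 reads |
| read edge filter | terminal fraction of read | 10% |
| deletion-with-insertion | nearby-insertion fraction (<1 kb / ≥1 kb) within 30 bp | 10% / 30% |
| region filters | low-MAPQ fraction (< MAPQ 30); VAF | ≥ 30%; < 0.03 |
| repeat filter | short-repeat cover of span | ≥ 80% |
| population merge | allele frequency; homozygous VAF | ≥ 0.1; ≥ 0.7 |
| somatic | matched-normal depth; breakend merge | ≥ 9; 500 bp |

Insertions have zero-length reference intervals, so the ≥ 80% reciprocal
overlap used for merging is replaced by a length ratio
min(L₁,L₂)/max(L₁,L₂) ≥ 0.8. The low-MAPQ region check samples spanning
reads at each breakpoint and ± 500 bp around it (the same scale as the
consensus flanks); depth for VAF counts every read spanning the
breakpoint regardless of MAPQ. Allele counting for the population merge
maps VAF ≥ 0.7 to two alleles and anything below to one; this
reproduces the intended behaviour (three heterozygous carriers of eleven
samples clear the 0.1 frequency cut, two do not) and is isolated in one
function since the mapping is a convention, not a measurement.

Large insertions deserve one extra rule: a multi-kilobase insertion is
rarely spanned end-to-end by a read, so a cluster with a single
insertion-bearing read is still promoted to candidacy when ≥ 2 reads are
long-clipped on *each* side of the insertion point. Pure clip-only loci
(no spanning read at all) are not called — the insertion length would be
unknown — which is a recognised limitation at low coverage.

Somatic calling reuses the full germline detection on the tumor (with
inter-chromosomal junctions enabled) and removes candidates with any
read-level evidence in the matched normal (a single normal read
suffices; specificity is favoured over sensitivity), candidates present
in the pooled normal panel under the same identity rule, and candidates
where the matched normal has depth < 9 (too shallow to exclude a missed
germline variant). The ≥ 80% short-repeat filter extends to deletions at
the somatic stage, and the segmental-duplication filter to all types.
The manual-review step of somatic pipelines is replaced by a
machine-readable per-call read-evidence table (`write_review_report`);
no attempt is made to emulate a human reviewer.

## Consensus sequences

Support-read segments (event ± 500 bp in read coordinates, all in
reference orientation) are star-aligned: the backbone is the
median-length segment (upper median on even counts), every other segment
is aligned to it globally with edit-distance (unit) costs via edlib, and
each backbone column is voted. A base or gap needs a majority (≥ 50%);
gap-majority columns emit nothing; ties resolve toward the backbone
symbol, then lexicographically. Bases inserted relative to the backbone
collect in per-position slots and are voted left-justified. One
refinement round re-aligns all segments against the first-pass consensus
as backbone, removing the vote-splitting that alignment ambiguity around
the initial backbone's own errors causes. Unit-cost alignment was chosen
for the pairwise step because it is bit-parallel and orders of magnitude
faster than affine-gap DP at 1–6 kb segment lengths, and the majority
vote is insensitive to the scoring scheme at ~10% divergence.

Validation mimics remapping the consensus to the genome: probes covering
each consensus end (flank + 100 bp) are locally aligned to the reference
window around the call, their junction-facing alignment ends are trimmed
(below), and the implied event position is compared with the call.
Insertions are accepted within 100 bp; deletions when the remapped
breakpoint interval overlaps the call. External remap results (BLAT PSL)
take precedence when supplied. Consensuses from a single read are
emitted but flagged low-confidence and never accepted.

At ~10% aggregate read error with 8–15 support reads the consensus is
≥ 98% identical to truth in effectively every accepted case; at the full
~15% error profile with few (< 8) reads, a few percent of residual error
remains.

## Breakpoint anatomy and mechanism

Both reference flanks (upstream flank extending 200 bp past its
breakpoint, and symmetrically downstream) are locally aligned to the
consensus with match +1 / mismatch −2 / gap open −2 / extend −1. The
junction homology is the consensus interval covered by *both* flank
alignments; the junction insertion is the interval covered by neither.

Two numerical safeguards make these measurements exact on clean
sequence. First, the junction-facing end of each flank alignment is
trimmed back to the last run of 10 consecutive exactly matching columns,
with the run reset at every gap — this removes chance extensions past
the true junction, whose probability per column pair is ~4⁻¹⁰. Second,
because the optimal alignment can route genuine boundary bases into a
trimmed extension, the boundary is recovered by greedy exact extension
from the trimmed end. The simulator plants guard bases at every junction
boundary (the bases flanking a homologous tract or an untemplated
insertion differ from their counterparts) so that measured homology and
insertion equal the planted values exactly; on error-free fixtures the
measurement agrees with an exhaustive all-split-positions oracle.
Anatomy is undefined — and the mechanism unclassified — when either
flank aligns at < 80% identity or over fewer than 100 columns (a chance
local hit of a dozen bases reaches 100% identity trivially).

Mechanism bands: homology > 100 bp → NAHR; 2–100 bp → alt-EJ; homology
≤ 1 with junction insertion ≤ 9 bp → NHEJ; insertion ≥ 10 bp →
FoSTeS/MMBIR. The > 100 bp NAHR bound is the established definition; the
2 bp microhomology floor and the 10 bp templated-insert cut follow the
conventions of prior breakpoint-anatomy studies and are single
configurable constants (`MechanismThresholds`). A chi-square test
(`scipy.stats.chi2_contingency`) compares mechanism proportions between
two callsets (e.g. germline vs somatic).

## Ancestral events

Anchors are placed 100 bp outside each breakpoint; the ratio
r = (d_outgroup − 200)/(d_reference − 200) is ~0 when the outgroup lacks
the intervening sequence and ~1 when it carries it, with bands
[−0.3, 0.3] and [0.7, 1.3] and anything else unclassified. For
reference-based insertions the breakpoints coincide and the denominator
degenerates to zero; the event length — the separation the anchors would
have in the carrier genome — takes its place, preserving the 0/1 band
semantics. Lift-over itself is out of scope: anchor distances arrive as
a TSV (the simulator writes one consistent with each spiked event's
intended label).

## Benchmarking

Calls match truth records one-to-one, greedily by increasing breakpoint
distance, requiring the same type and distance < 500 bp; the distance is
the maximum over both breakpoints by default (start-only is a flag).
Greedy matching prevents double counting and attains the maximum
bipartite matching on well-separated sets (asserted against a
Hopcroft–Karp oracle in the tests). Duplication-signature junctions and
explicit duplication records are the same event class for matching. An
empty callset reports precision 0 with a degenerate flag rather than
NaN.

## What the simulator emulates — and what it does not

The generator builds a uniform-random reference with planted SINE-like
(~300 bp) and LINE-like (~6 kb, mostly 5′-truncated) element copies at
~2% divergence from fixed internal family consensus sequences,
tandem-repeat tracts, and optional pairs of identical tracts as
recombination substrates. Donor haplotypes are block lists over the
reference, so reads sampled from them carry *exact* truth alignments:
CIGARs, split records and SA tags are emitted directly from the
coordinate bookkeeping, never from a mapper. Read lengths are log-normal
(mean ≈ 5.5 kb, σ_log 0.55, floor 600 bp, matching typical genomic
nanopore libraries); errors are independent per-base substitutions
(5.2%), insertions (4.4%) and deletions (6.6%), the deletion-dominated
profile of nanopore data. Viral insertions are marked unmappable so
their bases appear as soft clips, emulating an aligner that cannot place
viral sequence on the host reference. SVs keep ≥ ~12 kb from sequence
ends, where physical coverage tapers.

Consequences for interpretation: mapping errors do not exist here (truth
alignments), so the low-MAPQ and segmental-duplication filters are
exercised only by crafted unit fixtures, and precision on simulated data
overstates precision on real alignments. Error independence means no
homopolymer-length biases or strand effects; repeat landscapes are far
sparser than a real genome's; and the chimeric-read artifact filter
confronts no true chimeras. Passing tests therefore demonstrate the
correctness of the calling logic and its thresholds, not performance on
real data.

Problem sizes were chosen so that each end-to-end scenario runs in
seconds to a couple of minutes on one core: the standard germline
scenario is 1 Mb at 20x with 60 SVs (20 deletions, 20 insertions, 10
inversions, 10 tandem duplications; alternating homozygous/heterozygous);
the somatic scenario 600 kb at 20x with 20 shared and 10 private SVs;
consensus recovery 50 insertions of 100–5000 bp with 8–15 reads. Panels
shrink proportionally for smaller references.

## Degenerate inputs and determinism

Empty SAM files yield empty callsets; records with malformed CIGARs or
SA entries are skipped with a warning count; a missing sequence header
is fatal. Empty repeat annotations disable the repeat filters rather
than erroring. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; outputs carry no timestamps, and identical
configuration plus seed reproduces byte-identical SAM/VCF/JSON outputs.
VCF output is 4.2 with symbolic ALTs (`<DEL>`, `<INS>`, `<INV>`,
`<DUP>`) and paired `BND` records for inter-chromosomal junctions;
internal coordinates are 0-based half-open and convert at the boundary.

## Known limitations

* Clip-only large insertions (no spanning read) are not called.
* Inversion and duplication consensus sequences are built but not
  remap-validated (the validation rules are indel-specific).
* The chimeric-artifact heuristic is a stated approximation; real
  ligation chimeras may differ.
* The VAF → allele-count mapping for population frequencies is a
  convention; genotype likelihoods are out of scope.
* Breakpoint-anchor lift-over to an outgroup genome is consumed as a
  table, not computed.
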