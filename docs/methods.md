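# Methods

## The problem

A full-length cDNA clone carries one complete mRNA-derived insert.
Sequencing hundreds of clones cheaply is possible by pooling their PCR
amplicons, shotgun-sequencing the pool as millions of short (36 nt)
single-end reads on one flow-cell lane, and reassembling each clone
computationally.  Pure de novo assembly of such short reads yields
fragmented contigs; pure reference-guided assembly cannot place exons
shorter than the read length without splitting reads, which destroys
alignment specificity.  `clonefinish` implements the hybrid strategy:
contigs from an external de novo assembler are *anchored* on a
reference genome, *merged* where they overlap there, *repaired* by
aligning raw reads into short inter-contig gaps (exon filling) and by
split-read spliced alignment across longer gaps (intron recovery), and
finally *assigned* to physical clones via Sanger end reads.

## Pipeline stages and their rules

**Anchoring.**  Each contig is spliced-aligned to the genome by a
seed-and-chain aligner (12-mer exact seeds, co-linear chaining with
intron-sized target gaps allowed, per-segment refinement by banded
global alignment via edlib).  Only a uniquely best-scoring placement is
kept; exact score ties are discarded as repetitive, mirroring the rule
that a contig with ambiguous placement cannot be trusted.  Erroneous
short terminal exons — shorter than L = 12 bp and further than D = 5 bp
from their neighbour — are pruned iteratively to a fixpoint.

Two guards keep chaining honest on desk-scale genomes: an intron-sized
join requires exact runs of at least 15 bp on both sides, and a chain
whose mean exon length is under 25 bp is rejected as seed noise.
Without them, stray 12-mer hits chain genome-wide and short junk
contigs acquire "alignments" that fuse unrelated genes at the merge
step.

**Strand policy.**  A cDNA contig is emitted by the assembler in an
arbitrary orientation, so alignment strand carries no information about
the transcript.  Anchored contigs are therefore stored on the forward
genome strand and merging/gap logic ignores strand entirely; transcript
orientation is decided at clone assignment, where the 5' end read must
align forward (and the 3' read reverse) on the oriented sequence.

**Merging.**  Contigs sharing at least one genomic base pair, or
abutting with a zero-base gap, merge (transitive closure).  The merged
exon chain is the interval union; in sequence overlaps the base comes
from the contig with the higher alignment score (ties: longer contig,
then id) — deterministic and order-independent.

**Exon filling.**  A gap of at most `exon_gap_max` (1,000 bp) between
genome-adjacent contigs is an exon gap candidate.  Raw reads are
aligned to the gap extended by `ext` = 50 bp into both flanks, with at
most `fill_max_discrepancies` = 3 mismatches/indels, using a
pigeonhole-seeded aligner that provably finds every placement within
the edit budget.  Only uniquely placed reads count.  The gap fills only
when every base of the gap proper has unique coverage >= `e_min` = 2
reads; the fill sequence is taken from the reference genome (the reads
certify coverage; taking reference bases is deterministic and avoids
re-calling a consensus the de novo stage already failed to produce).

**Intron recovery.**  A longer gap (40 bp – 500 kb; the bounds are
package choices, exposed in `Params`) is an intron gap candidate.  Each
read — after a poly-A prefilter (discard if an A-run longer than 12 bp
or an A fraction above 50% in either orientation) — is split at every
position leaving both parts at least 13 bp (11 of the 35 possible
splits of a 36-mer).  Parts are aligned, mismatches only and at most
one per part, to the two 2W-bp (W = 50) boundary candidate regions
centred on the facing contig ends.  A valid pair places the 5' part in
the left region and the 3' part in the right region in one orientation.
Per read, pairs needing a mismatch are dropped when a perfect pair
exists (a mismatch can otherwise buy a junction one register off), the
implied junctions are left-aligned through any microhomology, and a
read supporting more than one distinct junction is discarded.  The
junction with most support (>= `min_intron_support` = 1) links the
contigs; no intronic sequence is inserted.

**Clone assignment.**  Sanger end reads are aligned to the final
contigs; alignments shorter than 30 bp or under 90% identity (identity
= matches / aligned columns including gaps) are discarded; each clone
goes to its best-scoring contig.  A clone with no surviving alignment
is "not amplified by PCR".  When a truncated contig end leaves at least
10 bp of a Sanger read unaligned beyond the terminus, that overhang is
grafted on (contig bases win inside the overlap); extensions with more
than 10% N are refused.  Contigs no read supports move to a secondary
output.  A clone whose two end reads best-match different contigs keeps
the better one and is flagged as carrying an internal gap of unknown
size; the evaluator then treats the two contigs as unlinked sub-chains.

## Evaluation

**CDS-structure consistency.**  A reconstruction is *consistent* when
every reference CDS exon lies inside a reconstructed exon and internal
CDS junctions coincide exactly; terminal CDS exons need containment
only.  Failures are classified with precedence: wrong exon boundary >
gap inside an exon > missing clone end > missing link between exons.
Both the reconstructed chain and the reference CDS structure are
obtained by aligning the respective *sequences* to the genome with the
same aligner, so junction-register ambiguity in microhomologies cancels
instead of producing false boundary failures.  The truth generator's
coordinates are used only to locate the CDS within the reference
transcript.

**Base accuracy** is a global (Needleman–Wunsch, unit-cost) alignment
of output versus finished reference; insertions are output-only bases,
deletions reference-only.  The CDS-level match ratio is computed for
consistent clones against the reference CDS subsequence.

**Coverage analysis.**  Per-clone coverage is (#reads aligned to the
clone x 36) / clone length, with reads counted by seed-verified
alignment at up to 3 mismatches.  Clones are binned in 10-fold coverage
bins; the titration harness re-assembles downsampled read sets
(fractions 0.1–0.9 in steps of 0.2 plus the full set — a problem-size
choice; the binning makes the fraction grid immaterial) and pools
(coverage, verdict) pairs across fractions.

**Cost model.**  Per-clone consumables cost of the short-read
multiclone approach is run_cost / usable_lanes / clones_per_lane /
pcr_efficiency / accuracy + sanger_cost; companions cover the
Sanger-era multiclone shotgun (reads to a target coverage plus custom
primers) and one-run amplicon shotgun on a long-read 454-class
instrument.  All rounded to cents.

## The synthetic study

`simulate.generate_world` lays out non-overlapping multi-exon genes on
a random genome: 2–8 exons, introns 100–2,000 bp, spliced lengths
1,200–2,900 bp (mean ≈ 2 kb), UTRs 60–250 bp, and a configurable
fraction (default 14%) of clones carrying one exon of 15–35 bp —
shorter than the read length, the case that motivates the hybrid
approach.  Clone sequences equal the spliced genome (no polymorphism
between clone library and reference is modelled).  Shotgun reads
(`shotgun_reads`) draw per clone: a Bernoulli PCR success (default
0.79), a lognormal amplification factor (default sigma 0.6, matching
the wide observed per-clone coverage spread; the law itself is a
stand-in), read starts with a linear density ramp from zero over 150 bp
at each molecule end (nebulisation is inefficient near ends), random
strand, and i.i.d. substitution errors (default 0.005/base; indel
errors are off by default as substitutions dominate on this platform).
Sanger ends are a 5' prefix and reverse-complemented 3' suffix of
400–800 bp at 1e-3 error.  Everything is deterministic under the
config seed via per-purpose derived streams.

Two de novo stand-ins are provided because external assemblers are an
input, not a dependency: a deliberately simple canonical-k-mer de
Bruijn unitig assembler (k = 25, k-mers seen < 2 times discarded,
contigs < 100 bp dropped — fragmentation then emerges exactly where
coverage dips, which is what the reference-guided stages repair), and a
truth-slicing fragmenter with dropout for tests needing controlled
fragmentation.

What passing on this material does *not* show: robustness to
polymorphism between library and reference, to chimeric clones or PCR
chimeras, to genomic repeats (the random genome is nearly repeat-free),
or to platform-specific error profiles (quality-by-cycle, indels).

## Numerical and procedural choices

- Coordinates are 0-based half-open internally; BED stays 0-based,
  GFF3 converts to 1-based, PSL matches the internal convention
  (minus-strand query coordinates in the reverse-complemented frame).
- Alignment score is matches − mismatches − one point per gap opening
  (introns included); only the induced order matters (best hit, ties
  repetitive).
- Junction ambiguity resolves to the leftmost donor placement
  everywhere (chain trimming, splice-fill canonicalisation), so
  independent routes to the same intron agree.
- Terminal alignment extension past the last seed is greedy
  score-maximising (+1 match / −2 mismatch): genuinely foreign query
  tails (e.g. the first bases of the next exon on a contig that ends
  just past a junction) stay unaligned rather than being forced onto
  the genome.
- N50 is the classic "sorted descending, cumulate to half the total"
  statistic; assembly selection by N50 breaks ties by total length,
  then input order.
- Degenerate inputs: empty contig sets produce empty outputs and
  zeroed stage rows; a read longer than `ext` − 3 is a configuration
  error naming the parameter to raise; a clone map row without a
  matching FASTA record is ignored.

## Problem sizes

The default test suite and the acceptance script run the study at 100
clones on a ~2 Mb genome (~280k reads), with the titration at five
downsampled fractions; unit tests use 8–20 clones on 200–500 kb.  These
sizes keep full runs in the minutes range on one core while preserving
every failure mode the larger study exhibits (seed-noise chains,
end-depletion truncation, junction-adjacent errors).

## Known limitations

- The consensus of merged overlaps prefers one contig rather than
  voting per column; an error in the preferred contig survives (and, if
  adjacent to a junction, can shift the apparent register — the main
  residual inconsistency class on synthetic runs, a few percent).
- Interior contig errors cannot be corrected by Sanger evidence
  (contig bases win in overlaps by design).
- Exons lying wholly inside an intron gap are not discovered; such
  links are junction-level joins only.
- Chimeric clone detection is out of scope.
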