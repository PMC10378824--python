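# Methods

This note records the models, conventions, parameter choices and known
limitations behind `sbscan`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

A genome is a circle; internally every feature is a 0-based half-open
interval whose `start` lies in `[0, length)` and whose `end` may exceed
`length` to denote an origin-spanning feature (interpreted modulo the
length).  Rotation is never applied automatically — deposited circular
sequences have a fixed registration, and silently re-rotating them would
desynchronize coordinates from the user's records; an explicit
`CircularSequence.rotate_to(p)` exists for controlled re-registration.  GFF3
output is 1-based inclusive, with wrapped features emitted as two part-lines
sharing an `ID` (GFF3 has no native circular encoding).  `N` is tolerated on
input but is deliberately inert: it is excluded from GC numerator and
denominator, and it never matches any motif symbol (ambiguity in the data
must not create annotations).

## ORF prediction (`orf_scan`)

Both strands are read from a tripled copy of the genome; stops occurring in
the middle copy are each considered once, which gives every stop a full
genome turn of upstream context, and results are deduplicated by (strand,
stop position mod length).  Per stop, the reported ORF begins at the most
upstream in-frame start after the previous in-frame stop (the longest-ORF
rule of standard ORF finders).  Start codons default to the bacterial
standard-code initiators {ATG, GTG, TTG}, all translated as Met.

`nt_length` *includes* the stop codon, so `aa_length = nt_length/3 − 1`; this
convention makes the usual paired size ranges for these genomes
(894–987 nt ↔ 297–328 aa) internally consistent.  The scan floor is 75 nt and
the reporting cutoff 95 aa, both configurable.  An ORF candidate longer than
one genome turn (a reading frame with no stop, as in trivial repeat circles)
is rejected with a warning rather than wrapped indefinitely.

## Tandem repeats and hairpins (`repeat_scan`)

The iteron detector is seed-and-extend: for each unit length u in the search
range (default 15–30 bp), positions where a unit is followed by a
near-identical unit (vectorized Hamming profile over the tripled sequence)
seed candidate arrays; copies are chained by comparison against the *first*
copy, each full copy allowed at most 3 substitutions.  Arrays are maximal
(no full copy fits on the left within budget).  Overlapping candidates are
resolved by (more full copies, longer unit, fewer total mismatches, smaller
start); the mismatch term is needed because a frame-shifted start can by
chance satisfy the per-copy budget and would otherwise displace the clean
array on the smaller-start tie-break.  A partial terminal repeat of ≥ 6 nt
is reported under a length-prorated mismatch budget (⌊3·t/u⌋ for a t-nt
tail) and must end on a matching base.  The consensus is the column-wise
majority over full copies, ties resolved by the first copy's base.

ITR typing assigns a 22-mer consensus to the nearest catalog motif within 3
mismatches (≈86% identity; ties to the lowest catalog index) and otherwise
mints a new motif id.  The catalog ships empty and is built from data; copy
number is reported per array but never used for typing.

Hairpin folding enumerates all (offset, stem, loop) decompositions of a
motif; stems are perfect Watson–Crick DNA pairs (no wobble), the longest
stem wins, ties prefer the smaller loop.  Genome-wide inverted-repeat search
grows arms outward around every candidate spacer (≤ 50 nt), tolerating one
mismatch inside the arm but requiring the outermost pair to match, and
suppresses folds nested inside a reported fold with the same loop centre.

## Degenerate motif scanning (`motif_scan`)

IUPAC semantics: a pattern symbol matches a subject base iff the base is in
the symbol's set; a degenerate-position non-match costs one full mismatch
(no partial credit); subject `N` matches nothing.  Scans cover both strands
and the origin (the subject is extended by a pattern-length prefix).  The
default panel carries the printed origin elements: DnaA-box `ATTTTCAT`
(exact), oriT `TAAGTGCGCCCT` (≤1 mismatch), dso nick `CTTGATA` (exact),
CS-6 `TAGCGW` (exact), viral nonanucleotide `WADTTATAC` (exact) and the
12-bp inverted motif `TAAATGCTTTTA` (exact).  `build_consensus` returns, per
column, the minimal IUPAC code covering the union of observed bases, so
every input motif matches the output with zero mismatches.

## Origin annotation (`origin_annot`)

*AT-rich regions.*  Every 20-nt sliding window with GC ≤ 0.30 qualifies;
overlapping qualifying windows merge into runs, and runs covering ≥ 40 nt
are loci.  A window straddling a low-GC boundary qualifies on the strength
of its low-GC half, so the raw union overstates the region by about half a
window per side; reported boundaries are therefore the *centres* of the
outermost qualifying windows.  Even so, boundary noise is asymmetric — any
error adds bases from the 36–42% background — so the reported mean GC of a
planted 23%-GC region averages about one point high.  The defaults were
chosen so that a 55-bp region at ~23 mol% GC inside a 36–42% background is
always called; at these settings sub-threshold background fluctuations also
produce additional loci (several per 2-kb genome), which is why the
classifier treats "AT-rich present" as weak evidence to be combined, never
as a call by itself.

*DnaA pair.*  Within an AT-rich locus (±10 nt), the closest opposite-strand
pair of DnaA-box hits whose intervals overlap by ≥ 1 nt.  The synthetic
construct `ATTTTCATGAAAAT` realizes one hit per strand with a 2-nt overlap;
the overlap observed in real sequences (a single G/C) cannot be reproduced
exactly from an 8-mer containing no G, so the detector accepts any ≥ 1-nt
overlap and records the observed geometry.

*dso / sso.*  A dso locus is an exact nick-heptamer hit with 30-nt flanks
kept for reporting.  An sso requires structural context: a CS-6 hit lying
entirely inside the loop (6–30 nt) of a hairpin with perfect arms ≥ 5 bp;
candidates are ranked by upstream proximity to a given dso, where "upstream"
on a circle is the arc ending at the reference start.  An oriT hit (≤ 1
mismatch) does *not* require its adjacent inverted repeats; they are
attached as evidence when found within 100 nt — mirroring the different
strengths of structural support the two elements have in these genomes.

*Viral nonanucleotide.*  Requires the 9-mer inside a 10–13-nt hairpin loop
within a 25–40-nt element (the canonical ~32-nt CRESS stem-loop); the
12-bp inverted motif of group-1 genomes folds with only a 4-nt loop and so
can never satisfy this geometry.

## Classification (`classify`)

The call is a pure function of the evidence.  GROUP1 = exactly one Rep-sized
ORF (270–332 aa) AND an ITR array AND (12-bp motif OR AT-rich region).
GROUP2 = a Rep-sized ORF (333–460 aa) AND dso AND sso.  The outer bounds
widen the observed ranges (297–328, 338–438 aa) by roughly 10% so boundary
genomes do not flip on one codon; between the groups the observed ranges are
disjoint, and the decision boundary sits at their midpoint (333 aa) rather
than letting the windows overlap.  Overlapping windows would let a group-1
genome whose Rep falls in the overlap satisfy both groups whenever a chance
`CTTGATA` (expected ~0.4 occurrences per random 2-kb circle) and a chance
CS-6-in-hairpin co-occur — a few percent of genomes — and conflicts are
never resolved by force: both-minimums-met yields UNCLASSIFIED with both
evidence sets.  Verdicts: RCR_LIKE iff dso∧sso; THETA_LIKE iff
ITR∧AT-rich∧DnaA-pair∧¬dso; VIRAL_LIKE iff a nonanucleotide stem-loop;
anything else, or more than one condition at once, is INCONCLUSIVE.  The
two small group-2 ORFs (90–160 aa window) contribute to the evidence score
only.  Pfam/homology assignment is explicitly *not assessed*.

## Phylogeny (`treebuild`)

Uncorrected p-distances (gap-vs-gap columns ignored; gap-vs-base counts as a
difference by default) feed a standard neighbor-joining implementation with
deterministic lowest-index tie-breaks; negative branch lengths are clamped
to zero and flagged.  NJ with p-distances deliberately stands in for
maximum-likelihood fitting: this module exists to test tree construction and
clade/motif concordance, not to reproduce published topologies, and NJ is
provably exact on additive matrices, which is what the property tests
exercise (alongside a cross-check against scikit-bio's independent NJ).
Bootstrap support resamples alignment columns (default 250 replicates) and
reports per-internal-edge bipartition frequencies.  Clade/ITR-motif
concordance takes the smaller side of each internal edge; purity is the
modal motif frequency over the clade size, and the overall statistic is the
mean over clades with ≥ 2 leaves (a tree with no internal edge contributes
its full leaf set).  Alignment is an external input; only equal-length
synthetic sequences are handled without an aligner.

## Synthetic genomes (`synth_data`)

The generator's defaults are the study conditions: group-1 genomes
1665–2522 bp at background GC 0.36–0.40 with the feature order AT-rich →
12-bp motif → ITR array → oriT → Rep ORF (894–987 nt) → optional second ORF
(303–660 nt, probability 0.25, matching 2 of 8 observed); group-2 genomes
2299–2442 bp at GC 0.38–0.42 with sso hairpin (8-bp arms, 12-nt loop) →
dso → Rep ORF (1017–1317 nt) → two small ORFs (111–145, 96–107 aa),
overlapping by one nucleotide with probability 0.5 ("sometimes
overlapping").  Lengths and sizes are drawn uniformly from the printed
ranges; spacers divide the remaining length at random; the finished circle
is rotated by a random offset so features regularly span the origin.

Constructions that make planted truth exactly recoverable:

* every planted ORF is preceded by an in-frame stop, so the longest-ORF rule
  recovers exactly the planted start; ORF bodies are sense codons drawn with
  base-composition weights at the background GC (uniform codons would push
  coding-dense genomes to ~48 mol% GC, far outside the observed range);
* the ITR array carries guard bases at both edges chosen to break period
  continuation (flanking background would otherwise extend the array by
  chance ≈26% per base, making the planted unit/copies/tail triple
  non-unique);
* the AT-rich segment realizes its composition as an exact count (13 GC in
  55 bp) rather than in expectation — an i.i.d. draw misses the target by
  enough to make the region undetectable in roughly one genome in 400;
* hairpin loops keep their terminal bases non-complementary so the planted
  (arm, loop) geometry is the fold's true optimum;
* overlapping small ORFs share exactly one nucleotide: the second ORF's ATG
  begins on the final A of the first ORF's TAA stop.

`mutate_features` applies seeded per-base substitutions (always to a
different base) strictly inside planted features and records every change in
the truth record; it drives the robustness/monotonicity tests.

What the generator does **not** emulate: dinucleotide/codon structure of
real genomes, homology of Rep ORFs to real Rep proteins, sequencing error,
amplification chimeras, or host contamination.  Passing tests therefore
demonstrate detector correctness on planted ground truth under realistic
composition — not performance on real isolates, where boundary cases
(diverged iterons, degenerate origins) are harder.

## Problem sizes and determinism

All randomness flows through explicit integer seeds (numpy `default_rng`);
identical inputs, configuration and seed give byte-identical outputs.  The
shipped suite uses: 100 seeded genomes for exact ITR-triple recovery and for
AT-rich recovery, 200 genomes per class for end-to-end label recovery at
mutation rate 0, 60 genomes per class at rates {0, 0.12, 0.45} for
monotone degradation, brute-force oracle equality on sequences ≤ 300 nt, and
NJ additive-recovery up to 12 taxa — sizes chosen so the full suite runs in
well under a minute per heavy test on a single core while keeping every
statistical claim at a sample size where it is stable.

## Known limitations

* dso detection is the exact nick heptamer plus reported flanks; alignment
  against reference plasmid dso regions is supported only if the user
  supplies those flank sequences (they are figure-bound in the literature).
* The 14 published ITR consensus motifs are not machine-readable here; the
  catalog starts empty and is built from data, so motif *ids* are
  dataset-local.
* The classifier's feature minimums are a reconstruction — the source
  characterization never states a minimal feature set — and are fully
  configurable.
* Reported AT-rich mean GC carries ~+1 point of boundary bias by
  construction (see above); consumers needing unbiased composition should
  re-measure GC over their own interval of interest.
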