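# Methods

This note documents the statistical procedures, the tunable parameters and
their defaults, the synthetic-data model, and the numerical/design choices
made where more than one reasonable convention exists.

## Coordinates and formats

All internal coordinates are 0-based half-open; SAM (1-based) and GTF
(1-based closed) are converted at the I/O boundary only.  SAM/BAM parsing
goes through pysam; reads are grouped by name, so both name-grouped and
coordinate-sorted inputs work.  Mismatch typing uses, in order of
preference: extended CIGAR (`=`/`X`) ops, the MD tag (reconstructed via
pysam's aligned-pairs machinery), or — during error profiling — direct
comparison of SEQ against the reference genome.  All three dialects yield
identical error counts (property-tested against an independent brute-force
CIGAR walker).  Reference case is preserved everywhere because lowercase
soft-masking carries the repeat annotation used by the repeat-fraction
analysis.

A path's read interval is always expressed in the original
(pre-reverse-complement) read orientation, so the paths of one read share
a common axis for combination; error events are reported in
reference-strand space so context cells are comparable across reads.

## Read classification

A read with k paths is classified by examining combinable pairs.  Two
paths are *combinable* when their read intervals overlap by at most
`max_read_overlap_fraction` (default 0.2) of the shorter interval, are
separated by at most `max_read_gap` (default 100 bases) on the read, and
jointly align at least `min_combined_gain` (default 50) more read bases
than the best single path.  A combinable pair is labelled:

* **self-chimeric** — same chromosome, overlapping genomic spans;
* **gapped** — same chromosome and strand, genomic gap ≤
  `max_genomic_gap_for_gapped` (default 500 kb, spanning intron/gene
  scales), and genomic order concordant with read order;
* **trans-chimeric** — anything else (different chromosome, excessive gap,
  discordant order or strand).

When pairs disagree the read takes the highest-priority label:
self-chimeric > trans-chimeric > gapped.  Adapter-retention artifacts must
not be hidden by an additional stray path, and chimera labels are
filtering signals.  Reads with no combinable pair are *single*; reads with
no paths are *unaligned*.  The mappable length is the combined aligned
bases of the best combinable pair when one exists (recorded alongside the
best single path), otherwise the best path's aligned bases.  Best-path
ties break deterministically on (chromosome, start, strand).

## Error profiling

The denominator choice matters: the overall rate is errors divided by
total alignment columns (matches + mismatches + inserted bases + deleted
bases), so the three per-type rates share one denominator and sum exactly
to the overall rate — matching the additive presentation of per-type rates
alongside an overall rate.  Whether "aligned bases" should include deleted
reference bases is not observable from the reported statistics; we count
alignment columns and say so here.

Sampling: reads are drawn in uniform random order without replacement
(fixed default seed 0) until cumulative columns reach `sample_target`
(default 1,000,000) for overall rates, or until each of the 16
(preceding, following) reference contexts has been observed
`min_context_obs` (default 10,000) times for context matrices.  If the
stream is exhausted first, everything available is used and the context
matrices carry an `undersampled` flag.  With a target at or above the data
size, sampled rates equal exhaustive rates exactly regardless of seed.

Context conventions: a mismatch's context is the reference base
immediately 5' and 3' of the mismatched position; an indel's context is
the pair of reference bases flanking the whole event, and each base of a
multi-base indel counts as a separate event with those flanks (keeping
counts additive per focal base).  The shared context denominator counts
reference-consuming columns with the given flanks; insertion frequencies
reuse it as per-junction exposure.  Columns containing N in read or
reference are excluded from numerator and denominator and tallied
separately.

Homopolymer statistics report both membership modes, since the convention
behind a single "indels in homopolymer" number is ambiguous: *loose* (the
indel base equals the 5' or the 3' neighbour) and *tight* (equals both).
Tight ⊆ loose by construction.

## Transcript assignment and identification

Assignment matches the read's exon chain (genomic blocks of the chosen
path; for gapped reads, of the combined pair) against every consecutive
run of transcript exons of the same length.  Exons internal to the run
must be covered at ≥ 80% of their length (one-sided); the run's terminal
exons need any positive overlap.  A passing run that spans the
transcript's first and last exons is a *full-length* match; any other
passing run is *partial*.  This consecutive-run reading is the only one
that makes "assignment requires terminal-exon coverage" and "partial
matches exist" simultaneously coherent, and it naturally handles
truncated cDNA.  A single-exon transcript is full-length when covered at
≥ 90% (the singleton identification threshold), partial otherwise.

Identification (per transcript, over all reads): singletons need one read
covering ≥ 90% of the isoform length — coverage is not aggregated across
reads, since identification evidence is a single molecule; multi-exon
isoforms need one read covering the first and last exons with *mutual*
(reciprocal) ≥ 80% overlap of each internal exon, i.e. |block ∩ exon| ≥
0.8·|exon| and ≥ 0.8·|block|.  The reciprocal form is what distinguishes
the identification rule from the one-sided assignment rule.  Spike-in
mode calls an isoform identified when at least one read is *uniquely*
assigned to it — unique meaning no other transcript matches at the same
status level.  Matching ignores read strand by default because cDNA
strandness is unreliable for some protocols; `require_strand_match`
enables enforcement.

Splice-junction offsets: each read junction is matched to the nearest
annotated junction whose donor and acceptor both lie within ±100 bases
(configurable); unmatched junctions count as novel.  Sign convention:
negative = the observed site moved *into* the annotated exon, so a donor
observed 4 bases before the annotated exon end scores −4.

Poly(A/T) detection scans the terminal 50-base windows (3' for A, 5' for
T): a tail is called when some terminal stretch of ≥ `min_run` (10) bases
has ≥ `min_fraction` (0.8) content of the tail base; the longest run is
reported.  The suffix-scan avoids diluting a genuine 30-base tail inside a
fixed-width window.  These parameters are this package's operational
definition; the detection procedure behind published tail percentages is
not specified anywhere we could adopt it from.

Repeat fraction is simply lowercase (soft-masked) bases within exons over
transcript length, binned 0 / (0, 0.5] / > 0.5 by default.

## Best-read selection

Molecules are keyed by PacBio movie/ZMW (parsed from `movie/zmw/…` names)
or by ONT channel/read identity (configurable regex; naming conventions
drift across basecaller versions).  Priority ladders:

* PacBio long-only: best aligned CCS → best aligned subread;
* PacBio hybrid: CCS with > 2 passes and accuracy > 95 → short-read-
  corrected CCS → subread;
* ONT (both): 2D → 1D template → 1D complement, hybrid operating on
  corrected members.

"Best aligned" is the most mapped read bases of the read's best path, with
the same tie-break as path selection.  Pass counts and predicted accuracy
(a 0–100 percentage) are upstream basecaller outputs carried as metadata,
never recomputed.  Groups whose members are all unaligned select nothing,
preserving "once and only once" over molecules with usable data.

## Synthetic data model

The generator emulates spliced cDNA long reads: reads are exact or
truncated copies of annotated isoforms with per-column errors, optional
poly(A) tails, and read-level artifacts.  Truth SAM records carry `=`/`X`
CIGARs (degradable to M + MD and to plain M to exercise all parsing
paths), so tests bypass aligners entirely.

Error injection is calibrated so the *realised column fractions* match the
requested rates in expectation under the shared-denominator convention:
with targets (f_mis, f_ins, f_del), per-position probabilities are
p_ins-gap = f_ins/(1−f_ins), p_del = f_del/(1−f_ins), p_mis =
f_mis/((1−f_ins)(1−p_del)).  Context bias reweights *which* base a
mismatch produces (target base at weight w against 1 for each alternative)
without changing the marginal mismatch rate, so rate recovery and
context-cell ranking are testable simultaneously.  The default profile
follows an ONT-2D-style spectrum (mismatch 5.50%, insertion 3.12%,
deletion 4.79% of columns) with a TAG→TGG substitution bias; a
subread-style preset is insertion-heavy with a homopolymer indel
multiplier.  The homopolymer multiplier (h) makes insertions copy an
adjacent base with probability 1−1/h and scales deletion probability next
to equal bases; h > 1 raises the marginal indel rate, so rate-recovery
experiments use h = 1.

Artifacts are mutually exclusive per read: trans-chimeras concatenate
fragments from transcripts on different chromosomes; self-chimeras append
a duplicated 5'-anchored fragment of the same transcript (overlapping
genomic span); junk reads are unalignable random sequence; adapter
retention appends a fixed 30-mer (soft-clipped in truth).  Chimera
fragments are drawn from transcripts ≥ 300 bases so the combined pair
decisively beats the single-path representation.  5' truncation is
geometric with configurable mean, emulating incomplete cDNA synthesis.
Poly(A) tails have a floor at half the mean length — enzymatic
polyadenylation rarely yields very short tails — which also keeps tails
above the detector's minimum-run threshold.  Junction jitter shifts a
configurable fraction of splice junctions by ±1–4 bases (donor and
acceptor together, preserving block lengths), producing realistic
imperfect splice sites whose offsets are recorded in the truth table.
Quality strings are constant: none of the analyses use base qualities.

What the generator does **not** model: aligner noise (truth alignments are
the intended ones — classification fidelity results on truth data bound
what an aligner could achieve, not what it does achieve), gapped-alignment
artifacts, base-quality-correlated errors, multi-base indel events
(indels are injected base-wise), expression heterogeneity (depth is
uniform per isoform unless size selection reweights it), and signal-level
platform effects.  Passing tests therefore demonstrate correctness of the
statistics and rules, not robustness to aligner idiosyncrasies.

## Problem sizes and reproducibility

The test-suite and acceptance-script simulations use toy genomes of 2 ×
60–400 kb with 12–80 genes: error-rate recovery runs at ≥ 2.2 Mb aligned
columns (standard error on a 5% rate ≈ 0.02 percentage points at the 1 Mb
sampling floor), classification fidelity at ~2,000 reads, and the
spike-in experiment at 68 isoforms × 10 reads.  These sizes leave the
binomial uncertainty of each check several times smaller than the effect
it verifies.  All randomness flows from explicit integer seeds; report
generation is a pure function of inputs and seed (no clock, no
hostnames), and `report.json` is byte-identical across identically seeded
runs.

## Known limitations

* Chimera classification evaluates path pairs only; reads with ≥ 3
  genuinely distinct loci still receive a single (highest-priority) label,
  and only the best pair contributes to the combined length accounting.
* The GTF reader handles exon features with `gene_id`/`transcript_id`
  attributes (the de-facto interchange subset); GFF3 ID/Parent chains are
  out of scope.
* CRAM input and aligner invocation are out of scope; GMAP- and
  minimap2-style SAM/BAM outputs (supplementary alignments, MD optional)
  are the targeted dialects.
* The REP scale ambiguity (fraction vs percent) is resolved by computing
  on fractions and exposing `scale="percent"` as a multiplier; distances
  on the two scales differ by exactly 100×.
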