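"""Read-to-transcript assignment, isoform identification, splice-site
accuracy, poly(A/T) tail detection and repeat-fraction analysis.

Assignment rule: a read's aligned exon chain (its genomic blocks, with
introns as gaps) is matched against a consecutive run of a transcript's
exons.  Exons internal to the matched run must be covered at >= 80% of
their length by the corresponding read block; the run's terminal exons may
be covered by any positive length.  A match whose run spans the
transcript's first and last exons is *full-length*; any other passing run
is *partial*.

Identification rules (per-transcript, over all assigned reads):

* singleton (one-exon) isoforms are identified when a single read covers
  >= 90% of the isoform length;
* multi-exon isoforms are identified when at least one read covers the
  first and last exons and every internal exon with >= 80% *mutual*
  (reciprocal) overlap — |block ∩ exon| >= 0.8·|exon| and >= 0.8·|block|;
* spike-in (SIRV-style) mode instead requires at least one read uniquely
  assigned to the isoform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AlignmentPath, GenomeSequence, ReadAlignment, TranscriptModel


@dataclass
class AssignmentThresholds:
    internal_exon_coverage: float = 0.8  # one-sided, assignment rule
    mutual_overlap: float = 0.8  # reciprocal, identification rule
    singleton_coverage: float = 0.9  # single-read fraction for singletons
    require_strand_match: bool = False  # cDNA strandness often unreliable


@dataclass
class MatchResult:
    read_id: str
    transcript_id: str
    status: str  # full-length / partial
    exon_coverages: list[float]  # per matched-run exon, fraction of exon covered
    matched_exon_range: tuple[int, int]  # half-open indices into transcript exons
    covered_bases: int
    mutual_full_length: bool  # passes the reciprocal-overlap identification rule
    unique: bool = False


class TranscriptIndex:
    """Interval index of transcripts per chromosome for overlap queries."""

    def __init__(self, transcripts: Sequence[TranscriptModel]):
        self.transcripts = list(transcripts)
        self._trees: dict[str, IntervalTree] = {}
        for t in self.transcripts:
            s, e = t.span
            self._trees.setdefault(t.chrom, IntervalTree()).addi(s, e, t)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda t: (t.span, t.transcript_id))


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _blocks_for_path(read: ReadAlignment) -> list[AlignmentPath]:
    """Paths contributing exon chains: the combined pair for gapped reads,
    otherwise the best path."""
    if read.classification == "gapped" and len(read.combined_paths) == 2:
        return read.combined_paths
    return [read.best_path] if read.best_path else []


def _merged_blocks(read: ReadAlignment) -> tuple[str, str, list[tuple[int, int]]] | None:
    paths = _blocks_for_path(read)
    if not paths:
        return None
    chrom = paths[0].chrom
    strand = paths[0].strand
    blocks = sorted(b for p in paths for b in p.genome_blocks)
    return chrom, strand, blocks


def assign_read(
    read: ReadAlignment,
    index: TranscriptIndex,
    thresholds: AssignmentThresholds | None = None,
) -> list[MatchResult]:
    """All transcript matches of one read, best first.

    Results are sorted full-length before partial, then by covered bases
    (descending), then transcript id.  ``unique`` flags are set relative to
    this read only: no other transcript matched at the same status.
    """
    th = thresholds or AssignmentThresholds()
    mb = _merged_blocks(read)
    if mb is None:
        return []
    chrom, strand, blocks = mb
    span = (blocks[0][0], blocks[-1][1])
    results: list[MatchResult] = []
    for t in index.overlapping(chrom, *span):
        if th.require_strand_match and t.strand != strand:
            continue
        m = _match_transcript(read.read_id, blocks, t, th)
        if m is not None:
            results.append(m)
    results.sort(key=lambda m: (m.status != "full-length", -m.covered_bases, m.transcript_id))
    if results:
        best_status = results[0].status
        at_best = [m for m in results if m.status == best_status]
        if len(at_best) == 1:
            at_best[0].unique = True
    return results


def _match_transcript(
    read_id: str,
    blocks: list[tuple[int, int]],
    t: TranscriptModel,
    th: AssignmentThresholds,
) -> MatchResult | None:
    m = len(blocks)
    n = t.n_exons

    if n == 1:
        ov = _overlap(blocks[0], t.exons[0]) if m == 1 else max(
            _overlap(b, t.exons[0]) for b in blocks
        )
        if ov <= 0:
            return None
        cov = ov / t.length
        status = "full-length" if cov >= th.singleton_coverage else "partial"
        block = max(blocks, key=lambda b: _overlap(b, t.exons[0]))
        mutual = (
            ov >= th.singleton_coverage * t.length
        )
        return MatchResult(
            read_id, t.transcript_id, status, [cov], (0, 1), ov, mutual
        )

    if m > n:
        return None
    best: MatchResult | None = None
    for i in range(n - m + 1):
        run = t.exons[i : i + m]
        covs = []
        covered = 0
        ok = True
        mutual_ok = True
        for k, (block, exon) in enumerate(zip(blocks, run)):
            ov = _overlap(block, exon)
            exon_len = exon[1] - exon[0]
            block_len = block[1] - block[0]
            internal_of_run = 0 < k < m - 1
            if ov <= 0:
                ok = False
                break
            if internal_of_run and ov < th.internal_exon_coverage * exon_len:
                ok = False
                break
            if ov < th.mutual_overlap * exon_len or ov < th.mutual_overlap * block_len:
                # reciprocal rule applies to internal exons only; terminals any length
                if internal_of_run:
                    mutual_ok = False
            covs.append(ov / exon_len)
            covered += ov
        if not ok:
            continue
        status = "full-length" if (i == 0 and i + m == n and m == n) else "partial"
        cand = MatchResult(
            read_id,
            t.transcript_id,
            status,
            covs,
            (i, i + m),
            covered,
            mutual_ok and m == n,
        )
        if (
            best is None
            or (best.status != "full-length" and cand.status == "full-length")
            or (best.status == cand.status and cand.covered_bases > best.covered_bases)
        ):
            best = cand
    return best


def assign_reads(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[TranscriptModel],
    thresholds: AssignmentThresholds | None = None,
) -> dict[str, list[MatchResult]]:
    index = TranscriptIndex(transcripts)
    th = thresholds or AssignmentThresholds()
    return {r.read_id: assign_read(r, index, th) for r in reads if r.best_path}


# ---------------------------------------------------------------------------
# Isoform identification
# ---------------------------------------------------------------------------

FULL_LENGTH_IDENTIFIED = "full-length-identified"
IDENTIFIED = "identified"
NOT_IDENTIFIED = "not-identified"


def identify_isoforms(
    assignments: dict[str, list[MatchResult]],
    transcripts: Sequence[TranscriptModel],
    mode: str = "coverage",
) -> pd.DataFrame:
    """Per-transcript identification status with supporting read counts.

    ``mode='coverage'`` applies the singleton-90% and multi-exon mutual-overlap
    rules; ``mode='sirv'`` calls a transcript identified when at least one
    read is uniquely assigned to it.  Identification is monotone in reads:
    adding reads can only move a transcript toward identified.
    """
    by_tx: dict[str, list[MatchResult]] = {t.transcript_id: [] for t in transcripts}
    for matches in assignments.values():
        for m in matches:
            if m.transcript_id in by_tx:
                by_tx[m.transcript_id].append(m)
    rows = []
    for t in transcripts:
        ms = by_tx[t.transcript_id]
        n_full = sum(1 for m in ms if m.status == "full-length")
        n_mutual = sum(1 for m in ms if m.mutual_full_length)
        n_unique = sum(1 for m in ms if m.unique)
        if mode == "sirv":
            status = IDENTIFIED if n_unique > 0 else NOT_IDENTIFIED
        elif t.is_singleton:
            best_cov = max((m.exon_coverages[0] for m in ms), default=0.0)
            status = IDENTIFIED if best_cov >= 0.9 else NOT_IDENTIFIED
        else:
            status = FULL_LENGTH_IDENTIFIED if n_mutual > 0 else NOT_IDENTIFIED
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": t.gene_id,
                "n_exons": t.n_exons,
                "length": t.length,
                "status": status,
                "supporting_reads": len(ms),
                "full_length_reads": n_full,
                "mutual_full_length_reads": n_mutual,
                "unique_reads": n_unique,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Splice-site accuracy
# ---------------------------------------------------------------------------

@dataclass
class SpliceOffset:
    chrom: str
    annotated_donor: int
    annotated_acceptor: int
    observed_donor: int
    observed_acceptor: int
    donor_offset: int  # negative = observed junction moved into the exon
    acceptor_offset: int

    @property
    def perfect(self) -> bool:
        return self.donor_offset == 0 and self.acceptor_offset == 0


def splice_offsets(
    reads: Iterable[ReadAlignment],
    transcripts: Sequence[TranscriptModel],
    window: int = 100,
) -> tuple[list[SpliceOffset], dict]:
    """Signed distances between observed and annotated splice junctions.

    Each read junction (boundary between consecutive genomic blocks) is
    matched to the nearest annotated junction whose donor and acceptor both
    fall within ``window`` bases.  Sign convention: negative = the observed
    site moved *into* the annotated exon.  Junctions with no annotated
    junction in the window are counted as novel and excluded from the
    offset distribution.
    """
    ann: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        ann.setdefault(t.chrom, []).extend(t.junctions)
    for c in ann:
        ann[c] = sorted(set(ann[c]))

    offsets: list[SpliceOffset] = []
    n_novel = 0
    for r in reads:
        mb = _merged_blocks(r)
        if mb is None:
            continue
        chrom, _, blocks = mb
        juncs = ann.get(chrom, [])
        for k in range(len(blocks) - 1):
            donor, acceptor = blocks[k][1], blocks[k + 1][0]
            best = None
            for ad, aa in juncs:
                if abs(ad - donor) <= window and abs(aa - acceptor) <= window:
                    dist = abs(ad - donor) + abs(aa - acceptor)
                    if best is None or dist < best[0]:
                        best = (dist, ad, aa)
            if best is None:
                n_novel += 1
                continue
            _, ad, aa = best
            offsets.append(
                SpliceOffset(
                    chrom,
                    ad,
                    aa,
                    donor,
                    acceptor,
                    donor_offset=donor - ad,
                    acceptor_offset=aa - acceptor,
                )
            )
    n = len(offsets)
    n_perfect = sum(1 for o in offsets if o.perfect)
    hist: dict[int, int] = {}
    for o in offsets:
        for v in (o.donor_offset, o.acceptor_offset):
            hist[v] = hist.get(v, 0) + 1
    summary = {
        "n_junctions": n,
        "n_perfect": n_perfect,
        "perfect_fraction": n_perfect / n if n else float("nan"),
        "n_novel": n_novel,
        "offset_histogram": dict(sorted(hist.items())),
    }
    return offsets, summary


# ---------------------------------------------------------------------------
# Poly(A/T) tails
# ---------------------------------------------------------------------------

@dataclass
class PolyATail:
    read_id: str
    detected: bool
    tail_kind: str  # 'A', 'T' or 'none'
    tail_length: int
    window: int
    min_fraction: float
    min_run: int


def _longest_run(seq: str, base: str) -> int:
    best = run = 0
    for c in seq:
        run = run + 1 if c == base else 0
        best = max(best, run)
    return best


def detect_polyA(
    read_id: str,
    sequence: str,
    window: int = 50,
    min_fraction: float = 0.8,
    min_run: int = 10,
) -> PolyATail:
    """Detect a poly(A) tail at the 3' end or a poly(T) head at the 5' end.

    cDNA reads may come off either strand, so an A-rich 3' window or a
    T-rich 5' window both count.  A window qualifies when the base content
    is >= ``min_fraction`` and contains a run of >= ``min_run`` identical
    bases; the longest qualifying run length is reported.
    """
    seq = sequence.upper()
    if len(seq) < min_run:
        return PolyATail(read_id, False, "none", 0, window, min_fraction, min_run)
    tail = seq[-window:]
    head = seq[:window]

    def qualifies(s: str, base: str) -> bool:
        # any terminal stretch of >= min_run bases passing the content bar
        best = 0.0
        for k in range(min_run, len(s) + 1):
            frac = s[-k:].count(base) / k if base == "A" else s[:k].count(base) / k
            best = max(best, frac)
        return best >= min_fraction

    a_run = _longest_run(tail, "A")
    t_run = _longest_run(head, "T")
    a_ok = a_run >= min_run and qualifies(tail, "A")
    t_ok = t_run >= min_run and qualifies(head, "T")
    if a_ok and (not t_ok or a_run >= t_run):
        return PolyATail(read_id, True, "A", a_run, window, min_fraction, min_run)
    if t_ok:
        return PolyATail(read_id, True, "T", t_run, window, min_fraction, min_run)
    return PolyATail(read_id, False, "none", 0, window, min_fraction, min_run)


def polyA_summary(tails: Sequence[PolyATail]) -> dict:
    n = len(tails)
    det = sum(1 for t in tails if t.detected)
    return {
        "n_reads": n,
        "n_detected": det,
        "detected_fraction": det / n if n else float("nan"),
    }


# ---------------------------------------------------------------------------
# Repeat (soft-mask) fraction
# ---------------------------------------------------------------------------

def repeat_fraction(t: TranscriptModel, genome: GenomeSequence) -> float:
    """Fraction of transcript bases that are soft-masked (lowercase) —
    i.e. marked repetitive by RepeatMasker / Tandem Repeats Finder."""
    lower = 0
    for s, e in t.exons:
        seq = genome.fetch(t.chrom, s, e)
        lower += sum(1 for c in seq if c.islower())
    return lower / t.length


def repeat_fraction_table(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    bins: Sequence[float] = (0.0, 0.5),
) -> pd.DataFrame:
    """Per-transcript repeat fractions with a binned label.

    Default bins follow the 0 / (0,0.5] / >0.5 convention.
    """
    rows = []
    for t in transcripts:
        f = repeat_fraction(t, genome)
        if f == 0:
            label = "0"
        elif f <= bins[1]:
            label = f"(0,{bins[1]}]"
        else:
            label = f">{bins[1]}"
        rows.append(
            {"transcript_id": t.transcript_id, "repeat_fraction": f, "bin": label}
        )
    return pd.DataFrame(rows)
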