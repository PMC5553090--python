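"""Synthetic long-read data with exact truth: genomes, transcriptomes and
spliced reads with parameterised platform-style error and artifact models.

The generator writes FASTQ + a *truth* SAM (the intended alignment, with
=/X CIGAR ops and N intron gaps) + truth tables, so every downstream module
can be exercised and validated without running an aligner.  Realised error
counts recorded in the truth table equal the injections exactly.

Error model
-----------
Per-type rates are specified as target fractions of alignment columns
(matches + mismatches + inserted + deleted bases), the same denominator the
profiler reports, and the per-position event probabilities are calibrated
so the realised column fractions match the targets in expectation.
Context bias redistributes *which* base a mismatch produces (a weighted
choice in the configured context) without changing the marginal mismatch
rate, so rate recovery and context-cell ranking can be tested at once.
The homopolymer multiplier makes inserted bases copy an adjacent reference
base and concentrates deletions next to equal bases; with a multiplier of
1 indel placement is context-free.

Artifact model
--------------
Reads can be emitted as trans-chimeras (two fragments from different
chromosomes sharing one read name), self-chimeras (a read carrying a
duplicated, genomically overlapping fragment — the unremoved-adapter
signature), adapter-retaining reads (a non-genomic adapter appended, soft-
clipped in truth), or unalignable junk.  A size-selection spec reweights
source transcripts into length bands, mimicking size-fractionated PacBio
libraries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomeSequence,
    TranscriptModel,
    write_fasta,
    write_fastq,
    write_gtf,
)

BASES = "ACGT"
_COMP = str.maketrans("ACGTacgtN", "TGCAtgcaN")

ADAPTER = "ATCTCTCTCAACAACAACAACGGAGGAGGA"  # fixed synthetic adapter, 30 nt


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """Target per-type error rates (fractions of alignment columns).

    context_bias maps (ref base, preceding ref base, following ref base) →
    (observed base, weight): in that context a mismatch produces the target
    base with probability weight/(weight+2), the two remaining bases with
    probability 1/(weight+2) each.  homopolymer_indel_multiplier h >= 1
    makes an inserted base copy the preceding reference base with
    probability 1 - 1/h and biases deletions toward positions flanked by an
    equal base by the same factor.  insertion_base_weights set the base
    composition of non-homopolymer insertions.
    """

    mismatch_rate: float = 0.055
    insertion_rate: float = 0.0312
    deletion_rate: float = 0.0479
    context_bias: dict[tuple[str, str, str], tuple[str, float]] = field(
        default_factory=dict
    )
    homopolymer_indel_multiplier: float = 1.0
    insertion_base_weights: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        for r in (self.mismatch_rate, self.insertion_rate, self.deletion_rate):
            if not 0 <= r < 1:
                raise ValueError("rates must be in [0,1)")
        if self.homopolymer_indel_multiplier <= 0:
            raise ValueError("multiplier must be > 0")

    @classmethod
    def perfect(cls) -> "ErrorModel":
        return cls(0.0, 0.0, 0.0)

    @classmethod
    def ont_2d(cls) -> "ErrorModel":
        """ONT 2D-style profile: 5.50% mismatch, 3.12% insertion, 4.79%
        deletion, with the characteristic TAG→TGG substitution bias."""
        return cls(
            mismatch_rate=0.0550,
            insertion_rate=0.0312,
            deletion_rate=0.0479,
            context_bias={("A", "T", "G"): ("G", 8.0)},
        )

    @classmethod
    def pacbio_subread(cls) -> "ErrorModel":
        """PacBio subread-style profile: insertion-heavy with strong
        homopolymer indel preference."""
        return cls(
            mismatch_rate=0.0527,
            insertion_rate=0.0592,
            deletion_rate=0.0301,
            homopolymer_indel_multiplier=3.0,
        )


@dataclass
class ArtifactModel:
    """Rates of read-level artifacts (mutually exclusive per read)."""

    chimera_rate: float = 0.0  # trans-chimeric
    self_chimera_rate: float = 0.0
    adapter_retention_rate: float = 0.0
    unaligned_junk_rate: float = 0.0
    size_selection: list[tuple[int, int, float]] | None = None  # (lo, hi, weight)

    def __post_init__(self) -> None:
        total = (
            self.chimera_rate
            + self.self_chimera_rate
            + self.adapter_retention_rate
            + self.unaligned_junk_rate
        )
        if total > 1:
            raise ValueError("artifact rates must sum to <= 1")


@dataclass
class TailModel:
    """Poly(A) tail appended to the transcript 3' end (soft-clipped in truth).

    Lengths are length_mean/2 plus a geometric excess with the same mean —
    enzymatic polyadenylation rarely yields very short tails, so the
    distribution has a floor at half the mean.
    """

    fraction: float = 0.0
    length_mean: int = 30


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def make_genome(
    seed: int,
    n_chrom: int = 2,
    lengths: Sequence[int] | int = 100_000,
    masked_fraction: float = 0.0,
    out_fasta: str | Path | None = None,
    out_bed: str | Path | None = None,
) -> tuple[GenomeSequence, dict[str, list[tuple[int, int]]]]:
    """Random genome with optional soft-masked (lowercase) tracts.

    Masked tracts of ~500 bp are placed uniformly until the requested
    fraction is reached.  Returns the genome and the truth masked regions.
    """
    if isinstance(lengths, int):
        lengths = [lengths] * n_chrom
    if len(lengths) != n_chrom or any(l <= 0 for l in lengths):
        raise ValueError("need one positive length per chromosome")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    masked: dict[str, list[tuple[int, int]]] = {}
    for i, L in enumerate(lengths):
        chrom = f"chr{i + 1}"
        seq = "".join(np.array(list(BASES))[rng.integers(0, 4, L)])
        regions: list[tuple[int, int]] = []
        if masked_fraction > 0:
            target = int(masked_fraction * L)
            covered = np.zeros(L, dtype=bool)
            while covered.sum() < target:
                tract = min(500, target - int(covered.sum()) + 250)
                s = int(rng.integers(0, max(1, L - tract)))
                covered[s : s + tract] = True
            arr = np.array(list(seq))
            arr[covered] = np.char.lower(arr[covered])
            seq = "".join(arr)
            # collapse the boolean mask into regions
            idx = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
            regions = [(int(idx[k]), int(idx[k + 1])) for k in range(0, len(idx), 2)]
        seqs[chrom] = seq
        masked[chrom] = regions
    if out_fasta:
        write_fasta(seqs, out_fasta)
    if out_bed:
        with open(out_bed, "w") as fh:
            for chrom, regions in masked.items():
                for s, e in regions:
                    fh.write(f"{chrom}\t{s}\t{e}\tmasked\n")
    return GenomeSequence.from_dict(seqs), masked


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------

def make_transcriptome(
    genome: GenomeSequence,
    seed: int,
    n_genes: int = 20,
    exon_count_mean: float = 5.0,
    exon_length_mean: int = 200,
    intron_length_mean: int = 500,
    singleton_fraction: float = 0.2,
    out_gtf: str | Path | None = None,
) -> list[TranscriptModel]:
    """Random non-overlapping gene models spread across chromosomes.

    Exon counts are Poisson (shifted to >= 2 for non-singletons), exon and
    intron lengths geometric around their means.  When n_genes >= 10, one
    multi-exon transcript additionally gets a second isoform that is a
    strict sub-chain of its exons, exercising containment edge cases.
    """
    rng = np.random.default_rng(seed)
    chroms = genome.chromosomes
    transcripts: list[TranscriptModel] = []
    cursors = {c: 1000 for c in chroms}
    sub_chain_done = False
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        singleton = rng.random() < singleton_fraction
        n_exons = 1 if singleton else max(2, 2 + rng.poisson(max(exon_count_mean - 2, 0.1)))
        for _attempt in range(20):
            exons = []
            pos = cursors[chrom] + int(rng.integers(200, 1000))
            ok = True
            for _ in range(n_exons):
                elen = max(30, int(rng.geometric(1.0 / exon_length_mean)))
                if pos + elen > genome.length(chrom) - 1000:
                    ok = False
                    break
                exons.append((pos, pos + elen))
                pos += elen + max(60, int(rng.geometric(1.0 / intron_length_mean)))
            if ok:
                break
        else:
            continue
        if not ok:
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        tid = f"TX{g + 1:04d}"
        transcripts.append(TranscriptModel(tid, f"G{g + 1:04d}", chrom, strand, exons))
        cursors[chrom] = exons[-1][1]
        if not sub_chain_done and n_genes >= 10 and len(exons) >= 4:
            sub = exons[1:-1]  # strict sub-chain of the parent's exons
            transcripts.append(
                TranscriptModel(f"{tid}.sub", f"G{g + 1:04d}", chrom, strand, list(sub))
            )
            sub_chain_done = True
    if out_gtf:
        write_gtf(transcripts, out_gtf)
    return transcripts


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class SimFragment:
    """One aligned fragment of a simulated read (one truth SAM record)."""

    chrom: str
    strand: str
    ops: list[tuple[str, int]]  # genomic-order ('=','X','I','D','N') ops
    ref_start: int
    gseq: str  # aligned read bases in genomic orientation (no clips)
    xbases: list[str]  # reference bases at X and D columns, genomic order


@dataclass
class SimRead:
    read_id: str
    sequence: str  # FASTQ orientation
    truth_class: str  # single / trans-chimeric / self-chimeric / unaligned
    fragments: list[SimFragment]
    transcript_id: str | None
    n_mismatch: int = 0
    n_insertion: int = 0
    n_deletion: int = 0
    n_columns: int = 0
    truncated_bases: int = 0
    polya_len: int = 0
    n_junctions: int = 0
    n_jittered_junctions: int = 0


@dataclass
class SimResult:
    reads: list[SimRead]
    transcripts: list[TranscriptModel]
    genome: GenomeSequence

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for r in self.reads:
            rows.append(
                {
                    "read_id": r.read_id,
                    "transcript_id": r.transcript_id or "NA",
                    "truth_class": r.truth_class,
                    "read_length": len(r.sequence),
                    "n_mismatch": r.n_mismatch,
                    "n_insertion": r.n_insertion,
                    "n_deletion": r.n_deletion,
                    "n_columns": r.n_columns,
                    "truncated_bases": r.truncated_bases,
                    "polya_len": r.polya_len,
                    "n_junctions": r.n_junctions,
                    "n_jittered_junctions": r.n_jittered_junctions,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path, prefix: str = "sim", dialect: str = "eqx") -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fastq": out / f"{prefix}.fastq",
            "sam": out / f"{prefix}.sam",
            "truth": out / f"{prefix}.truth.tsv",
        }
        write_fastq(((r.read_id, r.sequence) for r in self.reads), paths["fastq"])
        write_truth_sam(self, paths["sam"], dialect=dialect)
        self.truth_table().to_csv(paths["truth"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def _spliced(genome: GenomeSequence, t: TranscriptModel) -> str:
    return "".join(genome.fetch(t.chrom, s, e) for s, e in t.exons).upper()


def _geometric0(rng: np.random.Generator, mean: float) -> int:
    """Geometric on {0,1,2,...} with the given mean (0 when mean == 0)."""
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1))) - 1


def _inject_errors(
    rng: np.random.Generator,
    genome: GenomeSequence,
    t: TranscriptModel,
    exons: list[tuple[int, int]],
    em: ErrorModel,
) -> tuple[list[tuple[str, int]], str, list[str], dict]:
    """Inject per-column errors over an exon chain.

    Returns (genomic-order ops incl. N gaps, aligned read bases in genomic
    orientation, reference bases at X/D columns, error counts).
    """
    # calibration: per-position probabilities giving the target *column
    # fraction* for each type under the shared-denominator convention
    f_i = em.insertion_rate
    c_ins = f_i / (1.0 - f_i) if f_i > 0 else 0.0
    p_del = em.deletion_rate / (1.0 - f_i)
    p_mis = (
        em.mismatch_rate / ((1.0 - f_i) * (1.0 - p_del)) if p_del < 1 else 0.0
    )
    h = em.homopolymer_indel_multiplier

    chrom = t.chrom
    # per-exon windows with 1-base genomic flanks (flanks at exon edges are
    # intron bases, exactly as the profiler sees them)
    ref_parts: list[str] = []
    prev_ref: list[str] = []
    next_ref: list[str] = []
    for s, e in exons:
        w = genome.fetch_padded(chrom, s - 1, e + 1).upper()
        ref_parts.append(w[1:-1])
        prev_ref.extend(w[0:-2])
        next_ref.extend(w[2:])
    ref = "".join(ref_parts)
    n = len(ref)

    # deletion draw (homopolymer multiplier concentrates, preserving nothing:
    # h > 1 raises the marginal; kept at 1 for rate-recovery experiments)
    u = rng.random(n)
    if h != 1.0:
        hp = np.array(
            [ref[k] == prev_ref[k] or ref[k] == next_ref[k] for k in range(n)]
        )
        p_del_vec = np.where(hp, min(p_del * h, 0.99), p_del)
    else:
        p_del_vec = np.full(n, p_del)
    del_mask = u < p_del_vec
    u2 = rng.random(n)
    mis_mask = (~del_mask) & (u2 < p_mis)
    ins_mask = rng.random(n + 1) < c_ins  # insertion before position k (and after last)

    base_idx = {b: i for i, b in enumerate(BASES)}
    ins_weights = np.asarray(em.insertion_base_weights, dtype=float)
    ins_weights = ins_weights / ins_weights.sum()
    p_copy = 1.0 - 1.0 / h if h > 1 else 0.0

    ops: list[tuple[str, int]] = []
    gseq_parts: list[str] = []
    xbases: list[str] = []
    counts = {"mismatch": 0, "insertion": 0, "deletion": 0, "match": 0}

    def flush_run(op: str, length: int) -> None:
        if length > 0:
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + length)
            else:
                ops.append((op, length))

    k = 0  # index into transcript positions
    for ei, (s, e) in enumerate(exons):
        if ei > 0:
            intron = s - exons[ei - 1][1]
            ops.append(("N", intron))
        run_op = None
        run_len = 0
        for g in range(s, e):
            # insertion before this position
            if ins_mask[k]:
                flush_run(run_op, run_len)
                run_op, run_len = None, 0
                if p_copy > 0 and rng.random() < p_copy:
                    b = prev_ref[k] if prev_ref[k] in BASES else ref[k]
                else:
                    b = BASES[rng.choice(4, p=ins_weights)]
                ops.append(("I", 1))
                gseq_parts.append(b)
                counts["insertion"] += 1
            rb = ref[k]
            if del_mask[k]:
                this_op = "D"
                xbases.append(rb)
                counts["deletion"] += 1
            elif mis_mask[k] and rb in BASES:
                this_op = "X"
                bias = em.context_bias.get((rb, prev_ref[k], next_ref[k]))
                others = [b for b in BASES if b != rb]
                if bias is not None and bias[0] != rb:
                    target, w = bias
                    probs = [w if b == target else 1.0 for b in others]
                    pv = np.asarray(probs) / sum(probs)
                    obs = others[int(rng.choice(3, p=pv))]
                else:
                    obs = others[int(rng.integers(0, 3))]
                gseq_parts.append(obs)
                xbases.append(rb)
                counts["mismatch"] += 1
            else:
                this_op = "="
                gseq_parts.append(rb)
                counts["match"] += 1
            if this_op == run_op:
                run_len += 1
            else:
                flush_run(run_op, run_len)
                run_op, run_len = this_op, 1
            k += 1
        flush_run(run_op, run_len)
    # trailing insertion after the last position
    if ins_mask[n]:
        b = BASES[rng.choice(4, p=ins_weights)]
        ops.append(("I", 1))
        gseq_parts.append(b)
        counts["insertion"] += 1
    return ops, "".join(gseq_parts), xbases, counts


def _jitter_junctions(
    rng: np.random.Generator,
    exons: list[tuple[int, int]],
    rate: float,
    max_shift: int = 4,
) -> tuple[list[tuple[int, int]], int]:
    """Shift a fraction of junctions by +-1..max_shift bases (both donor and
    acceptor move together, preserving block lengths)."""
    if rate <= 0 or len(exons) < 2:
        return exons, 0
    exons = [list(e) for e in exons]
    n_jit = 0
    for j in range(len(exons) - 1):
        if rng.random() >= rate:
            continue
        delta = int(rng.integers(1, max_shift + 1)) * (1 if rng.random() < 0.5 else -1)
        donor, acceptor = exons[j][1], exons[j + 1][0]
        new_donor, new_acceptor = donor + delta, acceptor + delta
        if (
            new_donor > exons[j][0] + 1
            and new_acceptor < exons[j + 1][1] - 1
            and new_donor < new_acceptor
        ):
            exons[j][1] = new_donor
            exons[j + 1][0] = new_acceptor
            n_jit += 1
    return [tuple(e) for e in exons], n_jit


def _truncate_5p(
    rng: np.random.Generator, t: TranscriptModel, mean: float
) -> tuple[list[tuple[int, int]], int]:
    """Drop a geometric number of bases from the transcript 5' end.

    Incomplete cDNA synthesis shortens molecules from the 5' end; on the
    genome that is the left end for '+' transcripts and the right end for
    '-' transcripts.
    """
    cut = _geometric0(rng, mean)
    if cut <= 0:
        return list(t.exons), 0
    cut = min(cut, t.length - 50)  # keep at least 50 aligned bases
    if cut <= 0:
        return list(t.exons), 0
    exons = list(t.exons)
    remaining = cut
    if t.strand == "+":
        out = []
        for s, e in exons:
            L = e - s
            if remaining >= L:
                remaining -= L
                continue
            out.append((s + remaining, e))
            remaining = 0
        return out, cut
    out = []
    for s, e in reversed(exons):
        L = e - s
        if remaining >= L:
            remaining -= L
            continue
        out.append((s, e - remaining))
        remaining = 0
    return list(reversed(out)), cut


def _pick_partner(
    rng: np.random.Generator, transcripts: list[TranscriptModel], t: TranscriptModel
) -> TranscriptModel:
    """A transcript on a different chromosome (a genuinely different locus)."""
    others = [x for x in transcripts if x.chrom != t.chrom and x.length >= 300]
    if not others:
        others = [x for x in transcripts if x.chrom != t.chrom]
    if not others:
        raise ValueError(
            "trans-chimera simulation needs transcripts on >= 2 chromosomes"
        )
    return others[int(rng.integers(0, len(others)))]


def simulate_reads(
    transcripts: Sequence[TranscriptModel],
    genome: GenomeSequence,
    error_model: ErrorModel | None = None,
    artifact_model: ArtifactModel | None = None,
    depth: int = 10,
    truncation_mean: float = 0.0,
    tail_model: TailModel | None = None,
    junction_jitter_rate: float = 0.0,
    seed: int = 0,
) -> SimResult:
    """Simulate ``depth`` reads per transcript (or band-resampled when size
    selection is active) with the given error/artifact models."""
    em = error_model or ErrorModel()
    am = artifact_model or ArtifactModel()
    tm = tail_model or TailModel()
    rng = np.random.default_rng(seed)
    transcripts = list(transcripts)
    reads: list[SimRead] = []
    n_total = depth * len(transcripts)

    sources: list[TranscriptModel] = []
    if am.size_selection:
        bands = [(lo, hi, w) for lo, hi, w in am.size_selection]
        weights = np.asarray([w for _, _, w in bands], dtype=float)
        weights = weights / weights.sum()
        by_band = [
            [t for t in transcripts if lo <= t.length < hi] for lo, hi, _ in bands
        ]
        for _ in range(n_total):
            for _try in range(50):
                bi = int(rng.choice(len(bands), p=weights))
                if by_band[bi]:
                    sources.append(by_band[bi][int(rng.integers(0, len(by_band[bi])))])
                    break
    else:
        for t in transcripts:
            sources.extend([t] * depth)

    for i, t in enumerate(sources):
        rid = f"read{i + 1:06d}"
        u = rng.random()
        if u < am.unaligned_junk_rate:
            L = int(rng.integers(300, 1200))
            seq = "".join(np.array(list(BASES))[rng.integers(0, 4, L)])
            reads.append(SimRead(rid, seq, "unaligned", [], None))
            continue
        u -= am.unaligned_junk_rate
        if u < am.chimera_rate + am.self_chimera_rate:
            # chimera fragments need enough aligned bases for the combined
            # pair to beat the single-path representation decisively
            tc = t
            if tc.length < 300:
                long_enough = [x for x in transcripts if x.length >= 300]
                if long_enough:
                    tc = long_enough[int(rng.integers(0, len(long_enough)))]
            kind = "trans" if u < am.chimera_rate else "self"
            reads.append(_make_chimera(rng, rid, tc, transcripts, genome, em, kind=kind))
            continue
        u -= am.chimera_rate + am.self_chimera_rate
        adapter = u < am.adapter_retention_rate

        exons, cut = _truncate_5p(rng, t, truncation_mean)
        exons, n_jit = _jitter_junctions(rng, exons, junction_jitter_rate)
        ops, gseq, xb, counts = _inject_errors(rng, genome, t, exons, em)
        frag = SimFragment(t.chrom, t.strand, ops, exons[0][0], gseq, xb)
        seq = gseq if t.strand == "+" else revcomp(gseq)
        polya = 0
        if tm.fraction > 0 and rng.random() < tm.fraction:
            floor = max(1, tm.length_mean // 2)
            polya = floor + _geometric0(rng, tm.length_mean / 2)
            seq = seq + "A" * polya
        if adapter:
            seq = seq + ADAPTER
        r = SimRead(
            rid,
            seq,
            "single",
            [frag],
            t.transcript_id,
            n_mismatch=counts["mismatch"],
            n_insertion=counts["insertion"],
            n_deletion=counts["deletion"],
            n_columns=sum(counts.values()),
            truncated_bases=cut,
            polya_len=polya,
            n_junctions=len(exons) - 1,
            n_jittered_junctions=n_jit,
        )
        reads.append(r)
    return SimResult(reads=reads, transcripts=transcripts, genome=genome)


def _make_chimera(
    rng: np.random.Generator,
    rid: str,
    t: TranscriptModel,
    transcripts: list[TranscriptModel],
    genome: GenomeSequence,
    em: ErrorModel,
    kind: str,
) -> SimRead:
    """A two-fragment read: different loci (trans) or an overlapping
    duplicated fragment (self, the adapter-retention signature)."""
    ops1, gseq1, xb1, c1 = _inject_errors(rng, genome, t, list(t.exons), em)
    frag1 = SimFragment(t.chrom, t.strand, ops1, t.exons[0][0], gseq1, xb1)
    if kind == "trans":
        t2 = _pick_partner(rng, transcripts, t)
        ops2, gseq2, xb2, c2 = _inject_errors(rng, genome, t2, list(t2.exons), em)
        frag2 = SimFragment(t2.chrom, t2.strand, ops2, t2.exons[0][0], gseq2, xb2)
        cls = "trans-chimeric"
    else:
        # duplicate a 5'-anchored piece of the same transcript: overlapping
        # genomic span, as left by an unremoved adapter
        keep = max(200, t.length * 2 // 3)
        exons2 = []
        remaining = keep
        for s, e in t.exons:
            L = e - s
            if remaining <= 0:
                break
            take = min(L, remaining)
            exons2.append((s, s + take))
            remaining -= take
        ops2, gseq2, xb2, c2 = _inject_errors(rng, genome, t, exons2, em)
        frag2 = SimFragment(t.chrom, t.strand, ops2, exons2[0][0], gseq2, xb2)
        cls = "self-chimeric"
    seq1 = gseq1 if frag1.strand == "+" else revcomp(gseq1)
    seq2 = gseq2 if frag2.strand == "+" else revcomp(gseq2)
    return SimRead(
        rid,
        seq1 + seq2,
        cls,
        [frag1, frag2],
        t.transcript_id,
        n_mismatch=c1["mismatch"] + c2["mismatch"],
        n_insertion=c1["insertion"] + c2["insertion"],
        n_deletion=c1["deletion"] + c2["deletion"],
        n_columns=sum(c1.values()) + sum(c2.values()),
        n_junctions=(len(t.exons) - 1),
    )


# ---------------------------------------------------------------------------
# Truth SAM writing (three CIGAR dialects)
# ---------------------------------------------------------------------------

def _fragment_read_intervals(read: SimRead) -> list[tuple[int, int]]:
    """Read-orientation intervals occupied by each fragment, in order."""
    out = []
    pos = 0
    for f in read.fragments:
        L = len(f.gseq)
        out.append((pos, pos + L))
        pos += L
    return out


def _cigar_string(ops: list[tuple[str, int]], lead: int, trail: int, dialect: str) -> str:
    parts = []
    if lead:
        parts.append((str(lead), "S"))
    if dialect == "eqx":
        body = ops
    else:
        body = []
        for op, ln in ops:
            op2 = "M" if op in "=X" else op
            if body and body[-1][0] == op2:
                body[-1] = (op2, body[-1][1] + ln)
            else:
                body.append((op2, ln))
    for op, ln in body:
        parts.append((str(ln), op))
    if trail:
        parts.append((str(trail), "S"))
    return "".join(n + o for n, o in parts)


def _md_tag(ops: list[tuple[str, int]], xbases: list[str]) -> str:
    """MD string for the fragment: run-lengths of matches, mismatched
    reference bases, ^-prefixed deletions.  N ops are transparent."""
    md: list[str] = []
    match_run = 0
    xi = 0
    for op, ln in ops:
        if op == "=":
            match_run += ln
        elif op == "X":
            for _ in range(ln):
                md.append(str(match_run))
                md.append(xbases[xi])
                match_run = 0
                xi += 1
        elif op == "D":
            md.append(str(match_run))
            match_run = 0
            md.append("^" + "".join(xbases[xi : xi + ln]))
            xi += ln
        # I and N consume no MD
    md.append(str(match_run))
    return "".join(md)


def write_truth_sam(
    result: SimResult, path: str | Path, dialect: str = "eqx"
) -> None:
    """Write the intended alignments as a SAM file.

    ``dialect`` controls mismatch encoding: ``eqx`` uses =/X ops; ``m_md``
    collapses to M and adds an MD tag; ``m_only`` collapses to M with no
    tag (mismatch typing then requires the reference).  Chimeric reads
    yield two records sharing the read name (second one supplementary);
    junk reads yield one unmapped record.
    """
    if dialect not in ("eqx", "m_md", "m_only"):
        raise ValueError(f"unknown CIGAR dialect {dialect!r}")
    genome = result.genome
    lines = ["@HD\tVN:1.6\tSO:unknown"]
    for chrom in genome.chromosomes:
        lines.append(f"@SQ\tSN:{chrom}\tLN:{genome.length(chrom)}")
    for read in result.reads:
        L = len(read.sequence)
        if not read.fragments:
            lines.append(
                f"{read.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{read.sequence}\t*"
            )
            continue
        ivs = _fragment_read_intervals(read)
        for fi, (frag, (s, e)) in enumerate(zip(read.fragments, ivs)):
            flag = 0
            if frag.strand == "-":
                flag |= 16
            if fi > 0:
                flag |= 2048
            if frag.strand == "+":
                seq = read.sequence
                lead, trail = s, L - e
            else:
                seq = revcomp(read.sequence)
                lead, trail = L - e, s
            cigar = _cigar_string(frag.ops, lead, trail, dialect)
            fields = [
                read.read_id,
                str(flag),
                frag.chrom,
                str(frag.ref_start + 1),
                "60",
                cigar,
                "*",
                "0",
                "0",
                seq,
                "*",
            ]
            if dialect == "m_md":
                fields.append(f"MD:Z:{_md_tag(frag.ops, frag.xbases)}")
            lines.append("\t".join(fields))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
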