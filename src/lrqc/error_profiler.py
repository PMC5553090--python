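"""Base-level error profiling of long-read alignments against a reference.

The profiler replays each best alignment path column by column against the
reference genome and accumulates:

* overall and per-type error rates (mismatch / insertion / deletion), with
  one shared denominator — total alignment columns = matches + mismatches +
  inserted bases + deleted bases — so per-type rates add up to the overall
  rate;
* context-specific error matrices: for every mismatch (ref→observed pair)
  and every inserted/deleted base, a 4×4 grid over the reference bases
  immediately 5' and 3' of the event;
* homopolymer statistics: the fraction of indels whose base equals an
  adjacent reference base ("loose") or both adjacent bases ("tight") — the
  characteristic long-read error mode.

Sampling follows the tool's reporting rules: overall rates are estimated
from alignments drawn in uniform random order until at least a target
number of aligned bases (default 1,000,000) is covered; context matrices
sample until every (preceding, following) context has been observed at
least a floor number of times (default 10,000).

All events are reported in reference-strand space so context cells are
comparable across reads; columns containing an N in read or reference are
dropped from numerator and denominator and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    OP_DELETION,
    OP_INSERTION,
    OP_MATCH,
    OP_MISMATCH,
    AlignmentPath,
    GenomeSequence,
    ReadAlignment,
)

BASES = ("A", "C", "G", "T")
MISMATCH_PAIRS = tuple((r, o) for r in BASES for o in BASES if r != o)


class Column(NamedTuple):
    """One alignment column in reference orientation.

    ``read_base``/``ref_base`` are '-' on the non-consuming side of indels;
    ``prev_ref``/``next_ref`` are the reference bases flanking the event
    (uppercased; 'N' past chromosome ends).
    """

    op: str  # match / mismatch / insertion / deletion / ambiguous
    read_base: str
    ref_base: str
    prev_ref: str
    next_ref: str
    genome_pos: int


def reconstruct_columns(
    path: AlignmentPath, genome: GenomeSequence
) -> Iterator[Column]:
    """Enumerate every M/=/X/I/D alignment column of a path.

    Intron (N) gaps contribute no columns.  Mismatches are determined by
    comparing SEQ to the reference (trusting =/X or MD typing where the
    comparison is ambiguous is unnecessary: the reference is authoritative
    here).  Requires the path to carry SEQ; raises ``ValueError`` otherwise.
    """
    if path.seq is None:
        raise ValueError(f"read {path.read_id}: SEQ unavailable, cannot type errors")
    seq = path.seq.upper()
    chrom = path.chrom
    span_s, span_e = path.genome_span
    # one contiguous fetch (with 1-base flanks) instead of per-column fetches
    ref = genome.fetch_padded(chrom, span_s - 1, span_e + 1).upper()
    off = span_s - 1

    def refbase(pos: int) -> str:
        return ref[pos - off]

    for eo in path.edit_ops:
        if eo.op in (OP_MATCH, OP_MISMATCH):
            q0, g0 = eo.read_offset, eo.genome_offset
            for k in range(eo.length):
                qb = seq[q0 + k]
                rb = refbase(g0 + k)
                if qb == "N" or rb == "N":
                    op = "ambiguous"
                else:
                    op = OP_MATCH if qb == rb else OP_MISMATCH
                yield Column(op, qb, rb, refbase(g0 + k - 1), refbase(g0 + k + 1), g0 + k)
        elif eo.op == OP_INSERTION:
            # context = reference bases flanking the insertion point; each
            # inserted base is a separate event with the same flanks
            g = eo.genome_offset
            prev_b, next_b = refbase(g - 1), refbase(g)
            for k in range(eo.length):
                qb = seq[eo.read_offset + k]
                op = "ambiguous" if qb == "N" else OP_INSERTION
                yield Column(op, qb, "-", prev_b, next_b, g)
        elif eo.op == OP_DELETION:
            g0 = eo.genome_offset
            prev_b, next_b = refbase(g0 - 1), refbase(g0 + eo.length)
            for k in range(eo.length):
                rb = refbase(g0 + k)
                op = "ambiguous" if rb == "N" else OP_DELETION
                yield Column(op, "-", rb, prev_b, next_b, g0 + k)


@dataclass
class ErrorRates:
    """Per-type error rates over sampled alignment columns.

    Rates share the denominator ``total_columns`` (matches + mismatches +
    inserted + deleted bases), so ``mismatch_rate + insertion_rate +
    deletion_rate == total_rate`` exactly.  ``proportions`` give each type's
    share of the overall error (undefined — NaN — when there are no errors).
    """

    matches: int = 0
    mismatches: int = 0
    insertions: int = 0
    deletions: int = 0
    ambiguous: int = 0
    sampled_reads: int = 0

    @property
    def total_columns(self) -> int:
        return self.matches + self.mismatches + self.insertions + self.deletions

    @property
    def errors(self) -> int:
        return self.mismatches + self.insertions + self.deletions

    def _rate(self, n: int) -> float:
        if self.total_columns == 0:
            raise ValueError("no aligned columns sampled: rates undefined")
        return n / self.total_columns

    @property
    def total_rate(self) -> float:
        return self._rate(self.errors)

    @property
    def mismatch_rate(self) -> float:
        return self._rate(self.mismatches)

    @property
    def insertion_rate(self) -> float:
        return self._rate(self.insertions)

    @property
    def deletion_rate(self) -> float:
        return self._rate(self.deletions)

    @property
    def proportions(self) -> dict[str, float]:
        e = self.errors
        if e == 0:
            return {t: float("nan") for t in ("mismatch", "insertion", "deletion")}
        return {
            "mismatch": self.mismatches / e,
            "insertion": self.insertions / e,
            "deletion": self.deletions / e,
        }

    def add_column(self, op: str) -> None:
        if op == OP_MATCH:
            self.matches += 1
        elif op == OP_MISMATCH:
            self.mismatches += 1
        elif op == OP_INSERTION:
            self.insertions += 1
        elif op == OP_DELETION:
            self.deletions += 1
        else:
            self.ambiguous += 1

    def as_table(self) -> pd.DataFrame:
        """One summary row: per-type rates (%) with each type's share of the overall error."""
        prop = self.proportions
        return pd.DataFrame(
            [
                {
                    "sampled_reads": self.sampled_reads,
                    "sampled_columns": self.total_columns,
                    "overall_pct": 100 * self.total_rate,
                    "insertion_pct": 100 * self.insertion_rate,
                    "insertion_of_overall_pct": 100 * prop["insertion"],
                    "deletion_pct": 100 * self.deletion_rate,
                    "deletion_of_overall_pct": 100 * prop["deletion"],
                    "mismatch_pct": 100 * self.mismatch_rate,
                    "mismatch_of_overall_pct": 100 * prop["mismatch"],
                }
            ]
        )


def _eligible_paths(reads: Iterable[ReadAlignment]) -> list[AlignmentPath]:
    return [r.best_path for r in reads if r.best_path is not None and r.best_path.seq is not None]


def overall_error_rates(
    reads: Iterable[ReadAlignment],
    genome: GenomeSequence,
    sample_target: int = 1_000_000,
    seed: int = 0,
) -> ErrorRates:
    """Estimate error rates by sampling best alignments.

    Reads are drawn in uniform random order without replacement until the
    cumulative number of alignment columns reaches ``sample_target`` (or the
    stream is exhausted, in which case all usable reads contribute).
    """
    paths = _eligible_paths(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))
    rates = ErrorRates()
    for idx in order:
        if rates.total_columns >= sample_target:
            break
        for col in reconstruct_columns(paths[idx], genome):
            rates.add_column(col.op)
        rates.sampled_reads += 1
    if rates.total_columns == 0:
        raise ValueError("zero aligned bases in input: error rates undefined")
    return rates


@dataclass
class ContextMatrix:
    """Counts of one error event per (preceding, following) reference context.

    ``focal`` is ``"X>Y"`` for mismatches (reference X observed as Y) and a
    single base for insertions/deletions.  ``denominators`` count how often
    each context was observed among sampled reference positions; frequency =
    count / denominator.
    """

    error_type: str
    focal: str
    counts: np.ndarray  # 4x4, rows = preceding base, cols = following base
    denominators: np.ndarray  # 4x4 context observation counts
    min_context_obs: int

    @property
    def frequencies(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.denominators > 0, self.counts / self.denominators, np.nan)

    @property
    def undersampled(self) -> bool:
        return bool((self.denominators < self.min_context_obs).any())

    def max_cell(self) -> tuple[str, str]:
        """(preceding, following) of the highest-frequency cell."""
        f = np.nan_to_num(self.frequencies, nan=-1.0)
        i, j = np.unravel_index(int(np.argmax(f)), f.shape)
        return BASES[i], BASES[j]


@dataclass
class ContextProfile:
    mismatch: dict[str, ContextMatrix]  # keyed "A>C", ...
    insertion: dict[str, ContextMatrix]  # keyed by inserted base
    deletion: dict[str, ContextMatrix]  # keyed by deleted base
    sampled_reads: int = 0
    sampled_columns: int = 0

    def matrices(self) -> Iterator[ContextMatrix]:
        yield from self.mismatch.values()
        yield from self.insertion.values()
        yield from self.deletion.values()

    def as_long_table(self) -> pd.DataFrame:
        rows = []
        for m in self.matrices():
            freq = m.frequencies
            for i, p in enumerate(BASES):
                for j, n in enumerate(BASES):
                    rows.append(
                        {
                            "error_type": m.error_type,
                            "focal": m.focal,
                            "prev": p,
                            "next": n,
                            "count": int(m.counts[i, j]),
                            "denominator": int(m.denominators[i, j]),
                            "frequency": float(freq[i, j]),
                        }
                    )
        return pd.DataFrame(rows)


_B2I = {b: i for i, b in enumerate(BASES)}


def context_error_matrices(
    reads: Iterable[ReadAlignment],
    genome: GenomeSequence,
    min_context_obs: int = 10_000,
    seed: int = 0,
) -> ContextProfile:
    """Context-specific error matrices from randomly sampled best alignments.

    Sampling stops once every (preceding, following) context has been
    observed at least ``min_context_obs`` times among reference-consuming
    columns; if the stream runs out first, matrices carry an
    ``undersampled`` flag.  The shared context denominator counts
    reference-consuming columns (matches, mismatches, deleted bases) with
    the given flanks; insertion frequencies reuse it as the per-junction
    exposure.
    """
    paths = _eligible_paths(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(paths))

    denom = np.zeros((4, 4), dtype=np.int64)
    mm = {f"{r}>{o}": np.zeros((4, 4), dtype=np.int64) for r, o in MISMATCH_PAIRS}
    ins = {b: np.zeros((4, 4), dtype=np.int64) for b in BASES}
    dele = {b: np.zeros((4, 4), dtype=np.int64) for b in BASES}
    n_reads = 0
    n_cols = 0

    for idx in order:
        if denom.min() >= min_context_obs:
            break
        for col in reconstruct_columns(paths[idx], genome):
            n_cols += 1
            p, q = col.prev_ref, col.next_ref
            if p == "N" or q == "N":
                continue
            i, j = _B2I[p], _B2I[q]
            if col.op in (OP_MATCH, OP_MISMATCH, OP_DELETION):
                denom[i, j] += 1
            if col.op == OP_MISMATCH:
                mm[f"{col.ref_base}>{col.read_base}"][i, j] += 1
            elif col.op == OP_INSERTION:
                ins[col.read_base][i, j] += 1
            elif col.op == OP_DELETION:
                dele[col.ref_base][i, j] += 1
        n_reads += 1

    def pack(kind: str, d: dict[str, np.ndarray]) -> dict[str, ContextMatrix]:
        return {
            k: ContextMatrix(kind, k, v, denom.copy(), min_context_obs)
            for k, v in d.items()
        }

    return ContextProfile(
        mismatch=pack("mismatch", mm),
        insertion=pack("insertion", ins),
        deletion=pack("deletion", dele),
        sampled_reads=n_reads,
        sampled_columns=n_cols,
    )


@dataclass
class HomopolymerStats:
    """Fraction of indels adjacent to an identical reference base.

    ``loose``: the inserted/deleted base equals the reference base
    immediately 5' *or* 3' of the event.  ``tight``: it equals both.
    """

    indels_total: int = 0
    loose_count: int = 0
    tight_count: int = 0
    per_base: dict = field(
        default_factory=lambda: {
            (t, b): {"total": 0, "loose": 0, "tight": 0}
            for t in (OP_INSERTION, OP_DELETION)
            for b in BASES
        }
    )

    @property
    def loose_fraction(self) -> float:
        return self.loose_count / self.indels_total if self.indels_total else float("nan")

    @property
    def tight_fraction(self) -> float:
        return self.tight_count / self.indels_total if self.indels_total else float("nan")

    def as_table(self) -> pd.DataFrame:
        rows = []
        for (t, b), d in self.per_base.items():
            rows.append({"error_type": t, "base": b, **d})
        df = pd.DataFrame(rows)
        df.attrs["loose_fraction"] = self.loose_fraction
        df.attrs["tight_fraction"] = self.tight_fraction
        return df


def homopolymer_stats(
    reads: Iterable[ReadAlignment], genome: GenomeSequence
) -> HomopolymerStats:
    """Tally homopolymer-context indels over all best alignments (both modes)."""
    stats = HomopolymerStats()
    for path in _eligible_paths(reads):
        for col in reconstruct_columns(path, genome):
            if col.op not in (OP_INSERTION, OP_DELETION):
                continue
            base = col.read_base if col.op == OP_INSERTION else col.ref_base
            loose = base in (col.prev_ref, col.next_ref)
            tight = base == col.prev_ref and base == col.next_ref
            stats.indels_total += 1
            d = stats.per_base[(col.op, base)]
            d["total"] += 1
            if loose:
                stats.loose_count += 1
                d["loose"] += 1
            if tight:
                stats.tight_count += 1
                d["tight"] += 1
    return stats
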