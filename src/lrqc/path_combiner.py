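"""Best-path selection and read-level alignment classification.

A long read may produce several alignment paths (primary + supplementary
records).  Each read is reduced to one *best* path — the path aligning the
most read bases — and classified by how its paths relate:

* ``single``         one path explains the read (or no pair of paths is worth
                     combining);
* ``gapped``         two paths sit close together on the same chromosome and
                     strand, in read-concordant order: one gene, one long gap;
* ``trans-chimeric`` paths fall on different loci — a library-preparation
                     artifact in non-tumor samples;
* ``self-chimeric``  paths cover overlapping genomic positions, typically
                     unremoved adapters;
* ``unaligned``      no path at all.

Two paths are only *combinable* when they are reasonably spaced along the
read (small overlap, small gap) and jointly align enough extra read bases
over the best single path; the thresholds live in
:class:`CombinationPolicy`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_formats import (
    GAPPED,
    SELF_CHIMERIC,
    SINGLE,
    TRANS_CHIMERIC,
    UNALIGNED,
    AlignmentPath,
    ReadAlignment,
)


@dataclass
class CombinationPolicy:
    """Thresholds deciding when two paths jointly explain one read.

    max_read_gap: largest unaligned stretch allowed between the two paths'
        read intervals (bases).
    max_read_overlap_fraction: largest allowed overlap of the two read
        intervals, as a fraction of the shorter interval.
    max_genomic_gap_for_gapped: largest genomic separation still called a
        gapped (intron-scale) alignment rather than a chimera.
    min_combined_gain: extra read bases the pair must align over the best
        single path to be worth combining.
    """

    max_read_gap: int = 100
    max_read_overlap_fraction: float = 0.2
    max_genomic_gap_for_gapped: int = 500_000
    min_combined_gain: int = 50

    def __post_init__(self) -> None:
        if min(self.max_read_gap, self.max_genomic_gap_for_gapped, self.min_combined_gain) < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.max_read_overlap_fraction <= 1.0:
            raise ValueError("max_read_overlap_fraction must be in [0,1]")


def select_best_path(paths: Sequence[AlignmentPath]) -> AlignmentPath:
    """The path aligning the most read bases; ties break on (chrom, start, strand)."""
    if not paths:
        raise ValueError("select_best_path requires at least one path")
    return min(paths, key=lambda p: (-p.aligned_read_bases,) + p.sort_key())


def _read_axis_relation(a: AlignmentPath, b: AlignmentPath) -> tuple[int, int]:
    """(overlap, gap) of the two read intervals on the original read axis."""
    (s1, e1), (s2, e2) = a.read_interval, b.read_interval
    overlap = max(0, min(e1, e2) - max(s1, s2))
    gap = max(0, max(s1, s2) - min(e1, e2))
    return overlap, gap


def _combinable(a: AlignmentPath, b: AlignmentPath, policy: CombinationPolicy) -> bool:
    overlap, gap = _read_axis_relation(a, b)
    shorter = min(
        a.read_interval[1] - a.read_interval[0],
        b.read_interval[1] - b.read_interval[0],
    )
    if shorter <= 0:
        return False
    return (
        overlap <= policy.max_read_overlap_fraction * shorter
        and gap <= policy.max_read_gap
    )


def _combined_aligned_bases(a: AlignmentPath, b: AlignmentPath) -> int:
    overlap, _ = _read_axis_relation(a, b)
    return a.aligned_read_bases + b.aligned_read_bases - overlap


def _pair_label(a: AlignmentPath, b: AlignmentPath, policy: CombinationPolicy) -> str:
    """Classify one combinable pair: self-chimeric / gapped / trans-chimeric."""
    if a.chrom == b.chrom:
        (as_, ae), (bs, be) = a.genome_span, b.genome_span
        g_overlap = min(ae, be) - max(as_, bs)
        if g_overlap > 0:
            return SELF_CHIMERIC
        if a.strand == b.strand:
            gap = max(as_, bs) - min(ae, be)
            # genomic order must be concordant with read order
            first_on_read, second_on_read = (
                (a, b) if a.read_interval <= b.read_interval else (b, a)
            )
            forward = first_on_read.genome_span[1] <= second_on_read.genome_span[0]
            concordant = forward if a.strand == "+" else not forward
            if gap <= policy.max_genomic_gap_for_gapped and concordant:
                return GAPPED
    return TRANS_CHIMERIC


def classify_read(
    read: ReadAlignment, policy: CombinationPolicy | None = None
) -> ReadAlignment:
    """Assign the read's classification, best path and mappable length in place.

    Label priority when multiple pairs disagree: self-chimeric >
    trans-chimeric > gapped.  Only the best combinable pair contributes to
    the combined length accounting; further paths still influence the label.
    """
    policy = policy or CombinationPolicy()
    if not read.paths:
        read.classification = UNALIGNED
        read.best_path = None
        read.mappable_length = 0
        read.combined_paths = []
        return read

    best = select_best_path(read.paths)
    read.best_path = best
    label = SINGLE
    best_pair: tuple[AlignmentPath, AlignmentPath] | None = None
    best_pair_bases = 0
    labels_seen: set[str] = set()

    # order paths deterministically so pair iteration is order-invariant
    paths = sorted(read.paths, key=lambda p: (-p.aligned_read_bases,) + p.sort_key())
    for i in range(len(paths)):
        for j in range(i + 1, len(paths)):
            a, b = paths[i], paths[j]
            if not _combinable(a, b, policy):
                continue
            combined = _combined_aligned_bases(a, b)
            if combined < best.aligned_read_bases + policy.min_combined_gain:
                continue
            labels_seen.add(_pair_label(a, b, policy))
            if combined > best_pair_bases:
                best_pair_bases = combined
                best_pair = (a, b)

    if labels_seen:
        for candidate in (SELF_CHIMERIC, TRANS_CHIMERIC, GAPPED):
            if candidate in labels_seen:
                label = candidate
                break

    read.classification = label
    if best_pair is not None:
        read.combined_paths = sorted(best_pair, key=lambda p: p.read_interval)
        read.mappable_length = best_pair_bases
    else:
        read.combined_paths = [best]
        read.mappable_length = best.aligned_read_bases
    return read


def classify_reads(
    reads: Iterable[ReadAlignment], policy: CombinationPolicy | None = None
) -> list[ReadAlignment]:
    policy = policy or CombinationPolicy()
    return [classify_read(r, policy) for r in reads]


DEFAULT_LENGTH_BINS: list[tuple[str, float, float]] = [
    ("all", 0, float("inf")),
    ("0-4kb", 0, 4000),
    (">4kb", 4000, float("inf")),
]


def classification_summary(
    reads: Sequence[ReadAlignment],
    length_bins: Sequence[tuple[str, float, float]] = tuple(DEFAULT_LENGTH_BINS),
) -> pd.DataFrame:
    """Class fractions overall and per read-length bin.

    Fractions are over *all* reads in the bin, unaligned included, and sum
    to 1 per non-empty bin.  Bins are (label, lo, hi) on total read length,
    left-closed right-open.
    """
    from .io_formats import CLASS_LABELS

    rows = []
    for label, lo, hi in length_bins:
        in_bin = [r for r in reads if lo <= r.read_length < hi]
        n = len(in_bin)
        counts = {c: 0 for c in CLASS_LABELS}
        for r in in_bin:
            counts[r.classification] += 1
        row: dict = {"bin": label, "n_reads": n}
        for c in CLASS_LABELS:
            row[f"count_{c}"] = counts[c]
            row[f"fraction_{c}"] = counts[c] / n if n else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def classification_table(reads: Sequence[ReadAlignment]) -> pd.DataFrame:
    """Per-read classification table (read_id, class, mappable_length, chroms)."""
    rows = []
    for r in reads:
        rows.append(
            {
                "read_id": r.read_id,
                "classification": r.classification,
                "read_length": r.read_length,
                "mappable_length": r.mappable_length,
                "chroms": ";".join(sorted({p.chrom for p in r.paths})),
            }
        )
    return pd.DataFrame(rows)
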