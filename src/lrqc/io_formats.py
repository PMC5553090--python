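"""Readers/writers for the standard formats and the internal domain types.

All internal coordinates are 0-based half-open; conversions from SAM (1-based)
and GTF (1-based closed) happen only here, at the I/O boundary.

The central types:

* :class:`AlignmentPath` — one contiguous aligned segment of a read.
* :class:`ReadAlignment`  — all paths of one read, plus the best path and the
  read-level classification assigned by :mod:`lrqc.path_combiner`.
* :class:`TranscriptModel` — an annotated isoform as an ordered exon chain.
* :class:`GenomeSequence` — case-preserving reference lookup (soft-masking,
  i.e. lowercase repeat annotation, is never normalised away silently).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

logger = logging.getLogger("lrqc")

# Edit-operation labels used throughout.
OP_MATCH = "match"
OP_MISMATCH = "mismatch"
OP_INSERTION = "insertion"
OP_DELETION = "deletion"

# Read-level classification labels.
UNALIGNED = "unaligned"
SINGLE = "single"
GAPPED = "gapped"
TRANS_CHIMERIC = "trans-chimeric"
SELF_CHIMERIC = "self-chimeric"
CLASS_LABELS = (UNALIGNED, SINGLE, GAPPED, TRANS_CHIMERIC, SELF_CHIMERIC)


@dataclass
class EditOp:
    """One typed edit operation of an alignment path.

    ``read_offset`` indexes into the path's ``seq`` (the SAM SEQ string, i.e.
    reference orientation, soft clips included); ``genome_offset`` is an
    absolute 0-based reference coordinate.  ``None`` offsets mark ops that do
    not consume that axis (deletions consume no read, insertions no genome).
    """

    op: str
    length: int
    read_offset: int | None
    genome_offset: int | None


@dataclass
class AlignmentPath:
    read_id: str
    chrom: str
    strand: str  # '+' or '-'
    read_interval: tuple[int, int]  # original read orientation, half-open
    genome_blocks: list[tuple[int, int]]  # sorted, half-open, one chromosome
    edit_ops: list[EditOp]
    aligned_read_bases: int
    read_length: int
    seq: str | None = None  # SAM SEQ (reference orientation) or None
    mismatches_typed: bool = False  # True when =/X or MD typed the mismatches

    @property
    def genome_span(self) -> tuple[int, int]:
        return self.genome_blocks[0][0], self.genome_blocks[-1][1]

    def sort_key(self) -> tuple:
        """Deterministic ordering key: (chrom, start, strand)."""
        return (self.chrom, self.genome_blocks[0][0], self.strand)


@dataclass
class ReadAlignment:
    read_id: str
    read_length: int
    paths: list[AlignmentPath] = field(default_factory=list)
    best_path: AlignmentPath | None = None
    classification: str | None = None
    mappable_length: int = 0
    # set by the combiner when a pair of paths jointly explains the read
    combined_paths: list[AlignmentPath] = field(default_factory=list)

    @property
    def aligned(self) -> bool:
        return bool(self.paths)


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, non-overlapping, half-open

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def is_singleton(self) -> bool:
        return len(self.exons) == 1

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def junctions(self) -> list[tuple[int, int]]:
        """(donor, acceptor) = (exon end, next exon start) in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


class GenomeSequence:
    """Case-preserving per-chromosome sequence access.

    Backed either by an in-memory dict (synthetic data, tests) or a pyfaidx
    ``Fasta`` handle.  Lookups outside chromosome bounds raise ``ValueError``;
    a missing chromosome raises ``KeyError`` naming it.
    """

    def __init__(self, sequences: dict[str, str] | None = None, fasta=None):
        self._seqs = sequences
        self._fasta = fasta
        if sequences is not None:
            self._lengths = {c: len(s) for c, s in sequences.items()}
        else:
            self._lengths = {name: len(fasta[name]) for name in fasta.keys()}

    @classmethod
    def from_dict(cls, sequences: dict[str, str]) -> "GenomeSequence":
        return cls(sequences=sequences)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        import pyfaidx

        return cls(fasta=pyfaidx.Fasta(str(path)))

    @property
    def chromosomes(self) -> list[str]:
        return list(self._lengths)

    def length(self, chrom: str) -> int:
        if chrom not in self._lengths:
            raise KeyError(f"chromosome {chrom!r} not in reference")
        return self._lengths[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom[start:end)`` with original case preserved."""
        n = self.length(chrom)
        if start < 0 or end > n or start > end:
            raise ValueError(
                f"window [{start},{end}) outside {chrom} bounds [0,{n})"
            )
        if self._seqs is not None:
            return self._seqs[chrom][start:end]
        return str(self._fasta[chrom][start:end])

    def fetch_padded(self, chrom: str, start: int, end: int, pad: str = "N") -> str:
        """Like :meth:`fetch` but out-of-bounds positions yield ``pad``."""
        n = self.length(chrom)
        left = max(0, -start)
        right = max(0, end - n)
        core = self.fetch(chrom, max(start, 0), min(end, n))
        return pad * left + core + pad * right


# ---------------------------------------------------------------------------
# SAM/BAM parsing
# ---------------------------------------------------------------------------

_CONSUMES_READ = {0, 1, 4, 7, 8}  # M I S = X
_CONSUMES_REF = {0, 2, 3, 7, 8}  # M D N = X


def _path_from_record(rec: pysam.AlignedSegment) -> AlignmentPath | None:
    """Build an AlignmentPath from one aligned SAM record.

    Returns None for records with malformed/absent CIGAR (counted upstream).
    """
    cig = rec.cigartuples
    if not cig:
        return None
    seq = rec.query_sequence  # None when SEQ is '*'
    hard_left = cig[0][1] if cig[0][0] == 5 else 0
    hard_right = cig[-1][1] if cig[-1][0] == 5 else 0
    seq_len = (
        len(seq)
        if seq is not None
        else sum(ln for op, ln in cig if op in _CONSUMES_READ and op != 5)
    )
    read_length = seq_len + hard_left + hard_right

    # typed mismatches available from =/X ops or an MD tag
    has_eqx = any(op in (7, 8) for op, _ in cig)
    has_md = rec.has_tag("MD") and seq is not None
    use_md = has_md and not has_eqx
    md_ref: dict[int, str] | None = None
    if use_md:
        md_ref = {
            rp: base.upper()
            for _, rp, base in rec.get_aligned_pairs(with_seq=True)
            if rp is not None and base is not None
        }

    edit_ops: list[EditOp] = []
    blocks: list[tuple[int, int]] = []
    qpos = 0  # offset into SEQ (soft clips included, hard clips excluded)
    gpos = rec.reference_start
    block_start = gpos
    aligned_read_bases = 0
    q_align_start = None
    q_align_end = 0

    for op, ln in cig:
        if op in (4,):  # soft clip
            qpos += ln
            continue
        if op == 5:  # hard clip
            continue
        if op == 3:  # N: intron — close current block
            blocks.append((block_start, gpos))
            gpos += ln
            block_start = gpos
            continue
        if op in (0, 7, 8):  # M / = / X
            if q_align_start is None:
                q_align_start = qpos
            if op == 7:
                edit_ops.append(EditOp(OP_MATCH, ln, qpos, gpos))
            elif op == 8:
                edit_ops.append(EditOp(OP_MISMATCH, ln, qpos, gpos))
            elif use_md:
                # split M by MD-derived per-base match/mismatch runs
                _append_md_typed(edit_ops, seq, md_ref, qpos, gpos, ln)
            else:
                edit_ops.append(EditOp(OP_MATCH, ln, qpos, gpos))
            qpos += ln
            gpos += ln
            q_align_end = qpos
            aligned_read_bases += ln
        elif op == 1:  # I
            if q_align_start is None:
                q_align_start = qpos
            edit_ops.append(EditOp(OP_INSERTION, ln, qpos, gpos))
            qpos += ln
            q_align_end = qpos
            aligned_read_bases += ln
        elif op == 2:  # D
            edit_ops.append(EditOp(OP_DELETION, ln, None, gpos))
            gpos += ln
        elif op == 6:  # P
            continue
        else:
            return None
    blocks.append((block_start, gpos))
    blocks = [b for b in blocks if b[1] > b[0]]
    if not blocks or q_align_start is None:
        return None

    # read interval in the original (pre-reverse-complement) orientation
    so_start = q_align_start + hard_left
    so_end = q_align_end + hard_left
    if rec.is_reverse:
        read_iv = (read_length - so_end, read_length - so_start)
        strand = "-"
    else:
        read_iv = (so_start, so_end)
        strand = "+"

    return AlignmentPath(
        read_id=rec.query_name,
        chrom=rec.reference_name,
        strand=strand,
        read_interval=read_iv,
        genome_blocks=blocks,
        edit_ops=edit_ops,
        aligned_read_bases=aligned_read_bases,
        read_length=read_length,
        seq=seq,
        mismatches_typed=has_eqx or use_md,
    )


def _append_md_typed(
    edit_ops: list[EditOp],
    seq: str,
    md_ref: dict[int, str],
    qpos: int,
    gpos: int,
    ln: int,
) -> None:
    """Split one M run into match/mismatch ops using MD-derived reference bases."""
    run_op = None
    run_start = 0
    for k in range(ln):
        rb = md_ref.get(gpos + k, "N")
        qb = seq[qpos + k]
        this = OP_MISMATCH if (rb != "N" and qb != "N" and rb != qb.upper()) else OP_MATCH
        if this != run_op:
            if run_op is not None:
                edit_ops.append(EditOp(run_op, k - run_start, qpos + run_start, gpos + run_start))
            run_op, run_start = this, k
    edit_ops.append(EditOp(run_op, ln - run_start, qpos + run_start, gpos + run_start))


def read_alignments(
    path: str | Path, require_seq: bool = False
) -> Iterator[ReadAlignment]:
    """Stream :class:`ReadAlignment` objects from a SAM/BAM file.

    Records are grouped by read name (both name-grouped and coordinate-sorted
    inputs work; grouping buffers paths per name).  One ReadAlignment is
    yielded per distinct read name; reads present only as unmapped records
    yield an object with empty ``paths``.  Malformed CIGARs are skipped with
    a logged warning.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    groups: dict[str, ReadAlignment] = {}
    order: list[str] = []
    n_bad = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            name = rec.query_name
            if name not in groups:
                groups[name] = ReadAlignment(read_id=name, read_length=0)
                order.append(name)
            ra = groups[name]
            if rec.is_unmapped:
                if ra.read_length == 0 and rec.query_sequence:
                    ra.read_length = len(rec.query_sequence)
                continue
            p = _path_from_record(rec)
            if p is None:
                n_bad += 1
                logger.warning("skipping record with unusable CIGAR: %s", name)
                continue
            ra.paths.append(p)
            ra.read_length = max(ra.read_length, p.read_length)
    if n_bad:
        logger.warning("%d records skipped for malformed CIGAR", n_bad)
    for name in order:
        yield groups[name]


# ---------------------------------------------------------------------------
# Reference FASTA
# ---------------------------------------------------------------------------

def read_reference(path: str | Path) -> GenomeSequence:
    """Load an (indexable) FASTA as a :class:`GenomeSequence`, case preserved."""
    return GenomeSequence.from_fasta(path)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation: GTF and GenePred
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def _finalize_exons(
    tid: str, exons: list[tuple[int, int]]
) -> list[tuple[int, int]] | None:
    if not exons:
        logger.warning("transcript %s has zero exons; skipped", tid)
        return None
    exons = sorted(exons)
    merged = [exons[0]]
    overlapped = False
    for s, e in exons[1:]:
        ps, pe = merged[-1]
        if s < pe:
            merged[-1] = (ps, max(pe, e))
            overlapped = True
        else:
            merged.append((s, e))
    if overlapped:
        logger.warning("transcript %s had overlapping exons; merged", tid)
    return merged


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Parse exon features of a GTF into :class:`TranscriptModel` objects.

    GTF is 1-based closed; exons come out 0-based half-open, sorted by
    genomic coordinate, assembled per transcript_id.
    """
    raw: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = dict(_GTF_ATTR.findall(f[8]))
            tid = attrs.get("transcript_id")
            if tid is None:
                continue
            d = raw.setdefault(
                tid,
                {
                    "gene": attrs.get("gene_id", tid),
                    "chrom": f[0],
                    "strand": f[6] if f[6] in "+-" else "+",
                    "exons": [],
                },
            )
            d["exons"].append((int(f[3]) - 1, int(f[4])))
    out = []
    for tid, d in raw.items():
        exons = _finalize_exons(tid, d["exons"])
        if exons is None:
            continue
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=d["gene"],
                chrom=d["chrom"],
                strand=d["strand"],
                exons=exons,
            )
        )
    return out


def read_genepred(path: str | Path) -> list[TranscriptModel]:
    """Parse a GenePred (or GenePredExt) file; coordinates are already 0-based."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            # optional leading UCSC bin column
            if len(f) >= 11 and f[0].isdigit() and f[3] in "+-":
                f = f[1:]
            name, chrom, strand = f[0], f[1], f[2]
            starts = [int(x) for x in f[8].rstrip(",").split(",") if x]
            ends = [int(x) for x in f[9].rstrip(",").split(",") if x]
            gene = f[11] if len(f) > 11 and f[11] else name
            exons = _finalize_exons(name, list(zip(starts, ends)))
            if exons is None:
                continue
            out.append(
                TranscriptModel(
                    transcript_id=name,
                    gene_id=gene,
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
    return out


def read_annotation(path: str | Path) -> list[TranscriptModel]:
    """Dispatch on extension: .gtf/.gff → GTF parser, otherwise GenePred."""
    s = str(path)
    if s.endswith((".gtf", ".gff")):
        return read_gtf(path)
    return read_genepred(path)


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            for s, e in t.exons:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tlrqc\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# BED12
# ---------------------------------------------------------------------------

def write_bed(reads: Iterable[ReadAlignment], path: str | Path) -> int:
    """Write each aligned read's best path as one BED12 line.

    Unaligned reads are omitted.  Returns the number of lines written.
    """
    n = 0
    with open(path, "w") as fh:
        for ra in reads:
            p = ra.best_path
            if p is None:
                continue
            start, end = p.genome_span
            sizes = ",".join(str(e - s) for s, e in p.genome_blocks) + ","
            starts = ",".join(str(s - start) for s, _ in p.genome_blocks) + ","
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(start),
                        str(end),
                        ra.read_id,
                        "0",
                        p.strand,
                        str(start),
                        str(end),
                        "0,0,0",
                        str(len(p.genome_blocks)),
                        sizes,
                        starts,
                    ]
                )
                + "\n"
            )
            n += 1
    return n


def read_bed(path: str | Path) -> list[dict]:
    """Parse BED12 back into block structure (for round-trip checks)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            sizes = [int(x) for x in f[10].rstrip(",").split(",") if x]
            offs = [int(x) for x in f[11].rstrip(",").split(",") if x]
            blocks = [(start + o, start + o + s) for o, s in zip(offs, sizes)]
            out.append(
                {
                    "chrom": chrom,
                    "name": f[3],
                    "strand": f[5],
                    "blocks": blocks,
                }
            )
    return out


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, qual_char: str = "I") -> None:
    """Write (name, sequence) pairs with a constant quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence
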