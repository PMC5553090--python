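import numpy as np
import pytest

from lrqc import io_formats as io
from lrqc import path_combiner as pc
from lrqc import synthetic_reads as sr


def make_path(
    read_id="r1",
    chrom="chr1",
    strand="+",
    read_iv=(0, 100),
    blocks=((0, 100),),
    aligned=None,
    read_length=None,
    seq=None,
):
    """Hand-built AlignmentPath for combiner/selector tests."""
    blocks = [tuple(b) for b in blocks]
    aligned = aligned if aligned is not None else read_iv[1] - read_iv[0]
    return io.AlignmentPath(
        read_id=read_id,
        chrom=chrom,
        strand=strand,
        read_interval=tuple(read_iv),
        genome_blocks=blocks,
        edit_ops=[],
        aligned_read_bases=aligned,
        read_length=read_length or read_iv[1],
        seq=seq,
    )


def make_read(paths, read_id="r1", read_length=None):
    rl = read_length or max((p.read_length for p in paths), default=0)
    return io.ReadAlignment(read_id=read_id, read_length=rl, paths=list(paths))


def write_sam(path, records, chroms):
    """Write a minimal SAM file from (name, flag, chrom, pos1, cigar, seq[, tags]) tuples."""
    lines = ["@HD\tVN:1.6"]
    for c, ln in chroms.items():
        lines.append(f"@SQ\tSN:{c}\tLN:{ln}")
    for rec in records:
        name, flag, chrom, pos1, cigar, seq = rec[:6]
        tags = list(rec[6:])
        fields = [name, str(flag), chrom, str(pos1), "60", cigar, "*", "0", "0", seq, "*"] + tags
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture(scope="session")
def toy_genome():
    genome, masked = sr.make_genome(seed=11, n_chrom=2, lengths=60_000, masked_fraction=0.0)
    return genome


@pytest.fixture(scope="session")
def toy_transcriptome(toy_genome):
    return sr.make_transcriptome(toy_genome, seed=12, n_genes=14)


@pytest.fixture(scope="session")
def ont_sim(toy_genome, toy_transcriptome):
    """A moderate ONT-like simulation shared across tests (no artifacts)."""
    return sr.simulate_reads(
        toy_transcriptome, toy_genome, sr.ErrorModel.ont_2d(), depth=5, seed=13
    )


@pytest.fixture(scope="session")
def ont_reads(ont_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("ontsim")
    paths = ont_sim.write(d)
    return pc.classify_reads(list(io.read_alignments(paths["sam"])))
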