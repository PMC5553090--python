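"""Transcript assignment, isoform identification, splice accuracy,
poly(A) detection and repeat fractions."""

import numpy as np
import pytest

from lrqc import io_formats as io
from lrqc import path_combiner as pc
from lrqc import synthetic_reads as sr
from lrqc import transcript_annotator as ta

from conftest import make_path, make_read


def tx(tid, exons, chrom="chr1", strand="+", gene="G"):
    return io.TranscriptModel(tid, gene, chrom, strand, [tuple(e) for e in exons])


def read_with_blocks(blocks, read_id="r"):
    blocks = [tuple(b) for b in blocks]
    total = sum(e - s for s, e in blocks)
    p = make_path(read_id=read_id, read_iv=(0, total), blocks=blocks)
    r = make_read([p], read_id=read_id)
    return pc.classify_read(r)


FIVE_EXONS = [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]


class TestAssignRead:
    def assign(self, blocks, transcripts, **kw):
        idx = ta.TranscriptIndex(transcripts)
        th = ta.AssignmentThresholds(**kw)
        return ta.assign_read(read_with_blocks(blocks), idx, th)

    def test_exact_copy_is_full_length_and_unique(self):
        t = tx("T1", FIVE_EXONS)
        (m,) = self.assign(FIVE_EXONS, [t])
        assert m.status == "full-length" and m.unique

    @pytest.mark.parametrize("cov,expected", [(80, 1), (79, 0)])
    def test_internal_exon_coverage_boundary(self, cov, expected):
        # exon 3 of 5 covered at exactly cov of 100 bases
        blocks = list(FIVE_EXONS)
        blocks[2] = (400, 400 + cov)
        t = tx("T1", FIVE_EXONS)
        ms = self.assign(blocks, [t])
        assert len(ms) == expected

    def test_consecutive_internal_run_is_partial(self):
        # 6-exon transcript; read covers exons 2..4 (0-based 1..3) fully
        exons6 = FIVE_EXONS + [(1000, 1100)]
        t = tx("T1", exons6)
        blocks = exons6[1:4]
        (m,) = self.assign(blocks, [t])
        assert m.status == "partial"
        assert m.matched_exon_range == (1, 4)

    def test_terminal_exons_any_positive_length(self):
        blocks = [(80, 100), (200, 300), (400, 500), (600, 700), (800, 820)]
        t = tx("T1", FIVE_EXONS)
        (m,) = self.assign(blocks, [t])
        assert m.status == "full-length"

    def test_subchain_isoform_pair(self):
        """A full-length read of the shorter isoform is full-length for it
        and at most partial for the containing isoform."""
        long_t = tx("L", FIVE_EXONS)
        short_t = tx("S", FIVE_EXONS[1:4])
        ms = self.assign(FIVE_EXONS[1:4], [long_t, short_t])
        by_id = {m.transcript_id: m for m in ms}
        assert by_id["S"].status == "full-length"
        assert by_id["L"].status == "partial"
        assert by_id["S"].unique

    def test_strand_enforcement_optional(self):
        t = tx("T1", FIVE_EXONS, strand="-")
        assert len(self.assign(FIVE_EXONS, [t])) == 1
        assert len(self.assign(FIVE_EXONS, [t], require_strand_match=True)) == 0


class TestIdentifyIsoforms:
    def identify(self, blocks_list, transcripts, mode="coverage"):
        reads = [read_with_blocks(b, read_id=f"r{i}") for i, b in enumerate(blocks_list)]
        asn = ta.assign_reads(reads, transcripts)
        return ta.identify_isoforms(asn, transcripts, mode=mode).set_index("transcript_id")

    @pytest.mark.parametrize("covered,expected", [(900, "identified"), (899, "not-identified")])
    def test_singleton_90_percent_boundary(self, covered, expected):
        t = tx("S1", [(0, 1000)])
        df = self.identify([[(0, covered)]], [t])
        assert df.loc["S1", "status"] == expected

    def test_multi_exon_perfect_read_full_length_identified(self):
        t = tx("T1", FIVE_EXONS)
        df = self.identify([FIVE_EXONS], [t])
        assert df.loc["T1", "status"] == "full-length-identified"

    def test_mutual_overlap_is_reciprocal(self):
        """A read block that covers 100% of an internal exon but overhangs it
        heavily fails the mutual rule (exon < 80% of block)."""
        t = tx("T1", [(0, 100), (200, 300), (400, 500)])
        blocks = [(0, 100), (170, 330), (400, 500)]  # middle block 160 bp vs 100 bp exon
        df = self.identify([blocks], [t])
        assert df.loc["T1", "status"] == "not-identified"

    def test_identification_monotone_in_reads(self):
        t = tx("T1", FIVE_EXONS)
        few = self.identify([FIVE_EXONS], [t])
        more = self.identify([FIVE_EXONS, [(0, 50)], FIVE_EXONS], [t])
        assert few.loc["T1", "status"] == more.loc["T1", "status"] == "full-length-identified"

    def test_sirv_mode_requires_unique_read(self):
        a = tx("A", FIVE_EXONS)
        b = tx("B", FIVE_EXONS, chrom="chr1")  # identical twin: nothing unique
        df = self.identify([FIVE_EXONS], [a, b], mode="sirv")
        assert set(df["status"]) == {"not-identified"}
        df2 = self.identify([FIVE_EXONS], [a], mode="sirv")
        assert df2.loc["A", "status"] == "identified"


class TestSpliceOffsets:
    def offsets(self, read_blocks, transcripts):
        return ta.splice_offsets([read_with_blocks(read_blocks)], transcripts)

    def test_exact_junction_is_perfect(self):
        t = tx("T1", [(0, 100), (200, 300)])
        offs, summ = self.offsets([(0, 100), (200, 300)], [t])
        assert offs[0].perfect and summ["perfect_fraction"] == 1.0

    def test_donor_into_exon_is_negative(self):
        t = tx("T1", [(0, 100), (200, 300)])
        offs, _ = self.offsets([(0, 96), (200, 300)], [t])
        assert offs[0].donor_offset == -4
        assert offs[0].acceptor_offset == 0
        assert not offs[0].perfect

    def test_acceptor_into_exon_is_negative(self):
        t = tx("T1", [(0, 100), (200, 300)])
        offs, _ = self.offsets([(0, 100), (204, 300)], [t])
        assert offs[0].acceptor_offset == -4

    def test_unmatched_junction_counted_novel(self):
        t = tx("T1", [(0, 100), (200, 300)])
        _, summ = self.offsets([(0, 500), (900, 1000)], [t])
        assert summ["n_novel"] == 1 and summ["n_junctions"] == 0

    def test_jittered_simulation_recovers_perfect_fraction(
        self, toy_genome, toy_transcriptome, tmp_path
    ):
        res = sr.simulate_reads(
            toy_transcriptome,
            toy_genome,
            sr.ErrorModel.perfect(),
            depth=10,
            junction_jitter_rate=0.1,
            seed=51,
        )
        paths = res.write(tmp_path)
        reads = pc.classify_reads(list(io.read_alignments(paths["sam"])))
        _, summ = ta.splice_offsets(reads, toy_transcriptome)
        tt = res.truth_table()
        n_j = int(tt.n_junctions.sum())
        n_jit = int(tt.n_jittered_junctions.sum())
        truth_perfect = 1 - n_jit / n_j
        assert summ["n_junctions"] == n_j
        assert summ["perfect_fraction"] == pytest.approx(truth_perfect)
        # realised jitter should be near the 10% request (binomial 99% CI)
        se = np.sqrt(0.1 * 0.9 / n_j)
        assert abs(n_jit / n_j - 0.1) < 2.58 * se


class TestPolyA:
    def test_a_tail_detected(self):
        r = ta.detect_polyA("r", "ACGT" * 20 + "A" * 30)
        assert r.detected and r.tail_kind == "A" and r.tail_length >= 30

    def test_random_sequence_not_detected(self):
        rng = np.random.default_rng(3)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 200))
        assert not ta.detect_polyA("r", seq).detected

    def test_t_head_detected(self):
        r = ta.detect_polyA("r", "T" * 25 + "ACGT" * 30)
        assert r.detected and r.tail_kind == "T"

    def test_short_read_not_detected(self):
        assert not ta.detect_polyA("r", "AAAA").detected

    def test_simulated_tail_fraction(self, toy_genome, toy_transcriptome):
        res = sr.simulate_reads(
            toy_transcriptome,
            toy_genome,
            sr.ErrorModel.perfect(),
            depth=6,
            tail_model=sr.TailModel(fraction=1.0, length_mean=30),
            seed=61,
        )
        tails = [ta.detect_polyA(r.read_id, r.sequence) for r in res.reads]
        frac = ta.polyA_summary(tails)["detected_fraction"]
        assert frac > 0.9


class TestRepeatFraction:
    def test_all_uppercase_is_zero(self):
        g = io.GenomeSequence.from_dict({"chr1": "ACGT" * 100})
        assert ta.repeat_fraction(tx("T", [(0, 100)]), g) == 0.0

    def test_all_lowercase_is_one(self):
        g = io.GenomeSequence.from_dict({"chr1": "acgt" * 100})
        assert ta.repeat_fraction(tx("T", [(0, 100)]), g) == 1.0

    def test_mixed_count(self):
        seq = "A" * 101 + "a" * 100 + "C" * 200
        g = io.GenomeSequence.from_dict({"chr1": seq})
        t = tx("T", [(0, 151), (151, 201)])  # 201 bases, 100 lowercase
        assert ta.repeat_fraction(t, g) == pytest.approx(100 / 201)

    def test_binning(self):
        g = io.GenomeSequence.from_dict({"chr1": "A" * 50 + "a" * 50 + "C" * 100})
        ts = [tx("zero", [(100, 200)]), tx("half", [(0, 100)]), tx("hi", [(40, 100)])]
        df = ta.repeat_fraction_table(ts, g).set_index("transcript_id")
        assert df.loc["zero", "bin"] == "0"
        assert df.loc["half", "bin"] == "(0,0.5]"
        assert df.loc["hi", "bin"] == ">0.5"
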