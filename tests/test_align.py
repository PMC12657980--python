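"""Built-in chained aligner, SAM path, and the both-ends ROI filter."""

import numpy as np
import pytest

from switchjoint.align import (
    AlignmentBlock,
    AlignmentChain,
    ReferenceIndex,
    chain_align_read,
    flip_chain,
    read_alignment_chains,
    roi_filter,
    write_sam,
)
from switchjoint.signature import revcomp


@pytest.fixture(scope="module")
def random_ref():
    rng = np.random.default_rng(31)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=40000))


class TestChainAlignRead:
    def test_exact_substring_single_plus_block(self, random_ref):
        read = random_ref[5000:8000]
        chain = chain_align_read(read, random_ref)
        assert len(chain.blocks) == 1
        b = chain.blocks[0]
        assert (b.ref_start, b.ref_end, b.read_start, b.read_end, b.strand) == (
            5000, 8000, 0, 3000, "+"
        )

    def test_two_segment_split_read(self, random_ref):
        read = random_ref[0:5000] + random_ref[30000:35000]
        chain = chain_align_read(read, random_ref)
        assert len(chain.blocks) == 2
        b1, b2 = chain.blocks
        assert (b1.ref_start, b1.ref_end, b1.strand) == (0, 5000, "+")
        assert (b2.ref_start, b2.ref_end, b2.strand) == (30000, 35000, "+")
        assert (b2.read_start, b2.read_end) == (5000, 10000)

    def test_inverted_second_segment(self, random_ref):
        read = random_ref[0:5000] + revcomp(random_ref[30000:35000])
        chain = chain_align_read(read, random_ref)
        assert [b.strand for b in chain.blocks] == ["+", "-"]
        assert (chain.blocks[1].ref_start, chain.blocks[1].ref_end) == (30000, 35000)

    def test_sparse_errors_do_not_split_blocks(self, random_ref):
        rng = np.random.default_rng(4)
        read = list(random_ref[5000:15000])
        for pos in rng.choice(len(read), size=20, replace=False):  # 0.2%
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        chain = chain_align_read("".join(read), random_ref)
        assert len(chain.blocks) == 1
        b = chain.blocks[0]
        assert abs(b.ref_start - 5000) <= 25 and abs(b.ref_end - 15000) <= 25

    def test_junction_end_lands_at_ambiguity_boundary(self, random_ref):
        # plant a 6-bp shared flank: both templates agree across the junction
        ref = list(random_ref)
        d, a = 10000, 25000
        ref[a - 6:a] = ref[d - 6:d]
        # pin the tract to exactly 6: break the match just outside it
        alphabet = "ACGT"
        ref[a - 7] = alphabet[(alphabet.index(ref[d - 7]) + 1) % 4]
        ref[a] = alphabet[(alphabet.index(ref[d]) + 1) % 4]
        ref = "".join(ref)
        read = ref[4000:d] + ref[a:31000]
        chain = chain_align_read(read, ref)
        assert len(chain.blocks) == 2
        b1, b2 = chain.blocks
        # donor block may extend right only through the (0 here) right-run;
        # acceptor block extends left through the 6 shared bases
        assert b1.ref_end == d
        assert b2.ref_start == a - 6
        assert b1.read_end - (b2.read_start) == 6  # MH overlap visible

    def test_no_anchors_empty_chain(self, random_ref):
        rng = np.random.default_rng(9)
        foreign = "".join("ACGT"[i] for i in rng.integers(0, 4, size=500))
        chain = chain_align_read(foreign, random_ref)
        assert chain.blocks == ()

    def test_short_read_rejected(self, random_ref):
        with pytest.raises(ValueError):
            chain_align_read("ACGT" * 5, random_ref)

    def test_prebuilt_index_equivalent(self, random_ref):
        idx = ReferenceIndex(random_ref)
        read = random_ref[1000:3000]
        assert chain_align_read(read, idx) == chain_align_read(read, random_ref)


class TestRoiFilter:
    def test_both_windows_hit(self, locus60):
        chain = AlignmentChain(
            "r", 20000,
            [
                AlignmentBlock(2000, 8000, 0, 6000, "+"),
                AlignmentBlock(47000, 55000, 6000, 14000, "+"),
            ],
        )
        assert roi_filter(chain, locus60)

    def test_single_window_fails(self, locus60):
        chain = AlignmentChain("r", 5000, [AlignmentBlock(2000, 7000, 0, 5000, "+")])
        assert not roi_filter(chain, locus60)

    def test_empty_chain_fails(self, locus60):
        assert not roi_filter(AlignmentChain("r", 100), locus60)

    def test_monotone_under_block_addition(self, locus60):
        base = [AlignmentBlock(2000, 8000, 0, 6000, "+"),
                AlignmentBlock(47000, 55000, 6000, 14000, "+")]
        chain = AlignmentChain("r", 20000, base)
        assert roi_filter(chain, locus60)
        more = AlignmentChain(
            "r", 20000, base + [AlignmentBlock(20000, 21000, 14000, 15000, "+")]
        )
        assert roi_filter(more, locus60)


class TestFlipChain:
    def test_involution(self):
        chain = AlignmentChain(
            "r", 1000,
            [AlignmentBlock(100, 400, 0, 300, "+"),
             AlignmentBlock(600, 900, 300, 600, "-")],
        )
        assert flip_chain(flip_chain(chain)) == chain


class TestSamRoundTrip:
    def test_cigar_with_clip_and_supplementary(self, tmp_path, locus60):
        # 50S100M primary plus 100M50S supplementary on the same read
        sam = tmp_path / "toy.sam"
        name = locus60.reference_name
        sam.write_text(
            "@HD\tVN:1.6\n"
            f"@SQ\tSN:{name}\tLN:{locus60.locus.end}\n"
            f"q1\t0\t{name}\t501\t60\t50S100M\t*\t0\t0\t{'A' * 150}\t*\n"
            f"q1\t2048\t{name}\t2001\t60\t100M50S\t*\t0\t0\t{'A' * 150}\t*\n"
        )
        chains = read_alignment_chains(sam, locus60)
        assert len(chains) == 1
        blocks = chains[0].blocks
        assert (blocks[0].read_start, blocks[0].read_end) == (0, 100)
        assert (blocks[0].ref_start, blocks[0].ref_end) == (2000, 2100)
        assert (blocks[1].read_start, blocks[1].read_end) == (50, 150)
        assert (blocks[1].ref_start, blocks[1].ref_end) == (500, 600)

    def test_simple_100m_offset(self, tmp_path, locus60):
        sam = tmp_path / "one.sam"
        name = locus60.reference_name
        sam.write_text(
            f"@SQ\tSN:{name}\tLN:{locus60.locus.end}\n"
            f"q\t0\t{name}\t501\t60\t100M\t*\t0\t0\t{'C' * 100}\t*\n"
        )
        chains = read_alignment_chains(sam, locus60)
        b = chains[0].blocks[0]
        assert (b.ref_start, b.ref_end, b.read_start, b.read_end) == (500, 600, 0, 100)

    def test_empty_file(self, tmp_path, locus60):
        sam = tmp_path / "empty.sam"
        sam.write_text(f"@SQ\tSN:{locus60.reference_name}\tLN:{locus60.locus.end}\n")
        assert read_alignment_chains(sam, locus60) == []

    def test_missing_reference_rejected(self, tmp_path, locus60):
        sam = tmp_path / "bad.sam"
        sam.write_text("@SQ\tSN:other\tLN:1000\n")
        with pytest.raises(ValueError, match="sequence dictionary"):
            read_alignment_chains(sam, locus60)

    def test_writer_reader_roundtrip_on_synthetic_reads(
        self, tmp_path, small_sim
    ):
        from switchjoint.simulate import render_lrpcr_reads

        params, reference, locus, events = small_sim
        dels = [e for e in events if e.orientation == "DEL"][:5]
        reads, _ = render_lrpcr_reads(dels, reference, locus, params,
                                      both_strands=False)
        idx = ReferenceIndex(reference)
        originals = []
        for rid, seq in reads:
            chain = chain_align_read(seq, idx, read_id=rid)
            originals.append((chain, seq))
        sam = tmp_path / "rt.sam"
        write_sam(originals, locus, sam)
        recovered = {c.read_id: c for c in read_alignment_chains(sam, locus)}
        for chain, _ in originals:
            got = recovered[chain.read_id]
            assert got.read_len == chain.read_len
            assert [
                (b.ref_start, b.ref_end, b.read_start, b.read_end, b.strand)
                for b in got.blocks
            ] == [
                (b.ref_start, b.ref_end, b.read_start, b.read_end, b.strand)
                for b in chain.blocks
            ]
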