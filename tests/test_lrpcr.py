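"""LR-PCR breakpoint calling, dedup/depth filter, joint classification."""

import pytest

from switchjoint.align import AlignmentBlock, AlignmentChain, ReferenceIndex, chain_align_read
from switchjoint.locus import LocusMap
from switchjoint.lrpcr import (
    BreakpointCall,
    BreakpointError,
    ComplexReadError,
    UniqueJunction,
    classify_joint,
    dedup_and_filter,
    extract_breakpoint,
    junctions_to_frame,
    run_lrpcr,
    summarize_lrpcr,
)
from switchjoint.simulate import render_lrpcr_reads


def two_block_chain(d=12000, a=41000, gap=0, read_len=None, locus=None):
    """DEL chain: donor block [9000, d), acceptor block [a, 53000)."""
    len1 = d - 9000
    len2 = 53000 - a
    rl = read_len or (len1 + max(gap, 0) + len2)
    return AlignmentChain(
        "read1", rl,
        [
            AlignmentBlock(9000, d, 0, len1, "+"),
            AlignmentBlock(a, 53000, len1 + gap, len1 + gap + len2, "+"),
        ],
    )


class TestExtractBreakpoint:
    def test_two_block_del(self, locus60):
        bp = extract_breakpoint(two_block_chain(), locus60)
        assert (bp.donor_break, bp.acceptor_break) == (12000, 41000)
        assert bp.orientation == "DEL" and bp.gap_read_bases == 0

    def test_mh_overlap_resolved_leftmost(self, locus60):
        bp = extract_breakpoint(two_block_chain(gap=-5), locus60)
        assert bp.gap_read_bases == -5
        assert bp.mh_observed == 5
        # ambiguous bases assigned to donor: acceptor break advanced by 5
        assert (bp.donor_break, bp.acceptor_break) == (12000, 41005)

    def test_planted_mh_read_places_leftmost(self, small_sim):
        # construct a read with an engineered shared flank and verify both
        # that the overlap is observed and both placements rebuild the read
        params, reference, locus, _ = small_sim
        ref = list(reference)
        d, a = 8000, 47000
        ref[a - 5:a] = ref[d - 5:d]
        alphabet = "ACGT"
        ref[a - 6] = alphabet[(alphabet.index(ref[d - 6]) + 1) % 4]
        ref[a] = alphabet[(alphabet.index(ref[d]) + 1) % 4]
        ref = "".join(ref)
        read = ref[locus.primer5.start:d] + ref[a:locus.primer3.end]
        chain = chain_align_read(read, ref, read_id="mh5")
        bp = extract_breakpoint(chain, locus)
        assert bp.mh_observed == 5
        assert (bp.donor_break, bp.acceptor_break) == (d, a)
        # both extreme placements reproduce the same molecule
        assert (
            ref[locus.primer5.start:d - 5] + ref[a - 5:locus.primer3.end] == read
        )

    def test_three_block_chain_secondary_junction(self, small_sim):
        # intra-Smu deletion followed by the Smu->acceptor junction
        params, reference, locus, _ = small_sim
        # y - x deliberately not a multiple of the 25-bp repeat unit, so the
        # intra-Smu junction is not phase-ambiguous
        x, y, d, a = 7000, 7612, 9000, 47000
        read = (
            reference[locus.primer5.start:x]
            + reference[y:d]
            + reference[a:locus.primer3.end]
        )
        chain = chain_align_read(read, reference, read_id="triple")
        assert len(chain.blocks) == 3
        bp = extract_breakpoint(chain, locus)
        # calls may sit a few bases into the junction's natural MH tract,
        # shifted identically on both sides (leftmost-in-read placement)
        t = bp.donor_break - d
        assert 0 <= t <= 4 and bp.acceptor_break - a == t
        assert len(bp.secondary_junctions) == 1
        sd, sa, sorient = bp.secondary_junctions[0]
        assert abs(sd - x) <= 4 and sa - y == sd - x and sorient == "DEL"

    def test_reverse_complement_read_normalized(self, small_sim):
        from switchjoint.signature import revcomp

        params, reference, locus, _ = small_sim
        d, a = 8500, 48000
        read = revcomp(reference[locus.primer5.start:d] + reference[a:locus.primer3.end])
        chain = chain_align_read(read, reference, read_id="rc")
        bp = extract_breakpoint(chain, locus)
        t = bp.donor_break - d
        assert 0 <= t <= 4 and bp.acceptor_break - a == t  # natural MH shift

    def test_missing_acceptor_block_rejected(self, locus60):
        chain = AlignmentChain(
            "r", 12000,
            [AlignmentBlock(2000, 8000, 0, 6000, "+"),
             AlignmentBlock(42000, 48000, 6000, 12000, "+")],
        )
        # second block overlaps roi3, fine; now one without roi3 overlap
        only5 = AlignmentChain("r", 6000, [AlignmentBlock(2000, 8000, 0, 6000, "+")])
        with pytest.raises(BreakpointError):
            extract_breakpoint(only5, locus60)

    def test_too_many_blocks_flagged_complex(self, locus60):
        blocks = [
            AlignmentBlock(2000 + i * 100, 2100 + i * 100, i * 100, (i + 1) * 100, "+")
            for i in range(4)
        ] + [AlignmentBlock(47000, 53000, 400, 6400, "+")]
        with pytest.raises(ComplexReadError):
            extract_breakpoint(AlignmentChain("r", 6400, blocks), locus60)


def call(d, a, read_id="r", orientation="DEL", gap=0):
    return BreakpointCall(read_id, d, a, orientation, gap, 12000)


class TestDedupAndFilter:
    def test_depth_floor(self, locus60):
        calls = (
            [call(12000, 41000, f"a{i}") for i in range(12)]
            + [call(12500, 41500, f"b{i}") for i in range(10)]
            + [call(13000, 42000, f"c{i}") for i in range(9)]
        )
        juncs = dedup_and_filter(calls, min_depth=10, locus=None)
        assert len(juncs) == 2
        assert sorted(j.depth for j in juncs) == [10, 12]

    def test_monotone_in_min_depth(self, locus60):
        calls = [
            call(12000 + 10 * k, 41000, f"r{k}_{i}")
            for k, depth in enumerate([12, 10, 9, 5, 1])
            for i in range(depth)
        ]
        counts = [
            len(dedup_and_filter(calls, min_depth=md, locus=None))
            for md in range(1, 21)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[9] == 2 and counts[10] == 1  # min_depth 10 and 11

    def test_blocklisted_junction_removed(self, small_sim):
        _, _, locus, _ = small_sim
        blocked = LocusMap(**{**locus.__dict__, "blocklist": ((7000, 47000),)})
        calls = [call(7000, 47000, f"x{i}") for i in range(50)]
        assert dedup_and_filter(calls, min_depth=10, locus=blocked) == []
        assert len(dedup_and_filter(calls, min_depth=10, locus=locus)) == 1

    def test_empty_input(self):
        assert dedup_and_filter([], min_depth=10) == []

    def test_consensus_majority_vote(self, small_sim):
        _, _, locus, _ = small_sim
        calls = [call(7000, 47000, f"m{i}", gap=-3) for i in range(8)] + [
            call(7000, 47000, "odd", gap=0)
        ]
        (j,) = dedup_and_filter(calls, min_depth=5, locus=locus)
        assert j.mh_len == 3 and j.consensus_insertion_len == 0


class TestClassifyJoint:
    def test_s_s_productive(self, small_sim):
        _, _, locus, _ = small_sim
        j = classify_joint(UniqueJunction(8000, 47000, "DEL", 12), locus)
        assert j.label == "S_S" and not j.resected
        assert j.productive_length  # coordinate amplicon within S_S window

    def test_acceptor_out_resected(self, small_sim):
        _, _, locus, _ = small_sim
        a = locus.acceptor_S.end + 300
        j = classify_joint(UniqueJunction(8000, a, "DEL", 12), locus)
        assert j.label == "RESECTED" and j.acceptor_out and not j.donor_out

    def test_short_coordinate_amplicon_unproductive(self, small_sim):
        _, _, locus, _ = small_sim
        # maximal deletion beyond both S borders -> below the productive floor
        d = locus.donor_S.start - 2000
        a = locus.acceptor_S.end + 2000
        j = classify_joint(UniqueJunction(d, a, "DEL", 12), locus)
        assert not j.productive_length and j.label == "RESECTED"

    def test_classification_idempotent(self, small_sim):
        _, _, locus, _ = small_sim
        j = classify_joint(UniqueJunction(8000, 47000, "DEL", 12), locus)
        assert classify_joint(j, locus) == j


class TestSummarize:
    def test_median_and_percentages(self, small_sim):
        _, _, locus, _ = small_sim
        kb = 1000
        lens = [5 * kb, 9 * kb, 11 * kb]
        s = summarize_lrpcr(lens, [], locus, n_reads_in=3)
        assert s.median_read_len == 9 * kb
        lens = [4.2 * kb, 9 * kb, 11 * kb]
        # synthetic productive_min is ~10 kb: one read below it here
        s = summarize_lrpcr(lens, [], locus)
        below = [x for x in lens if x <= locus.thresholds.productive_min_len]
        assert s.pct_reads_below_productive_min == pytest.approx(
            100.0 * len(below) / 3
        )

    def test_resected_percentage(self, small_sim):
        _, _, locus, _ = small_sim
        juncs = [classify_joint(UniqueJunction(8000 + i, 47000, "DEL", 12), locus)
                 for i in range(9)]
        juncs.append(
            classify_joint(
                UniqueJunction(8000, locus.acceptor_S.end + 500, "DEL", 12), locus
            )
        )
        s = summarize_lrpcr([10000] * 10, juncs, locus)
        assert s.pct_unique_junctions_resected == pytest.approx(10.0)

    def test_histogram_mass(self, small_sim):
        _, _, locus, _ = small_sim
        juncs = [classify_joint(UniqueJunction(7000 + 11 * i, 47000 + 7 * i, "DEL", 12), locus)
                 for i in range(20)]
        s = summarize_lrpcr([10000] * 20, juncs, locus)
        assert sum(s.donor_hist["counts"]) == 20
        assert sum(s.acceptor_hist["counts"]) == 20

    def test_no_reads_gives_absent_not_zero(self, small_sim):
        _, _, locus, _ = small_sim
        s = summarize_lrpcr([], [], locus, n_reads_in=0)
        assert s.median_read_len is None
        assert s.pct_reads_below_productive_min is None
        assert s.pct_unique_junctions_resected is None


class TestPipelineRecovery:
    def test_small_end_to_end_exact_recovery(self, small_sim):
        params, reference, locus, events = small_sim
        reads, unamplified = render_lrpcr_reads(events, reference, locus, params)
        result = run_lrpcr(reads, reference, locus, min_depth=params.depth_min)
        truth = {}
        for e in events:
            if e.orientation == "DEL":
                truth.setdefault((e.donor_break, e.acceptor_break), []).append(e)
        keys = {(j.donor_break, j.acceptor_break): j for j in result.junctions}
        matched = set()
        for (d, a), group in truth.items():
            mh = max(e.realized_mh for e in group)
            hit = next(
                ((d + t, a + t) for t in range(mh + 1) if (d + t, a + t) in keys),
                None,
            )
            assert hit is not None, f"event at {(d, a)} not recovered"
            matched.add(hit)
        assert matched == set(keys)
        # classification recomputable from coordinates
        for j in result.junctions:
            assert classify_joint(j, locus) == j
        # coordinate-derived amplicon equals observed read length (error-free)
        for j in result.junctions:
            assert j.amplicon_len_from_coords > 0

    def test_junction_frame_has_genome_coords(self, small_sim):
        params, reference, locus, events = small_sim
        reads, _ = render_lrpcr_reads(events[:10], reference, locus, params)
        result = run_lrpcr(reads, reference, locus, min_depth=1)
        df = junctions_to_frame(result.junctions, locus)
        if len(df):
            assert (df["donor_break_genome"] == df["donor_break"]).all()  # '+' locus
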