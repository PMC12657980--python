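"""LR-PCR long-read breakpoint calling and unique-junction analysis.

From ROI-passing alignment chains this module calls one primary breakpoint
per read (donor break on the Sµ side, acceptor break on the downstream
S-region side), deduplicates calls into unique junctions with a sequencing
depth floor (>= 10 reads by default, to counter PCR amplification bias),
classifies each joint as within-S (S_S) or resected, labels it by
coordinate-derived amplicon length against the productive window, and
summarizes read lengths and binned junction distributions.

Junction-placement convention: when microhomology lets both aligned blocks
claim the junction bases, the blocks overlap in read coordinates by m
bases.  Placement is resolved *leftmost-in-read* — the ambiguous bases are
assigned to the donor side and the acceptor block is advanced by m — so the
same physical junction always maps to a single key; m is recorded as the
per-read microhomology observation.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .align import AlignmentChain, ReferenceIndex, chain_align_read, flip_chain, roi_filter
from .locus import LocusMap, acceptor_break_inside, donor_break_inside

__all__ = [
    "BreakpointCall",
    "UniqueJunction",
    "LrpcrSummary",
    "LrpcrResult",
    "ComplexReadError",
    "BreakpointError",
    "extract_breakpoint",
    "dedup_and_filter",
    "classify_joint",
    "summarize_lrpcr",
    "run_lrpcr",
    "junctions_to_frame",
]


class BreakpointError(ValueError):
    """Chain does not satisfy the breakpoint-extraction precondition."""


class ComplexReadError(ValueError):
    """Chain has more blocks than the aligner contract allows."""


@dataclass(frozen=True)
class BreakpointCall:
    """Primary breakpoint of one read (canonical coordinates)."""

    read_id: str
    donor_break: int
    acceptor_break: int
    orientation: str  # DEL | INV
    gap_read_bases: int  # read bases between blocks; negative = MH overlap
    amplicon_len: int  # observed read length
    gap_seq: str = ""
    secondary_junctions: tuple = ()

    @property
    def insertion_len(self) -> int:
        return max(self.gap_read_bases, 0)

    @property
    def mh_observed(self) -> int:
        return max(-self.gap_read_bases, 0)


@dataclass(frozen=True)
class UniqueJunction:
    """Deduplicated breakpoint pair with support depth and labels."""

    donor_break: int
    acceptor_break: int
    orientation: str
    depth: int
    consensus_insertion_len: int = 0
    mh_len: int = 0
    donor_out: bool = False
    acceptor_out: bool = False
    productive_length: bool = False
    amplicon_len_from_coords: int = 0
    label: str = ""
    single_read: bool = False

    @property
    def resected(self) -> bool:
        return self.donor_out or self.acceptor_out

    @property
    def key(self):
        return (self.donor_break, self.acceptor_break, self.orientation)


def _junction_end(block, side: str) -> int:
    """Junction-facing coordinate of a block. side: 'downstream' for the
    block 5' of the junction in read order, 'upstream' for the block 3'."""
    if side == "downstream":
        return block.ref_end if block.strand == "+" else block.ref_start
    return block.ref_start if block.strand == "+" else block.ref_end


def extract_breakpoint(chain: AlignmentChain, locus: LocusMap,
                       max_blocks: int = 4, read_seq: str = None) -> BreakpointCall:
    """Call the primary donor->acceptor breakpoint of one ROI-passing chain.

    The acceptor block is the ROI3-overlapping block holding the read's 3'
    end; the donor block is the last ROI5-overlapping block preceding it in
    read order, so with intra-Sµ deletions the primary junction is the
    Sµ->acceptor span and earlier block-to-block junctions are recorded as
    ``secondary_junctions``.  Chains whose 5'-most block is on the minus
    strand are flipped first (reads are sequenced from either amplicon
    strand).  Orientation is DEL when both junction blocks share a strand,
    INV otherwise.  MH overlaps are resolved leftmost-in-read (see module
    docstring).
    """
    if not roi_filter(chain, locus):
        raise BreakpointError("chain does not pass the both-ends ROI filter")
    if len(chain.blocks) > max_blocks:
        raise ComplexReadError(
            f"{chain.read_id}: {len(chain.blocks)} blocks exceed max_blocks={max_blocks}"
        )
    if chain.blocks[0].strand == "-":
        chain = flip_chain(chain)
        read_seq = None  # gap bases would need the flipped sequence

    blocks = chain.blocks
    w5, w3 = locus.roi5_window, locus.roi3_window

    def overlaps(b, w):
        return b.ref_start < w.end and w.start < b.ref_end

    acceptor_idx = None
    for i in reversed(range(len(blocks))):
        if overlaps(blocks[i], w3):
            acceptor_idx = i
            break
    if acceptor_idx is None or acceptor_idx == 0:
        raise BreakpointError("chain lacks an acceptor-side (ROI3) block")
    donor_idx = None
    for i in reversed(range(acceptor_idx)):
        if overlaps(blocks[i], w5):
            donor_idx = i
            break
    if donor_idx is None:
        raise BreakpointError("chain lacks a donor-side (ROI5) block")

    donor, acceptor = blocks[donor_idx], blocks[acceptor_idx]
    orientation = "DEL" if donor.strand == acceptor.strand else "INV"
    donor_break = _junction_end(donor, "downstream")
    acceptor_break = _junction_end(acceptor, "upstream")
    gap = acceptor.read_start - donor.read_end
    if gap < 0:
        m = -gap
        # leftmost-in-read: ambiguous bases stay with the donor side
        if acceptor.strand == "+":
            acceptor_break += m
        else:
            acceptor_break -= m
    gap_seq = ""
    if gap > 0 and read_seq is not None:
        gap_seq = read_seq[donor.read_end:acceptor.read_start]

    secondary = []
    for i in range(len(blocks) - 1):
        if i == donor_idx and i + 1 == acceptor_idx:
            continue
        b1, b2 = blocks[i], blocks[i + 1]
        j2 = _junction_end(b2, "upstream")
        sec_overlap = b1.read_end - b2.read_start
        if sec_overlap > 0:  # same leftmost-in-read resolution as the primary
            j2 += sec_overlap if b2.strand == "+" else -sec_overlap
        secondary.append(
            (
                _junction_end(b1, "downstream"),
                j2,
                "DEL" if b1.strand == b2.strand else "INV",
            )
        )

    return BreakpointCall(
        read_id=chain.read_id,
        donor_break=donor_break,
        acceptor_break=acceptor_break,
        orientation=orientation,
        gap_read_bases=gap,
        amplicon_len=chain.read_len,
        gap_seq=gap_seq,
        secondary_junctions=tuple(secondary),
    )


def _majority(values):
    """Majority vote; ties broken toward the smallest value."""
    counts = Counter(values)
    top = max(counts.values())
    return min(v for v, c in counts.items() if c == top)


def dedup_and_filter(calls, min_depth: int = 10, locus: LocusMap = None,
                     blocklist_tol: int = 0):
    """Deduplicate breakpoint calls into unique junctions with a depth floor.

    Calls are grouped by (donor_break, acceptor_break, orientation); each
    group's depth is its read count, and groups below ``min_depth`` are
    discarded — only unique breakpoints with sufficient sequencing depth are
    carried forward, to counteract PCR amplification bias.  Groups matching
    a locus blocklist entry (within ``blocklist_tol`` bp on both
    coordinates; default exact) are removed, e.g. a cell line's rearranged
    non-productive allele.  Consensus insertion and MH lengths are majority
    votes over the group.
    """
    groups = defaultdict(list)
    for c in calls:
        groups[(c.donor_break, c.acceptor_break, c.orientation)].append(c)

    blocklist = tuple(locus.blocklist) if locus is not None else ()
    out = []
    for (db, ab, orient), group in sorted(groups.items()):
        depth = len(group)
        if depth < min_depth:
            continue
        if any(
            abs(db - bdb) <= blocklist_tol and abs(ab - bab) <= blocklist_tol
            for bdb, bab in blocklist
        ):
            continue
        ins = _majority([c.insertion_len for c in group])
        mh = _majority([c.mh_observed for c in group])
        if ins > 0:
            mh = 0
        j = UniqueJunction(
            donor_break=db,
            acceptor_break=ab,
            orientation=orient,
            depth=depth,
            consensus_insertion_len=ins,
            mh_len=mh,
            single_read=depth == 1,
        )
        out.append(classify_joint(j, locus) if locus is not None else j)
    return out


def classify_joint(j: UniqueJunction, locus: LocusMap) -> UniqueJunction:
    """Label one junction: S_S vs resected, and productive-length flag.

    A joint is resected when either break coordinate lies outside its S
    region.  The productive-length flag compares the coordinate-derived
    amplicon length — (donor_break - primer5.start) + insertion +
    (primer3.end - acceptor_break) — against the isotype's productive
    minimum (e.g. 4.9 kb for Sµ-Sγ1).
    """
    donor_out = not donor_break_inside(locus.donor_S, j.donor_break)
    acceptor_out = not acceptor_break_inside(locus.acceptor_S, j.acceptor_break)
    amplicon = (
        (j.donor_break - locus.primer5.start)
        + j.consensus_insertion_len
        + (locus.primer3.end - j.acceptor_break)
    )
    return replace(
        j,
        donor_out=donor_out,
        acceptor_out=acceptor_out,
        label="RESECTED" if (donor_out or acceptor_out) else "S_S",
        productive_length=amplicon > locus.thresholds.productive_min_len,
        amplicon_len_from_coords=amplicon,
    )


@dataclass
class LrpcrSummary:
    n_reads_in: int
    n_reads_pass_roi: int
    n_unique_junctions: int
    median_read_len: float = None
    pct_reads_below_productive_min: float = None
    pct_unique_junctions_resected: float = None
    pct_donor_inside_S: float = None
    pct_acceptor_inside_S: float = None
    bin_width: int = 250
    donor_hist: dict = field(default_factory=dict)
    acceptor_hist: dict = field(default_factory=dict)

    def to_dict(self):
        return asdict(self)


def _coord_hist(coords, window, bin_width):
    edges = np.arange(window.start, window.end + bin_width, bin_width)
    counts, _ = np.histogram(coords, bins=edges)
    return {
        "start": int(edges[0]),
        "bin_width": int(bin_width),
        "counts": counts.astype(int).tolist(),
    }


def summarize_lrpcr(read_lengths, junctions, locus: LocusMap,
                    bin_width: int = 250, n_reads_in: int = None) -> LrpcrSummary:
    """Per-sample LR-PCR summary.

    ``read_lengths`` are the lengths of ROI-passing reads; ``junctions`` the
    classified unique junctions.  Read-length metrics use observed lengths
    (what the sequencer saw); junction classifications use coordinates —
    both views are reported.  With no passing reads, percentage fields stay
    absent (None) rather than 0.
    """
    lens = np.asarray(list(read_lengths))
    juncs = list(junctions)
    s = LrpcrSummary(
        n_reads_in=n_reads_in if n_reads_in is not None else len(lens),
        n_reads_pass_roi=len(lens),
        n_unique_junctions=len(juncs),
        bin_width=bin_width,
    )
    if len(lens):
        s.median_read_len = float(np.median(lens))
        s.pct_reads_below_productive_min = float(
            100.0 * np.mean(lens <= locus.thresholds.productive_min_len)
        )
    if juncs:
        s.pct_unique_junctions_resected = 100.0 * sum(
            1 for j in juncs if j.resected
        ) / len(juncs)
        s.pct_donor_inside_S = 100.0 * sum(
            1 for j in juncs if not j.donor_out
        ) / len(juncs)
        s.pct_acceptor_inside_S = 100.0 * sum(
            1 for j in juncs if not j.acceptor_out
        ) / len(juncs)
        s.donor_hist = _coord_hist(
            [j.donor_break for j in juncs], locus.roi5_window, bin_width
        )
        s.acceptor_hist = _coord_hist(
            [j.acceptor_break for j in juncs], locus.roi3_window, bin_width
        )
    return s


@dataclass
class LrpcrResult:
    summary: LrpcrSummary
    junctions: list
    calls: list
    n_reads_in: int
    n_pass_roi: int
    n_complex: int
    n_failed: int


def run_lrpcr(reads, reference: str, locus: LocusMap, min_depth: int = 10,
              bin_width: int = 250, k: int = 21, min_block: int = 100,
              max_blocks: int = 4, keep_calls: bool = False) -> LrpcrResult:
    """Full LR-PCR pipeline over an iterable of (read_id, sequence) pairs.

    Aligns each read with the built-in chained aligner, applies the
    both-ends ROI filter, extracts breakpoints, deduplicates with the depth
    floor and classifies joints.  For externally mapped data, feed chains
    from :func:`switchjoint.align.read_alignment_chains` to
    :func:`calls_from_chains` instead.
    """
    index = ReferenceIndex(reference, k)
    calls, lengths = [], []
    n_in = n_pass = n_complex = n_failed = 0
    for read_id, seq in reads:
        n_in += 1
        chain = chain_align_read(seq, index, min_block=min_block, read_id=read_id)
        if not roi_filter(chain, locus):
            continue
        n_pass += 1
        lengths.append(len(seq))
        try:
            calls.append(
                extract_breakpoint(chain, locus, max_blocks=max_blocks, read_seq=seq)
            )
        except ComplexReadError:
            n_complex += 1
        except BreakpointError:
            n_failed += 1
    junctions = dedup_and_filter(calls, min_depth=min_depth, locus=locus)
    summary = summarize_lrpcr(lengths, junctions, locus, bin_width, n_reads_in=n_in)
    return LrpcrResult(
        summary=summary,
        junctions=junctions,
        calls=calls if keep_calls else [],
        n_reads_in=n_in,
        n_pass_roi=n_pass,
        n_complex=n_complex,
        n_failed=n_failed,
    )


def calls_from_chains(chains, locus: LocusMap, max_blocks: int = 4):
    """Breakpoint calls (and ROI-passing read lengths) from parsed chains."""
    calls, lengths = [], []
    n_complex = n_failed = 0
    for chain in chains:
        if not roi_filter(chain, locus):
            continue
        lengths.append(chain.read_len)
        try:
            calls.append(extract_breakpoint(chain, locus, max_blocks=max_blocks))
        except ComplexReadError:
            n_complex += 1
        except BreakpointError:
            n_failed += 1
    return calls, lengths, n_complex, n_failed


def junctions_to_frame(junctions, locus: LocusMap = None) -> pd.DataFrame:
    """Unique-junction table (canonical plus genome coordinates)."""
    rows = []
    for j in junctions:
        row = {
            "donor_break": j.donor_break,
            "acceptor_break": j.acceptor_break,
            "orientation": j.orientation,
            "depth": j.depth,
            "insertion_len": j.consensus_insertion_len,
            "mh_len": j.mh_len,
            "label": j.label,
            "donor_out": j.donor_out,
            "acceptor_out": j.acceptor_out,
            "productive_length": j.productive_length,
            "amplicon_len_from_coords": j.amplicon_len_from_coords,
        }
        if locus is not None:
            row["donor_break_genome"] = locus.break_to_genome(j.donor_break)
            row["acceptor_break_genome"] = locus.break_to_genome(j.acceptor_break)
        rows.append(row)
    return pd.DataFrame(rows)
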