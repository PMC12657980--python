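"""Per-read alignment chains over a switch locus.

Two paths produce the same :class:`AlignmentChain` representation:

* :func:`read_alignment_chains` parses standard SAM/BAM produced by an
  external long-read mapper (the real-data path), converting each primary or
  supplementary record into one aligned block in canonical coordinates;
* :func:`chain_align_read` is a built-in exact-seed chained aligner used on
  synthetic reads, so the test suite runs without any external binary.  It
  is deliberately not a general mapper: its contract is a handful of
  segments (split reads), divergence within ~2%, and unique seed k-mers.

The built-in aligner indexes unique k-mers of both reference strands,
chains anchors by diagonal, and extends block ends base-by-base.  Extension
crosses *isolated* mismatches (sequencing errors) but stops at the first
mismatch that is followed by another one within a short window — the
density jump that marks the switch to the other template at a junction.
With error-free reads this places each junction-facing block end exactly at
the end of the junction's microhomology-ambiguity tract, which is what
makes breakpoint calls exact up to the documented MH shift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from .locus import LocusMap
from .signature import revcomp

__all__ = [
    "AlignmentBlock",
    "AlignmentChain",
    "ReferenceIndex",
    "chain_align_read",
    "read_alignment_chains",
    "roi_filter",
    "flip_chain",
    "write_sam",
]


@dataclass(frozen=True)
class AlignmentBlock:
    """One aligned block: canonical ref interval, as-sequenced read interval."""

    ref_start: int
    ref_end: int
    read_start: int
    read_end: int
    strand: str
    matches: int = 0

    def __post_init__(self):
        if self.ref_start >= self.ref_end or self.read_start >= self.read_end:
            raise ValueError("block intervals must be non-empty half-open")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class AlignmentChain:
    """Ordered aligned blocks of one read (sorted by read_start)."""

    read_id: str
    read_len: int
    blocks: tuple = ()

    def __post_init__(self):
        object.__setattr__(
            self, "blocks", tuple(sorted(self.blocks, key=lambda b: b.read_start))
        )


def flip_chain(chain: AlignmentChain) -> AlignmentChain:
    """The same chain with the read reverse-complemented (coords mirrored)."""
    n = chain.read_len
    blocks = [
        AlignmentBlock(
            ref_start=b.ref_start,
            ref_end=b.ref_end,
            read_start=n - b.read_end,
            read_end=n - b.read_start,
            strand="+" if b.strand == "-" else "-",
            matches=b.matches,
        )
        for b in chain.blocks
    ]
    return AlignmentChain(chain.read_id, n, blocks)


# ---------------------------------------------------------------------------
# built-in exact-seed chained aligner


class ReferenceIndex:
    """Unique k-mer index over both strands of one reference sequence."""

    def __init__(self, reference: str, k: int = 21):
        if len(reference) < k:
            raise ValueError(f"reference shorter than k={k}")
        self.k = k
        self.seq = reference
        self.rc = revcomp(reference)
        self.arr = np.frombuffer(reference.encode(), dtype=np.uint8)
        self.rc_arr = np.frombuffer(self.rc.encode(), dtype=np.uint8)
        index: dict = {}
        ambig = object()
        for strand, seq in (("+", reference), ("-", self.rc)):
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos:pos + k]
                if kmer in index:
                    index[kmer] = ambig
                else:
                    index[kmer] = (pos, strand)
        self._ambig = ambig
        self.index = index

    def lookup(self, kmer: str):
        hit = self.index.get(kmer)
        if hit is None or hit is self._ambig:
            return None
        return hit


def _extend_forward(read_arr, ref_arr, r0: int, f0: int,
                    lookthrough: int = 20, max_diverg: float = 0.02) -> int:
    """Bases the alignment extends beyond (r0, f0) walking forward.

    Isolated mismatches (next mismatch >= ``lookthrough`` bases away) are
    crossed; the first mismatch followed by another within the window ends
    the extension (template switch).  A cumulative-divergence guard bounds
    crossings to roughly ``max_diverg``.
    """
    m = min(len(read_arr) - r0, len(ref_arr) - f0)
    if m <= 0:
        return 0
    neq = np.nonzero(read_arr[r0:r0 + m] != ref_arr[f0:f0 + m])[0]
    if neq.size == 0:
        return m
    crossed = 0
    for i, q in enumerate(neq):
        nxt = neq[i + 1] if i + 1 < neq.size else m
        if nxt - q - 1 < lookthrough:
            return int(q)
        crossed += 1
        if crossed > 2 + max_diverg * q:
            return int(q)
    return m


def _extend_backward(read_arr, ref_arr, r0: int, f0: int,
                     lookthrough: int = 20, max_diverg: float = 0.02) -> int:
    """Mirror of :func:`_extend_forward`, walking from (r0-1, f0-1) leftward."""
    return _extend_forward(
        read_arr[:r0][::-1], ref_arr[:f0][::-1], 0, 0, lookthrough, max_diverg
    )


def chain_align_read(read: str, reference, k: int = 21, max_diverg: float = 0.02,
                     min_block: int = 100, stride: int = 32,
                     read_id: str = "read") -> AlignmentChain:
    """Align one read against the locus reference by unique-anchor chaining.

    ``reference`` may be the sequence string or a prebuilt
    :class:`ReferenceIndex` (build one per locus when aligning many reads).
    Returns an empty chain when no anchors are found.
    """
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, k)
    k = index.k
    if len(read) < 2 * k:
        raise ValueError(f"read shorter than 2k = {2 * k}")

    read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
    blocks = _chain_blocks(read, read_arr, index, max_diverg, min_block, stride)
    if not blocks and stride > 8:
        blocks = _chain_blocks(read, read_arr, index, max_diverg, min_block, 8)
    return AlignmentChain(read_id, len(read), blocks)


def _chain_blocks(read, read_arr, index, max_diverg, min_block, stride):
    k = index.k
    positions = list(range(0, len(read) - k + 1, stride))
    if positions[-1] != len(read) - k:
        positions.append(len(read) - k)
    anchors = []  # (read_pos, frame_pos, strand); frame_pos is rc-frame for '-'
    for r in positions:
        hit = index.lookup(read[r:r + k])
        if hit is not None:
            anchors.append((r, hit[0], hit[1]))

    # band tolerates 1-bp-indel diagonal drift between adjacent anchors while
    # rejecting spurious junction-spanning k-mer hits on nearby diagonals
    band, max_anchor_gap = 16, 4000
    groups = []
    for r, p, strand in anchors:
        diag = p - r
        g = groups[-1] if groups else None
        if (
            g is not None
            and g["strand"] == strand
            and abs(diag - g["diag"]) <= band
            and r - g["last_r"] <= max_anchor_gap
        ):
            g["last_r"], g["last_p"], g["diag"] = r, p, diag
        else:
            groups.append(
                {"strand": strand, "first_r": r, "first_p": p,
                 "last_r": r, "last_p": p, "diag": diag}
            )

    L = len(index.seq)
    blocks = []
    for g in groups:
        frame_arr = index.arr if g["strand"] == "+" else index.rc_arr
        r0, p0 = g["first_r"], g["first_p"]
        r1, p1 = g["last_r"] + k, g["last_p"] + k
        left = _extend_backward(read_arr, frame_arr, r0, p0,
                                max_diverg=max_diverg)
        right = _extend_forward(read_arr, frame_arr, r1, p1,
                                max_diverg=max_diverg)
        read_s, read_e = r0 - left, r1 + right
        frame_s, frame_e = p0 - left, p1 + right
        if read_e - read_s < min_block:
            continue
        if g["strand"] == "+":
            ref_s, ref_e = frame_s, frame_e
        else:
            ref_s, ref_e = L - frame_e, L - frame_s
        blocks.append(
            AlignmentBlock(
                ref_start=ref_s,
                ref_end=ref_e,
                read_start=read_s,
                read_end=read_e,
                strand=g["strand"],
                matches=read_e - read_s,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# standard-format path


def read_alignment_chains(path, locus: LocusMap):
    """Parse SAM/BAM into per-read alignment chains in canonical coordinates.

    Primary and supplementary records are grouped per read name; unmapped
    and secondary records are ignored (reads left with no usable record are
    dropped).  Soft and hard clips are consumed to recover as-sequenced read
    coordinates.  Raises ValueError when the file's sequence dictionary does
    not name the locus reference.
    """
    mode = "rb" if str(path).endswith(".bam") else "r"
    per_read: dict = {}
    read_lens: dict = {}
    n_unusable = 0
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        if locus.reference_name not in (fh.references or ()):
            raise ValueError(
                f"sequence dictionary lacks locus reference {locus.reference_name!r}"
            )
        for rec in fh:
            if rec.is_unmapped or rec.reference_name != locus.reference_name:
                continue
            if rec.is_secondary:
                if rec.query_name not in per_read:
                    n_unusable += 1
                continue
            block, total_len = _record_to_block(rec, locus)
            per_read.setdefault(rec.query_name, []).append(block)
            read_lens[rec.query_name] = total_len
    chains = [
        AlignmentChain(name, read_lens[name], blocks)
        for name, blocks in sorted(per_read.items())
    ]
    return chains


def _record_to_block(rec, locus: LocusMap):
    cig = rec.cigartuples or []
    lead = 0
    for op, ln in cig:
        if op in (4, 5):  # S, H
            lead += ln
        else:
            break
    tail = 0
    for op, ln in reversed(cig):
        if op in (4, 5):
            tail += ln
        else:
            break
    aligned = sum(ln for op, ln in cig if op in (0, 1, 7, 8))  # M, I, =, X
    total = lead + aligned + tail
    if rec.is_reverse:
        read_s, read_e = total - (lead + aligned), total - lead
    else:
        read_s, read_e = lead, lead + aligned
    g_start, g_end = rec.reference_start, rec.reference_end
    ref_s, ref_e = locus.interval_to_canonical(g_start, g_end)
    genome_fwd = not rec.is_reverse
    canonical_fwd = genome_fwd == (locus.canonical_strand == "+")
    matched = sum(ln for op, ln in cig if op in (0, 7))
    return (
        AlignmentBlock(
            ref_start=ref_s,
            ref_end=ref_e,
            read_start=read_s,
            read_end=read_e,
            strand="+" if canonical_fwd else "-",
            matches=matched,
        ),
        total,
    )


def write_sam(chains_with_seqs, locus: LocusMap, path) -> None:
    """Write chains (with their read sequences) as plain SAM.

    Each block becomes one record (first block primary, the rest
    supplementary) with soft clips encoding the as-sequenced read interval;
    a length mismatch between read and ref spans is reconciled with a single
    I or D operation.  Intended for synthetic data and round-trip tests.
    """
    ln = locus.locus.end
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{locus.reference_name}\tLN:{ln}\n")
        for chain, seq in chains_with_seqs:
            for i, b in enumerate(chain.blocks):
                genome_fwd = (b.strand == "+") == (locus.canonical_strand == "+")
                flag = (0 if genome_fwd else 16) | (2048 if i > 0 else 0)
                g_start, g_end = locus.interval_to_genome(b.ref_start, b.ref_end)
                rspan = b.read_end - b.read_start
                fspan = b.ref_end - b.ref_start
                mlen = min(rspan, fspan)
                mid = f"{mlen}M"
                if rspan > fspan:
                    mid += f"{rspan - fspan}I"
                elif fspan > rspan:
                    mid += f"{fspan - rspan}D"
                lead, tail = b.read_start, chain.read_len - b.read_end
                if not genome_fwd:
                    lead, tail = tail, lead
                cigar = (f"{lead}S" if lead else "") + mid + (f"{tail}S" if tail else "")
                out_seq = seq if genome_fwd else revcomp(seq)
                fh.write(
                    f"{chain.read_id}\t{flag}\t{locus.reference_name}\t{g_start + 1}"
                    f"\t60\t{cigar}\t*\t0\t0\t{out_seq}\t*\n"
                )


def roi_filter(chain: AlignmentChain, locus: LocusMap) -> bool:
    """Both-ends region-of-interest filter.

    True iff at least one block overlaps the donor-side ROI window and at
    least one block overlaps the acceptor-side ROI window.  Reads that do
    not reach both ends of the region of interest (incomplete amplicons,
    off-target products) are excluded from breakpoint calling.
    """
    hit5 = hit3 = False
    w5, w3 = locus.roi5_window, locus.roi3_window
    for b in chain.blocks:
        if b.ref_start < w5.end and w5.start < b.ref_end:
            hit5 = True
        if b.ref_start < w3.end and w3.start < b.ref_end:
            hit3 = True
        if hit5 and hit3:
            return True
    return False
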