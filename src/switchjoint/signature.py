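"""Repair signatures at recombination junctions.

A junction between a donor break ``d`` and an acceptor break ``a`` on one
reference carries one of three mutually exclusive signatures:

* **microhomology (MH)** — bases shared by both sides of the junction, so
  that the exact break placement is ambiguous.  MH of >= 4 bp is the
  hallmark of Pol theta-mediated end joining (TMEJ).
* **untemplated insertion** — read bases at the junction matching neither
  template.
* **direct joint** — neither MH nor insertion; blunt-style NHEJ signature.

The MH length implemented here is the *total junction-placement ambiguity*:
the number of alternative (d', a') placements that produce the same joined
molecule, i.e. the count of valid placements minus one.  For a deletional
join the joined molecule is ``ref[:d] + ref[a:]``; for an inversional join
the acceptor side is the reverse complement of ``ref[:a]``.  This count is
invariant under shifting the junction within its ambiguity tract, which is
what makes consensus MH across reads stable regardless of each caller's
placement convention.

V(D)J Sanger junctions (V -> J coding joints) are decomposed into V-side
resection, J-side resection, MH and insertion with the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Signature",
    "VdjSignature",
    "microhomology_length",
    "placement_ambiguity",
    "call_signature",
    "signature_summary",
    "analyze_vdj_junction",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Signature:
    """Repair signature of one junction.

    MH and insertion are mutually exclusive by convention: any untemplated
    base sets ``mh_len`` to 0.  ``direct`` is true iff both are 0.
    """

    mh_len: int
    ins_len: int
    ins_seq: str = ""
    direct: bool = field(default=False)

    def __post_init__(self):
        if self.mh_len < 0 or self.ins_len < 0:
            raise ValueError("mh_len and ins_len must be >= 0")
        if self.mh_len > 0 and self.ins_len > 0:
            raise ValueError("mh_len and ins_len are mutually exclusive")
        object.__setattr__(self, "direct", self.mh_len == 0 and self.ins_len == 0)


@dataclass(frozen=True)
class VdjSignature:
    """Decomposition of one V(D)J coding-joint sequence."""

    v_resection: int
    j_resection: int
    mh_len: int
    ins_len: int
    ins_seq: str = ""

    def __post_init__(self):
        if min(self.v_resection, self.j_resection, self.mh_len, self.ins_len) < 0:
            raise ValueError("all fields must be >= 0")
        if self.mh_len > 0 and self.ins_len > 0:
            raise ValueError("mh_len and ins_len are mutually exclusive")


def _match_run(seq: str, i: int, other: str, j: int, step_i: int, step_j: int,
               limit: int, complement: bool = False) -> int:
    """Length of the run of equal bases walking from (i, j) by (step_i, step_j)."""
    n = 0
    comp = _COMPLEMENT
    while n < limit:
        if not (0 <= i < len(seq) and 0 <= j < len(other)):
            break
        a, b = seq[i], other[j]
        if complement:
            b = b.translate(comp)
        if a != b:
            break
        n += 1
        i += step_i
        j += step_j
    return n


def placement_ambiguity(reference: str, donor_break: int, acceptor_break: int,
                        orientation: str = "DEL", cap: int = 20):
    """Leftward and rightward junction-placement ambiguity runs (bp).

    DEL placements shift both breaks together, (d+t, a+t); INV placements
    shift them apart, (d+t, a-t).  Returns ``(left, right)`` — the maximal
    negative and positive shifts that leave the joined molecule unchanged.
    """
    d, a = donor_break, acceptor_break
    if not (0 <= d <= len(reference) and 0 <= a <= len(reference)):
        raise ValueError("breaks must lie within the reference")
    if orientation == "DEL":
        left = _match_run(reference, d - 1, reference, a - 1, -1, -1, cap)
        right = _match_run(reference, d, reference, a, 1, 1, cap)
    elif orientation == "INV":
        left = _match_run(reference, d - 1, reference, a, -1, 1, cap,
                          complement=True)
        right = _match_run(reference, d, reference, a - 1, 1, -1, cap,
                           complement=True)
    else:
        raise ValueError(f"orientation must be 'DEL' or 'INV', got {orientation!r}")
    return left, right


def microhomology_length(reference: str, donor_break: int, acceptor_break: int,
                         orientation: str = "DEL", mh_max: int = 20) -> int:
    """Microhomology at the junction (d, a), as placement ambiguity.

    DEL: joined molecule is ``ref[:d] + ref[a:]``; placement (d+t, a+t) is
    equivalent when the shifted bases match between the two templates.
    INV: joined molecule is ``ref[:d] + revcomp(ref[:a])``; the equivalent
    placements are (d+t, a-t).

    Returns the number of equivalent placements minus one, capped at
    ``mh_max`` and truncated at the sequence ends (windows extending past an
    end are evaluated over the available overlap only).
    """
    left, right = placement_ambiguity(
        reference, donor_break, acceptor_break, orientation, mh_max
    )
    return min(left + right, mh_max)


def call_signature(reference: str, donor_break: int, acceptor_break: int,
                   orientation: str = "DEL", gap_len: int = 0,
                   gap_seq: str = "", mh_max: int = 20) -> Signature:
    """Signature of one junction given its coordinates and any inserted bases.

    ``gap_len`` is the number of read bases between the two aligned segments
    (the untemplated-insertion candidate).  If positive, the signature is an
    insertion (``gap_seq`` holds the bases when available) and MH is 0 by
    convention; otherwise MH is computed from the reference context.
    """
    if gap_len > 0:
        if gap_seq and len(gap_seq) != gap_len:
            raise ValueError("gap_seq length disagrees with gap_len")
        return Signature(mh_len=0, ins_len=gap_len, ins_seq=gap_seq)
    if reference is None:
        raise ValueError("reference context required to compute microhomology")
    mh = microhomology_length(reference, donor_break, acceptor_break,
                              orientation, mh_max)
    return Signature(mh_len=mh, ins_len=0)


def signature_summary(signatures, mh_class_min: int = 4, ins_class_min: int = 2,
                      mh_max: int = 20) -> dict:
    """Summarize junction signatures the way switch-joint studies report them.

    Returns percentages of direct joints, of joints with MH >= mh_class_min,
    of joints with insertions of >1 bp (>= ins_class_min), and the MH "usage
    landscape": the fraction of all joints at each MH length 0..mh_max
    (insertion-bearing joints are tallied separately, so the landscape sums
    to the direct + MH-bearing fraction).
    """
    sigs = list(signatures)
    if not sigs:
        raise ValueError("signature_summary requires a nonempty list")
    n = len(sigs)
    n_direct = sum(1 for s in sigs if s.direct)
    n_ins = sum(1 for s in sigs if s.ins_len > 0)
    n_mh_class = sum(1 for s in sigs if s.ins_len == 0 and s.mh_len >= mh_class_min)
    n_ins_class = sum(1 for s in sigs if s.ins_len >= ins_class_min)
    landscape = np.zeros(mh_max + 1)
    for s in sigs:
        if s.ins_len == 0:
            landscape[min(s.mh_len, mh_max)] += 1
    landscape /= n
    return {
        "n": n,
        "pct_direct": 100.0 * n_direct / n,
        "pct_mh_ge_class": 100.0 * n_mh_class / n,
        "pct_ins_gt_1bp": 100.0 * n_ins_class / n,
        "pct_insertion": 100.0 * n_ins / n,
        "mh_class_min": mh_class_min,
        "ins_class_min": ins_class_min,
        "landscape": landscape.tolist(),
    }


class VdjDecompositionError(ValueError):
    """The sequence could not be anchored in both germline references."""


def _prefix_match_len(seq: str, ref: str, max_mismatch: int = 0) -> int:
    """Longest k with hamming(seq[:k], ref[:k]) <= max_mismatch, not ending in a mismatch."""
    best = 0
    mism = 0
    for i in range(min(len(seq), len(ref))):
        if seq[i] != ref[i]:
            mism += 1
            if mism > max_mismatch:
                break
        else:
            best = i + 1
    return best


def analyze_vdj_junction(seq: str, v_ref: str, j_ref: str,
                         max_mismatch: int = 0, min_anchor: int = 8) -> VdjSignature:
    """Decompose a Sanger V(D)J junction into resections, MH and insertion.

    Finds the longest prefix of ``seq`` matching the prefix of the germline V
    segment and the longest suffix matching the suffix of the germline J
    segment (each allowing at most ``max_mismatch`` mismatches).  Resections
    are the germline bases missing from the V 3' end and the J 5' end at
    those maximal match extents; if the two matched spans overlap, the
    overlap is the junction MH (the ambiguous bases are counted as present
    on both sides); a positive gap between them is an untemplated insertion.
    """
    k = _prefix_match_len(seq, v_ref, max_mismatch)
    l = _prefix_match_len(seq[::-1], j_ref[::-1], max_mismatch)
    if k < min_anchor or l < min_anchor:
        raise VdjDecompositionError(
            f"sequence anchors in only one reference (V match {k} bp, J match {l} bp)"
        )
    overlap = k + l - len(seq)
    if overlap >= 0:
        return VdjSignature(
            v_resection=len(v_ref) - k,
            j_resection=len(j_ref) - l,
            mh_len=overlap,
            ins_len=0,
        )
    gap = -overlap
    return VdjSignature(
        v_resection=len(v_ref) - k,
        j_resection=len(j_ref) - l,
        mh_len=0,
        ins_len=gap,
        ins_seq=seq[k:k + gap],
    )
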