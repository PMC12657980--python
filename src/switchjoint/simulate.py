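"""Synthetic switch-locus and recombination-event simulator.

Generates a miniature class-switch-recombination (CSR) assay with known
ground truth:

* a synthetic locus with primer sites flanking a repeat-rich, G-rich donor
  switch region (Sµ-like) and acceptor switch region (Sγ1-like), separated
  by a long intervening spacer so that the germline primer-to-primer span
  exceeds the productive-amplicon window (as for the real Igh locus, where
  the primers sit >100 kb apart on the unrecombined allele);
* recombination events sampled at the break-coordinate level: deletional or
  inversional, with optional resection tracts extending the deletion beyond
  the S-region borders and optional untemplated junction insertions;
* three rendered fixture inputs: LR-PCR long reads (CCS-like errors),
  an HTGTS-style TLX junction table, and V(D)J Sanger junction sequences,
  each paired with a truth table.

Resection is modeled as geometric per end, extending the *deletion*: a
resected donor break moves upstream of Sµ (toward the 5' primer) and a
resected acceptor break moves downstream of the acceptor S region (toward
the 3' primer), so resected joints yield shorter amplicons and break
coordinates outside the S regions — the defining property of resected
joints in LR-PCR profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .locus import (
    BaitSite,
    GenomicInterval,
    IsotypeThresholds,
    LocusMap,
    donor_break_inside,
    acceptor_break_inside,
)
from .signature import microhomology_length, placement_ambiguity, revcomp

__all__ = [
    "SimParams",
    "EventSpec",
    "make_synthetic_locus",
    "sample_events",
    "render_lrpcr_reads",
    "render_htgts_table",
    "render_vdj_junctions",
    "events_to_frame",
    "apply_ccs_errors",
    "write_fastq",
    "write_tlx",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Degenerate switch-repeat units (G-rich on the canonical top strand).
# Unit lengths are coprime (25 vs 23) and shared motifs short (<= ~5 bp), so
# donor/acceptor arrays never align over long phase-matched stretches; cross-
# region identity stays local, producing realistic short junction MH without
# extended ambiguity tracts.
_DONOR_REPEAT = "GAGCTGAGCTGGGGTGAGCTGGGGT"
_ACCEPTOR_REPEAT = "GGGTTAGCGTGGGCTAAGGCGGG"
_REPEAT_DEGENERACY = 0.08  # per-base substitution rate within repeat arrays


@dataclass(frozen=True)
class SimParams:
    """Simulation conditions.

    Defaults emulate an NHEJ-deficient (Xrcc4-/-) stimulated B-cell sample:
    ~12% inversional joints, ~13% resected joints, unique junctions backed
    by 10-20 reads, and CCS-like per-base error rates (~0.2%).
    """

    seed: int = 0
    n_events: int = 2000
    p_inversion: float = 0.12
    p_resected: float = 0.13
    resection_mean: float = 800.0
    p_insertion: float = 0.10
    insertion_len_max: int = 6
    depth_min: int = 10
    depth_max: int = 20
    error_sub_rate: float = 0.002
    error_indel_rate: float = 0.0002
    locus_scale: int = 60000
    # V(D)J Sanger-junction generator
    vdj_v_len: int = 300
    vdj_j_len: int = 200
    vdj_resection_mean: float = 3.0

    def __post_init__(self):
        for name in ("p_inversion", "p_resected", "p_insertion"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.depth_min < 1 or self.depth_max < self.depth_min:
            raise ValueError("require 1 <= depth_min <= depth_max")
        for name in ("error_sub_rate", "error_indel_rate"):
            r = getattr(self, name)
            if not (0.0 <= r <= 0.05):
                raise ValueError(f"{name} must be in [0, 0.05], got {r}")
        if self.resection_mean < 1.0:
            raise ValueError("resection_mean must be >= 1 bp")
        if self.insertion_len_max < 1:
            raise ValueError("insertion_len_max must be >= 1")


@dataclass(frozen=True)
class EventSpec:
    """Ground truth for one recombination event (canonical coordinates)."""

    event_id: str
    orientation: str  # DEL | INV
    donor_break: int
    acceptor_break: int
    donor_out: bool
    acceptor_out: bool
    region_class: str  # S_S | RESECTED
    insertion_seq: str
    realized_mh: int
    depth: int

    def __post_init__(self):
        if self.orientation not in ("DEL", "INV"):
            raise ValueError("orientation must be DEL or INV")
        resected = self.donor_out or self.acceptor_out
        if (self.region_class == "RESECTED") != resected:
            raise ValueError("region_class inconsistent with side flags")
        if self.insertion_seq and self.realized_mh != 0:
            raise ValueError("insertion and microhomology are mutually exclusive")


def events_to_frame(events) -> pd.DataFrame:
    """Truth table as a DataFrame (one row per event)."""
    return pd.DataFrame([asdict(e) for e in events])


def _random_bases(rng, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _repeat_array(rng, unit: str, length: int) -> str:
    """Tandem repeats of ``unit`` with per-base degeneracy, length bp."""
    reps = -(-length // len(unit))
    arr = np.frombuffer((unit * reps)[:length].encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(length) < _REPEAT_DEGENERACY)[0]
    arr[hits] = _BASES[rng.integers(0, 4, size=hits.size)]
    return arr.tobytes().decode()


def make_synthetic_locus(params: SimParams):
    """Build the synthetic reference and its LocusMap.

    Deterministic in ``params.seed``.  Feature coordinates depend only on
    ``locus_scale``; sequence content (spacers, repeat degeneracy) on the
    seed.  Returns ``(SeqRecord, LocusMap)``.
    """
    L = params.locus_scale
    if L < 20000:
        raise ValueError(f"locus_scale must be >= 20000 bp, got {L}")
    rng = np.random.default_rng([params.seed, 0])

    p5_start = L // 60
    primer_len = 30
    donor_start = L // 10
    s_len = L // 15
    donor_end = donor_start + s_len
    acc_start = (77 * L) // 100
    acc_end = acc_start + s_len
    p3_start = (92 * L) // 100
    p3_end = p3_start + primer_len
    roi_pad = L // 12
    junction_pad = L // 6

    seq = list(_random_bases(rng, L))
    seq[donor_start:donor_end] = _repeat_array(rng, _DONOR_REPEAT, s_len)
    seq[acc_start:acc_end] = _repeat_array(rng, _ACCEPTOR_REPEAT, s_len)
    reference = "".join(seq)

    name = "synthetic_switch_locus"
    # Productive window brackets the strictly-within-S (S_S) amplicon range.
    min_ss = (donor_start + 1 - p5_start) + (p3_end - acc_end + 1)
    max_ss = (donor_end - p5_start) + (p3_end - acc_start)
    thresholds = IsotypeThresholds(
        productive_min_len=min_ss - 1,
        productive_max_len=max_ss + 1,
        label="synthetic",
    )
    bait_coord = donor_start - min(500, (donor_start - (p5_start + primer_len)) // 2)
    locus = LocusMap(
        reference_name=name,
        locus=GenomicInterval(name, 0, L, "+"),
        canonical_strand="+",
        primer5=GenomicInterval(name, p5_start, p5_start + primer_len),
        primer3=GenomicInterval(name, p3_start, p3_end),
        donor_S=GenomicInterval(name, donor_start, donor_end),
        acceptor_S=GenomicInterval(name, acc_start, acc_end),
        thresholds=thresholds,
        bait_site=BaitSite(bait_coord, "+"),
        roi_pad=roi_pad,
        junction_pad=junction_pad,
        del_strand="+",
    )
    record = SeqRecord(Seq(reference), id=name, description="synthetic CSR locus")
    return record, locus


def _draw_insertion(rng, ref: str, d: int, a: int, orientation: str,
                    max_len: int) -> str:
    """Random untemplated insertion whose boundary bases differ from the
    adjacent template bases (so no part of it is templated at the junction)."""
    n = int(rng.integers(1, max_len + 1))
    ins = list(_random_bases(rng, n))
    left_forbidden = ref[d] if d < len(ref) else None
    if orientation == "DEL":
        right_forbidden = ref[a - 1] if a > 0 else None
    else:
        right_forbidden = revcomp(ref[a])[0] if a < len(ref) else None

    def pick(current, forbidden):
        allowed = [b for b in "ACGT" if b not in forbidden]
        if current in allowed:
            return current
        return allowed[int(rng.integers(0, len(allowed)))]

    if n == 1:
        ins[0] = pick(ins[0], {left_forbidden, right_forbidden})
    else:
        ins[0] = pick(ins[0], {left_forbidden})
        ins[-1] = pick(ins[-1], {right_forbidden})
    return "".join(ins)


def sample_events(params: SimParams, locus: LocusMap, reference: str):
    """Sample ground-truth recombination events on a synthetic locus.

    Orientation is inversional with probability ``p_inversion``; with
    probability ``p_resected`` at least one break is displaced beyond its
    S-region border by a geometric tract (mean ``resection_mean``), the
    donor break moving upstream and the acceptor break downstream so the
    deletion grows; otherwise both breaks are uniform within their S
    regions.  Untemplated insertions are added with probability
    ``p_insertion``; realized microhomology is computed from the reference.
    Deterministic in ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 1])
    dS, aS = locus.donor_S, locus.acceptor_S
    # keep >= ~300 bp of primer-proximal template on each side so the
    # resected amplicon still anchors an alignment (and a primer can bind)
    donor_cap = dS.start - (locus.primer5.end + 300)
    acc_cap = (locus.primer3.start - 300) - aS.end
    p_geom = 1.0 / params.resection_mean

    def label_stable(d: int, a: int, left: int, right: int, orientation: str) -> bool:
        """True when the S_S/resected label is identical at every junction
        placement within the microhomology-ambiguity tract, so ground truth
        does not depend on a caller's placement convention."""
        if orientation != "DEL":
            return True
        ref_flags = (donor_break_inside(dS, d), acceptor_break_inside(aS, a))
        return all(
            (donor_break_inside(dS, d + t), acceptor_break_inside(aS, a + t))
            == ref_flags
            for t in range(-left, right + 1)
        )

    events = []
    occupied = set()  # placement-equivalence classes already planted
    for i in range(params.n_events):
        orientation = "INV" if rng.random() < params.p_inversion else "DEL"
        resected = rng.random() < params.p_resected
        side = int(rng.integers(0, 3)) if resected else -1  # 0 donor, 1 acceptor, 2 both
        while True:
            d = int(rng.integers(dS.start + 1, dS.end + 1))
            a = int(rng.integers(aS.start, aS.end))
            if side in (0, 2):
                tract = min(int(rng.geometric(p_geom)), donor_cap)
                d = dS.start - tract
            if side in (1, 2):
                tract = min(int(rng.geometric(p_geom)), acc_cap)
                a = aS.end - 1 + tract
            left, right = placement_ambiguity(reference, d, a, orientation, cap=40)
            delta = a - d if orientation == "DEL" else a + d
            cls = {(orientation, delta, d + t) for t in range(-left, right + 1)}
            # distinct events must be distinguishable: no two may share any
            # junction placement (they would render identical molecules)
            if label_stable(d, a, left, right, orientation) and not (cls & occupied):
                occupied |= cls
                break
        donor_out = not donor_break_inside(dS, d)
        acceptor_out = not acceptor_break_inside(aS, a)

        ins = ""
        if rng.random() < params.p_insertion:
            ins = _draw_insertion(rng, reference, d, a, orientation,
                                  params.insertion_len_max)
        # cap well above any realistic tract so realized_mh is the full ambiguity
        mh = 0 if ins else microhomology_length(reference, d, a, orientation, mh_max=40)
        depth = int(rng.integers(params.depth_min, params.depth_max + 1))
        events.append(
            EventSpec(
                event_id=f"ev{i:05d}",
                orientation=orientation,
                donor_break=d,
                acceptor_break=a,
                donor_out=donor_out,
                acceptor_out=acceptor_out,
                region_class="RESECTED" if (donor_out or acceptor_out) else "S_S",
                insertion_seq=ins,
                realized_mh=mh,
                depth=depth,
            )
        )
    return events


def apply_ccs_errors(seq: str, rng, sub_rate: float, indel_rate: float) -> str:
    """CCS-like error model: independent substitutions and 1-bp indels."""
    if sub_rate == 0.0 and indel_rate == 0.0:
        return seq
    n = len(seq)
    draws = rng.random(n)
    sub_pos = np.nonzero(draws < sub_rate)[0]
    indel_pos = np.nonzero((draws >= sub_rate) & (draws < sub_rate + indel_rate))[0]
    if sub_pos.size == 0 and indel_pos.size == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    if sub_pos.size:
        # substitute with one of the three other bases
        shift = rng.integers(1, 4, size=sub_pos.size)
        base_idx = np.empty(sub_pos.size, dtype=np.int64)
        for j, b in enumerate(_BASES):
            base_idx[arr[sub_pos] == b] = j
        arr[sub_pos] = _BASES[(base_idx + shift) % 4]
    if indel_pos.size == 0:
        return arr.tobytes().decode()
    out = []
    prev = 0
    ins_or_del = rng.random(indel_pos.size) < 0.5
    ins_bases = _BASES[rng.integers(0, 4, size=indel_pos.size)]
    s = arr.tobytes().decode()
    for k, pos in enumerate(indel_pos):
        out.append(s[prev:pos])
        if ins_or_del[k]:
            out.append(chr(ins_bases[k]) + s[pos])
        # deletion: skip the base
        prev = pos + 1
    out.append(s[prev:])
    return "".join(out)


def render_lrpcr_reads(events, reference: str, locus: LocusMap,
                       params: SimParams, both_strands: bool = True):
    """Render LR-PCR amplicon reads for deletional events.

    LR-PCR with two convergent primers amplifies only deletional
    recombination products, so inversional events are returned in the
    ``unamplified`` list and produce no reads.  Returns
    ``(read_iterator, unamplified)`` where the iterator yields
    ``(read_id, sequence)`` pairs, ``depth`` reads per DEL event.
    Deterministic in ``params.seed``.
    """
    p5, p3 = locus.primer5, locus.primer3
    for e in events:
        if not (p5.end <= e.donor_break < p3.start) or not (
            p5.end <= e.acceptor_break < p3.start
        ):
            raise ValueError(
                f"event {e.event_id}: break coordinates outside the amplifiable "
                f"interval [{p5.end}, {p3.start})"
            )
    unamplified = [e for e in events if e.orientation == "INV"]

    def _reads():
        rng = np.random.default_rng([params.seed, 2])
        for e in events:
            if e.orientation != "DEL":
                continue
            amplicon = (
                reference[p5.start:e.donor_break]
                + e.insertion_seq
                + reference[e.acceptor_break:p3.end]
            )
            for r in range(e.depth):
                seq = apply_ccs_errors(
                    amplicon, rng, params.error_sub_rate, params.error_indel_rate
                )
                if both_strands and rng.random() < 0.5:
                    seq = revcomp(seq)
                yield f"{e.event_id}_r{r:03d}", seq

    return _reads(), unamplified


def write_fastq(reads, path) -> int:
    """Write (read_id, seq) pairs as FASTQ with uniform CCS-like quality."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'~' * len(seq)}\n")
            n += 1
    return n


TLX_COLUMNS = [
    "read_id",
    "bait_chrom",
    "bait_coord",
    "bait_strand",
    "prey_chrom",
    "prey_coord",
    "prey_strand",
    "junction_context",
]


def render_htgts_table(events, reference: str, locus: LocusMap,
                       params: SimParams, context_width: int = 40) -> pd.DataFrame:
    """Render a TLX-like junction table (one row per captured junction).

    Bait coordinate is the donor break, prey coordinate the acceptor break,
    both in the genome frame; prey strand equals ``locus.del_strand`` for
    deletional joins and its opposite for inversional joins.  The junction
    context column stores ``donor_flank|insertion|prey_flank`` with
    ``context_width`` template bases on each side, from which the insertion
    is recoverable without a width convention.
    """
    chrom = locus.locus.chrom
    bait_strand = locus.canonical_strand
    inv_strand = "-" if locus.del_strand == "+" else "+"
    rows = []
    w = context_width
    for e in events:
        d, a = e.donor_break, e.acceptor_break
        donor_flank = reference[max(0, d - w):d]
        if e.orientation == "DEL":
            prey_flank = reference[a:a + w]
            strand = locus.del_strand
        else:
            prey_flank = revcomp(reference[max(0, a - w):a])
            strand = inv_strand
        rows.append(
            {
                "read_id": e.event_id,
                "bait_chrom": chrom,
                "bait_coord": locus.break_to_genome(d),
                "bait_strand": bait_strand,
                "prey_chrom": chrom,
                "prey_coord": locus.break_to_genome(a),
                "prey_strand": strand,
                "junction_context": f"{donor_flank}|{e.insertion_seq}|{prey_flank}",
            }
        )
    return pd.DataFrame(rows, columns=TLX_COLUMNS)


def write_tlx(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def decompose_junction(seq: str, v_ref: str, j_ref: str):
    """Canonical decomposition of a V-J junction by placement enumeration.

    Enumerates every split ``seq = V[:x] + ins + J[y:]``, minimizing the
    insertion length; with zero insertion the number of valid splits minus
    one is the junction MH, and resections are reported at the maximal
    germline match extents (MH bases counted as present on both sides).
    Returns ``(v_resection, j_resection, mh, ins_seq)``.
    """
    n = len(seq)
    # maximal germline-anchored extents
    k = 0
    while k < min(n, len(v_ref)) and seq[k] == v_ref[k]:
        k += 1
    l = 0
    while l < min(n, len(j_ref)) and seq[n - 1 - l] == j_ref[len(j_ref) - 1 - l]:
        l += 1
    zero_ins_splits = [
        x for x in range(max(0, n - l), min(k, n) + 1)
        if seq[:x] == v_ref[:x] and seq[x:] == j_ref[len(j_ref) - (n - x):]
    ]
    if zero_ins_splits:
        x_hi, x_lo = max(zero_ins_splits), min(zero_ins_splits)
        return len(v_ref) - x_hi, len(j_ref) - (n - x_lo), x_hi - x_lo, ""
    return len(v_ref) - k, len(j_ref) - l, 0, seq[k:n - l]


def render_vdj_junctions(params: SimParams, n: int = None):
    """Simulate Sanger-sequenced V(D)J coding joints with ground truth.

    Each junction sequence is the germline V segment with ``v_resection``
    bases removed from its 3' end, an optional untemplated insertion, and
    the germline J segment with ``j_resection`` bases removed from its 5'
    end.  The truth table records the *canonical* decomposition recomputed
    from the sequence by placement enumeration (so ambiguous junctions are
    reported the same way an exact analyzer must report them).

    Returns ``(v_ref, j_ref, junctions, truth)`` where junctions is a list
    of ``(seq_id, sequence)`` and truth a DataFrame.
    """
    if n is None:
        n = params.n_events
    rng = np.random.default_rng([params.seed, 4])
    v_ref = _random_bases(rng, params.vdj_v_len)
    j_ref = _random_bases(rng, params.vdj_j_len)
    p_geom = 1.0 / (params.vdj_resection_mean + 1.0)
    cap_v = params.vdj_v_len - 30
    cap_j = params.vdj_j_len - 30

    junctions, rows = [], []
    for i in range(n):
        v_res = min(int(rng.geometric(p_geom)) - 1, cap_v)
        j_res = min(int(rng.geometric(p_geom)) - 1, cap_j)
        ins = ""
        if rng.random() < params.p_insertion:
            ins = _random_bases(rng, int(rng.integers(1, params.insertion_len_max + 1)))
        seq = v_ref[:params.vdj_v_len - v_res] + ins + j_ref[j_res:]
        vr, jr, mh, ins_seq = decompose_junction(seq, v_ref, j_ref)
        sid = f"vdj{i:04d}"
        junctions.append((sid, seq))
        rows.append(
            {
                "seq_id": sid,
                "v_resection": vr,
                "j_resection": jr,
                "mh": mh,
                "ins_len": len(ins_seq),
                "ins_seq": ins_seq,
            }
        )
    return v_ref, j_ref, junctions, pd.DataFrame(rows)
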