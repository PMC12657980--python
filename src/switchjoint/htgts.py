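"""HTGTS-style junction-table analysis.

High-throughput genome-wide translocation sequencing anchors one side of
every junction at a fixed bait break (here the 5' Sµ bait) and captures the
partner ("prey") side genome-wide.  This module consumes TLX-like junction
tables — the standard tabular output of HTGTS pipelines — classifies every
junction by acceptor region and orientation, and computes the summary
quantities used to characterize class-switch joints: region fractions,
the inversional/deletional ratio, the resected fraction among Sµ-acceptor
joints, binned junction distributions and repair-signature summaries.

Orientation convention: a prey on ``locus.del_strand`` is a deletional
join; the opposite prey strand marks an inversional join.  Which genome
strand is deletional depends on the locus orientation and bait design, so
it is configuration, not inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locus import LocusMap, acceptor_break_inside
from .signature import Signature, call_signature, signature_summary

__all__ = [
    "TlxRecord",
    "ClassifiedJunction",
    "HtgtsSummary",
    "TLX_DIALECTS",
    "read_tlx",
    "classify_record",
    "summarize_htgts",
    "classified_to_frame",
]

logger = logging.getLogger(__name__)

# column-name maps: our field -> column in the file
TLX_DIALECTS = {
    "switchjoint": {
        "read_id": "read_id",
        "bait_chrom": "bait_chrom",
        "bait_coord": "bait_coord",
        "bait_strand": "bait_strand",
        "prey_chrom": "prey_chrom",
        "prey_coord": "prey_coord",
        "prey_strand": "prey_strand",
        "junction_context": "junction_context",
    },
    # the published HTGTS pipeline's junction table ("tlx") headers
    "tlx": {
        "read_id": "Qname",
        "bait_chrom": "B_Rname",
        "bait_coord": "B_Junction",
        "bait_strand": "B_Strand",
        "prey_chrom": "Rname",
        "prey_coord": "Junction",
        "prey_strand": "Strand",
        "junction_context": None,
    },
}

_MANDATORY = ("bait_coord", "prey_chrom", "prey_coord", "prey_strand")


@dataclass(frozen=True)
class TlxRecord:
    """One HTGTS junction: bait and prey coordinates (genome frame)."""

    read_id: str
    bait_coord: int
    bait_strand: str
    prey_chrom: str
    prey_coord: int
    prey_strand: str
    bait_chrom: str = ""
    junction_context: str = ""
    sample_id: str = ""

    def __post_init__(self):
        if self.bait_coord < 0 or self.prey_coord < 0:
            raise ValueError("coordinates must be >= 0")
        if self.prey_strand not in ("+", "-") or self.bait_strand not in ("+", "-"):
            raise ValueError("strands must be '+' or '-'")


def _normalize_strand(value) -> str:
    s = str(value)
    if s in ("+", "-"):
        return s
    if s in ("1", "1.0"):
        return "+"
    if s in ("-1", "-1.0"):
        return "-"
    raise ValueError(f"unrecognized strand {value!r}")


def read_tlx(path, dialect: str = "switchjoint", sample_id: str = ""):
    """Parse a TLX-like junction table into TlxRecords.

    ``dialect`` selects a column-name map (see ``TLX_DIALECTS``).  Rows
    missing a mandatory field (bait/prey coordinates, prey chromosome or
    strand) are dropped with a logged count.  Coordinates stay in the
    genome frame here; conversion to canonical coordinates happens at
    classification time against a LocusMap.
    """
    if dialect not in TLX_DIALECTS:
        raise ValueError(
            f"unknown TLX dialect {dialect!r}; known: {sorted(TLX_DIALECTS)}"
        )
    cols = TLX_DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    records, n_dropped = [], 0
    for _, row in df.iterrows():
        def get(fieldname):
            col = cols.get(fieldname)
            if col is None or col not in row or pd.isna(row[col]):
                return None
            return row[col]

        if any(get(f) is None for f in _MANDATORY):
            n_dropped += 1
            continue
        try:
            records.append(
                TlxRecord(
                    read_id=str(get("read_id") or ""),
                    bait_chrom=str(get("bait_chrom") or ""),
                    bait_coord=int(float(get("bait_coord"))),
                    bait_strand=_normalize_strand(get("bait_strand") or "+"),
                    prey_chrom=str(get("prey_chrom")),
                    prey_coord=int(float(get("prey_coord"))),
                    prey_strand=_normalize_strand(get("prey_strand")),
                    junction_context=str(get("junction_context") or ""),
                    sample_id=sample_id,
                )
            )
        except (ValueError, TypeError):
            n_dropped += 1
    if n_dropped:
        logger.info("read_tlx: dropped %d malformed rows from %s", n_dropped, path)
    return records


@dataclass(frozen=True)
class ClassifiedJunction:
    record: TlxRecord
    region: str  # Smu_intra | Smu_acceptor | <extra S name> | outside | translocation_other
    orientation: str = ""  # DEL | INV ('' for off-locus prey)
    resected: bool = None  # only meaningful for Smu_acceptor joints
    bait_canonical: int = None
    prey_canonical: int = None
    signature: Signature = None


def classify_record(r: TlxRecord, locus: LocusMap,
                    reference: str = None) -> ClassifiedJunction:
    """Assign one junction to a region class, orientation and resected flag.

    Prey on another chromosome -> "translocation_other" (outside the CSR
    summaries).  On-locus prey is assigned to Sµ-intra (donor_S +/- roi_pad),
    Sµ-acceptor (acceptor_S +/- junction_pad), a named extra S region
    (+/- junction_pad), or "outside".  For Sµ-acceptor joints the resected
    flag is true when the prey falls outside the unpadded acceptor S region.
    When a junction-context column and the reference are available the
    repair signature (insertion vs MH vs direct) is computed.
    """
    if r.prey_chrom != locus.locus.chrom:
        return ClassifiedJunction(record=r, region="translocation_other")
    try:
        prey = locus.break_to_canonical(r.prey_coord)
    except ValueError:
        return ClassifiedJunction(record=r, region="translocation_other")
    try:
        bait = locus.break_to_canonical(r.bait_coord)
    except ValueError:
        bait = None
    orientation = "DEL" if r.prey_strand == locus.del_strand else "INV"

    aS = locus.acceptor_S
    region, resected = "outside", None
    if aS.start - locus.junction_pad <= prey < aS.end + locus.junction_pad:
        region = "Smu_acceptor"
        resected = not acceptor_break_inside(aS, prey)
    else:
        for name, iv in locus.extra_S.items():
            if iv.start - locus.junction_pad <= prey < iv.end + locus.junction_pad:
                region = name
                break
        else:
            w5 = locus.roi5_window
            if w5.start <= prey < w5.end:
                region = "Smu_intra"

    sig = None
    if r.junction_context and "|" in r.junction_context:
        parts = r.junction_context.split("|")
        if len(parts) == 3 and bait is not None and reference is not None:
            ins = parts[1]
            sig = call_signature(
                reference, bait, prey, orientation,
                gap_len=len(ins), gap_seq=ins,
            )
    return ClassifiedJunction(
        record=r,
        region=region,
        orientation=orientation,
        resected=resected,
        bait_canonical=bait,
        prey_canonical=prey,
        signature=sig,
    )


@dataclass
class HtgtsSummary:
    n_junctions: int
    n_on_locus: int
    pct_by_region: dict = field(default_factory=dict)
    inv_del_ratio: float = None
    pct_resected: float = None
    genomewide_hist: dict = field(default_factory=dict)
    zoom_hist: dict = field(default_factory=dict)
    signatures: dict = None

    def to_dict(self):
        return {
            "n_junctions": self.n_junctions,
            "n_on_locus": self.n_on_locus,
            "pct_by_region": self.pct_by_region,
            "inv_del_ratio": self.inv_del_ratio,
            "pct_resected": self.pct_resected,
            "genomewide_hist": self.genomewide_hist,
            "zoom_hist": self.zoom_hist,
            "signatures": self.signatures,
        }


def _hist(coords, start, end, bin_width):
    edges = np.arange(start, end + bin_width, bin_width)
    counts, _ = np.histogram(coords, bins=edges)
    return {"start": int(start), "bin_width": int(bin_width),
            "counts": counts.astype(int).tolist()}


def summarize_htgts(classified, locus: LocusMap, bin_width: int = 1000,
                    zoom_bin_width: int = 250) -> HtgtsSummary:
    """Summary quantities over classified junctions.

    INV/DEL ratio and resected percentage are computed among Sµ-acceptor
    joints; region percentages over all on-locus junctions; the
    genome-wide histogram in 1 kb bins across the locus and the
    acceptor-region zoom in 250 bp bins over acceptor_S +/- junction_pad.
    With zero deletional joints the ratio is reported absent (None).
    """
    cls = list(classified)
    on_locus = [c for c in cls if c.region != "translocation_other"]
    acc = [c for c in cls if c.region == "Smu_acceptor"]
    summary = HtgtsSummary(n_junctions=len(cls), n_on_locus=len(on_locus))
    if on_locus:
        counts = {}
        for c in on_locus:
            counts[c.region] = counts.get(c.region, 0) + 1
        summary.pct_by_region = {
            k: 100.0 * v / len(on_locus) for k, v in sorted(counts.items())
        }
        summary.genomewide_hist = _hist(
            [c.prey_canonical for c in on_locus], 0, len(locus.locus), bin_width
        )
    if acc:
        n_inv = sum(1 for c in acc if c.orientation == "INV")
        n_del = len(acc) - n_inv
        if n_del > 0:
            summary.inv_del_ratio = n_inv / n_del
        else:
            logger.info("summarize_htgts: no deletional joints; INV/DEL ratio undefined")
        summary.pct_resected = 100.0 * sum(1 for c in acc if c.resected) / len(acc)
        zoom_start = max(0, locus.acceptor_S.start - locus.junction_pad)
        zoom_end = min(len(locus.locus), locus.acceptor_S.end + locus.junction_pad)
        summary.zoom_hist = _hist(
            [c.prey_canonical for c in acc], zoom_start, zoom_end, zoom_bin_width
        )
        sigs = [c.signature for c in acc if c.signature is not None]
        if sigs:
            summary.signatures = signature_summary(sigs)
    return summary


def classified_to_frame(classified) -> pd.DataFrame:
    rows = []
    for c in classified:
        rows.append(
            {
                "read_id": c.record.read_id,
                "prey_chrom": c.record.prey_chrom,
                "prey_coord": c.record.prey_coord,
                "prey_strand": c.record.prey_strand,
                "region": c.region,
                "orientation": c.orientation,
                "resected": c.resected,
                "prey_canonical": c.prey_canonical,
                "mh_len": c.signature.mh_len if c.signature else None,
                "ins_len": c.signature.ins_len if c.signature else None,
                "direct": c.signature.direct if c.signature else None,
            }
        )
    return pd.DataFrame(rows)
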