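"""Genomic model of a switch-locus assay.

A :class:`LocusMap` describes one long-range PCR / HTGTS assay over an
immunoglobulin switch locus: the two primer footprints, the donor (Sµ) and
acceptor (Sγ1/Sα) switch regions, the regions of interest used by the
both-ends read filter, the HTGTS bait site, productive-amplicon length
thresholds and an optional junction blocklist.

All coordinates are held internally in a single *canonical* frame: 0-based,
half-open, on the transcriptional strand of the locus, with 0 at the
canonical 5' edge of the locus.  Genome coordinates (either convention)
appear only at I/O boundaries; :meth:`LocusMap.to_canonical` and friends
convert between frames.  Keeping one internal frame avoids the sign errors
that arise because the Igh locus is on the genome minus strand while joins
are described in transcriptional orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

__all__ = [
    "GenomicInterval",
    "IsotypeThresholds",
    "BaitSite",
    "LocusMap",
    "LocusConfigError",
    "LocusValidationError",
    "load_locus_config",
    "save_locus_config",
    "validate_locus",
    "donor_break_inside",
    "acceptor_break_inside",
]


class LocusConfigError(ValueError):
    """Malformed locus configuration file."""


class LocusValidationError(ValueError):
    """A LocusMap violates one or more structural invariants."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class IsotypeThresholds:
    """Productive-amplicon length window for one isotype assay (bp)."""

    productive_min_len: int
    productive_max_len: int
    label: str = ""

    def __post_init__(self):
        if not (0 < self.productive_min_len < self.productive_max_len):
            raise ValueError(
                "require 0 < productive_min_len < productive_max_len, got "
                f"{self.productive_min_len}, {self.productive_max_len}"
            )


@dataclass(frozen=True)
class BaitSite:
    """HTGTS bait primer location (canonical coordinate + strand)."""

    coord: int
    strand: str = "+"


def donor_break_inside(region: GenomicInterval, donor_break: int) -> bool:
    """True if a donor-side break coordinate falls inside ``region``.

    ``donor_break`` is the half-open end of the retained donor segment, so the
    last retained base is ``donor_break - 1``; the break is inside the region
    when that base is.
    """
    return region.start < donor_break <= region.end


def acceptor_break_inside(region: GenomicInterval, acceptor_break: int) -> bool:
    """True if an acceptor-side break coordinate falls inside ``region``.

    ``acceptor_break`` is the first retained acceptor base.
    """
    return region.start <= acceptor_break < region.end


@dataclass(frozen=True)
class LocusMap:
    """One switch assay: primers, S regions, windows, thresholds.

    All interval/coordinate fields except ``locus`` are in the canonical
    frame (0-based half-open offsets from the canonical 5' edge); ``locus``
    records the genome placement used to convert at I/O boundaries.
    """

    reference_name: str
    locus: GenomicInterval
    canonical_strand: str
    primer5: GenomicInterval
    primer3: GenomicInterval
    donor_S: GenomicInterval
    acceptor_S: GenomicInterval
    thresholds: IsotypeThresholds
    bait_site: BaitSite
    extra_S: dict = field(default_factory=dict)
    roi_pad: int = 5000
    junction_pad: int = 10000
    roi5_window: Optional[GenomicInterval] = None
    roi3_window: Optional[GenomicInterval] = None
    blocklist: tuple = ()
    del_strand: str = "+"

    def __post_init__(self):
        if self.canonical_strand not in ("+", "-"):
            raise ValueError("canonical_strand must be '+' or '-'")
        L = len(self.locus)
        if self.roi5_window is None:
            object.__setattr__(
                self, "roi5_window", self._padded(self.donor_S, self.roi_pad, L)
            )
        if self.roi3_window is None:
            object.__setattr__(
                self, "roi3_window", self._padded(self.acceptor_S, self.roi_pad, L)
            )
        object.__setattr__(self, "blocklist", tuple(tuple(p) for p in self.blocklist))

    @staticmethod
    def _padded(iv: GenomicInterval, pad: int, locus_len: int) -> GenomicInterval:
        return GenomicInterval(
            iv.chrom, max(0, iv.start - pad), min(locus_len, iv.end + pad)
        )

    # -- coordinate services -------------------------------------------------

    def __len__(self) -> int:
        return len(self.locus)

    def to_canonical(self, g: int) -> int:
        """Map a genome base coordinate into the canonical frame.

        Bijective on the locus; order-reversing iff the canonical strand is
        the genome minus strand.
        """
        if not (self.locus.start <= g < self.locus.end):
            raise ValueError(
                f"coordinate {g} outside locus [{self.locus.start}, {self.locus.end})"
            )
        if self.canonical_strand == "+":
            return g - self.locus.start
        return (self.locus.end - 1) - g

    def to_genome(self, c: int) -> int:
        """Inverse of :meth:`to_canonical` (base coordinates)."""
        if not (0 <= c < len(self.locus)):
            raise ValueError(f"canonical coordinate {c} outside [0, {len(self.locus)})")
        if self.canonical_strand == "+":
            return c + self.locus.start
        return (self.locus.end - 1) - c

    def break_to_genome(self, b: int) -> int:
        """Map a between-base (break) canonical coordinate to the genome frame."""
        if not (0 <= b <= len(self.locus)):
            raise ValueError(f"break coordinate {b} outside [0, {len(self.locus)}]")
        if self.canonical_strand == "+":
            return b + self.locus.start
        return self.locus.end - b

    def break_to_canonical(self, g: int) -> int:
        """Inverse of :meth:`break_to_genome`."""
        if self.canonical_strand == "+":
            b = g - self.locus.start
        else:
            b = self.locus.end - g
        if not (0 <= b <= len(self.locus)):
            raise ValueError(f"break coordinate {g} outside locus")
        return b

    def interval_to_canonical(self, gs: int, ge: int) -> tuple:
        """Map a genome half-open interval to a canonical half-open interval."""
        if self.canonical_strand == "+":
            return gs - self.locus.start, ge - self.locus.start
        return self.locus.end - ge, self.locus.end - gs

    def interval_to_genome(self, cs: int, ce: int) -> tuple:
        if self.canonical_strand == "+":
            return cs + self.locus.start, ce + self.locus.start
        return self.locus.end - ce, self.locus.end - cs

    def strand_to_canonical(self, genome_strand: str) -> str:
        if genome_strand not in ("+", "-"):
            raise ValueError(f"invalid strand {genome_strand!r}")
        if self.canonical_strand == "+":
            return genome_strand
        return "-" if genome_strand == "+" else "+"

    # genome->canonical and canonical->genome strand maps are the same flip
    strand_to_genome = strand_to_canonical

    @property
    def germline_amplicon_len(self) -> int:
        """Primer-to-primer span on the unrecombined locus (canonical bp)."""
        return self.primer3.end - self.primer5.start


def validate_locus(locus: LocusMap) -> list:
    """Check every LocusMap invariant; return a list of violation strings.

    Reports, never raises: an empty list means the map is valid.
    """
    v = []
    chain = [
        ("primer5.end", locus.primer5.end),
        ("donor_S.start", locus.donor_S.start),
        ("donor_S.end", locus.donor_S.end),
        ("acceptor_S.start", locus.acceptor_S.start),
        ("acceptor_S.end", locus.acceptor_S.end),
        ("primer3.start", locus.primer3.start),
    ]
    for (n1, c1), (n2, c2) in zip(chain, chain[1:]):
        if c1 > c2:
            v.append(f"ordering violated: {n1} ({c1}) > {n2} ({c2})")
    L = len(locus.locus)
    for name, iv in [
        ("primer5", locus.primer5),
        ("primer3", locus.primer3),
        ("donor_S", locus.donor_S),
        ("acceptor_S", locus.acceptor_S),
        ("roi5_window", locus.roi5_window),
        ("roi3_window", locus.roi3_window),
    ] + [(f"extra_S[{k}]", iv) for k, iv in locus.extra_S.items()]:
        if iv.start < 0 or iv.end > L:
            v.append(f"{name} [{iv.start}, {iv.end}) extends outside locus [0, {L})")
    if not locus.roi5_window.contains_interval(locus.donor_S):
        v.append("roi5_window does not contain donor_S")
    if not locus.roi3_window.contains_interval(locus.acceptor_S):
        v.append("roi3_window does not contain acceptor_S")
    if locus.roi5_window.overlaps(locus.roi3_window):
        v.append("roi5_window and roi3_window overlap")
    if locus.bait_site.coord > locus.donor_S.end:
        v.append(
            f"bait_site ({locus.bait_site.coord}) lies downstream of donor_S.end "
            f"({locus.donor_S.end}); bait must be within or upstream of donor_S"
        )
    if locus.bait_site.coord < 0 or locus.bait_site.coord > L:
        v.append("bait_site outside locus")
    for i, (db, ab) in enumerate(locus.blocklist):
        if not (0 <= db <= L):
            v.append(f"blocklist[{i}] donor_break {db} outside locus")
        if not (0 <= ab <= L):
            v.append(f"blocklist[{i}] acceptor_break {ab} outside locus")
    if locus.del_strand not in ("+", "-"):
        v.append(f"del_strand must be '+' or '-', got {locus.del_strand!r}")
    if locus.germline_amplicon_len <= locus.thresholds.productive_max_len:
        v.append(
            f"germline amplicon length ({locus.germline_amplicon_len}) does not "
            f"exceed productive_max_len ({locus.thresholds.productive_max_len})"
        )
    return v


_CONVENTIONS = ("0-based-half-open", "1-based-inclusive")


def _require(cfg: dict, key: str):
    if key not in cfg:
        raise LocusConfigError(f"missing required key: {key!r}")
    return cfg[key]


def _interval_from_cfg(raw, key: str, chrom: str, convention: str) -> tuple:
    """Return a genome-frame half-open (start, end) from a config mapping."""
    try:
        start, end = int(raw["start"]), int(raw["end"])
    except (TypeError, KeyError, ValueError) as exc:
        raise LocusConfigError(f"key {key!r}: expected mapping with integer start/end") from exc
    if convention == "1-based-inclusive":
        start -= 1
    if start < 0 or start >= end:
        raise LocusConfigError(f"key {key!r}: invalid interval [{start}, {end})")
    return start, end


def _coord_from_cfg(value, key: str, convention: str) -> int:
    try:
        c = int(value)
    except (TypeError, ValueError) as exc:
        raise LocusConfigError(f"key {key!r}: expected an integer coordinate") from exc
    if convention == "1-based-inclusive":
        c -= 1
    return c


def load_locus_config(path) -> LocusMap:
    """Load a YAML locus configuration and normalize to canonical coordinates.

    The file must declare its coordinate convention explicitly
    (``coordinate_convention: 0-based-half-open`` or ``1-based-inclusive``);
    no silent guessing.  Raises :class:`LocusConfigError` naming the offending
    key on parse problems and :class:`LocusValidationError` listing every
    violated structural constraint.
    """
    with open(path) as fh:
        try:
            cfg = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise LocusConfigError(f"cannot parse YAML: {exc}") from exc
    if not isinstance(cfg, dict):
        raise LocusConfigError("config root must be a mapping")

    convention = _require(cfg, "coordinate_convention")
    if convention not in _CONVENTIONS:
        raise LocusConfigError(
            f"key 'coordinate_convention': must be one of {_CONVENTIONS}, got {convention!r}"
        )
    reference = str(_require(cfg, "reference"))
    locus_raw = _require(cfg, "locus")
    chrom = str(locus_raw.get("chrom", reference))
    g_start, g_end = _interval_from_cfg(locus_raw, "locus", chrom, convention)
    strand = locus_raw.get("strand", "+")
    if strand not in ("+", "-"):
        raise LocusConfigError(f"key 'locus.strand': must be '+' or '-', got {strand!r}")
    locus_iv = GenomicInterval(chrom, g_start, g_end, strand)

    # temporary map for coordinate conversion only
    def conv_interval(key) -> GenomicInterval:
        gs, ge = _interval_from_cfg(_require_path(cfg, key), key, chrom, convention)
        if strand == "+":
            cs, ce = gs - g_start, ge - g_start
        else:
            cs, ce = g_end - ge, g_end - gs
        if cs < 0 or ce > g_end - g_start:
            raise LocusConfigError(f"key {key!r}: interval outside declared locus")
        return GenomicInterval(chrom, cs, ce)

    def _require_path(cfg: dict, dotted: str):
        node = cfg
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise LocusConfigError(f"missing required key: {dotted!r}")
            node = node[part]
        return node

    primer5 = conv_interval("primer5")
    primer3 = conv_interval("primer3")
    donor = conv_interval("s_regions.donor")
    acceptor = conv_interval("s_regions.acceptor")
    extra = {}
    extra_raw = cfg.get("s_regions", {}).get("extra") or {}
    for name in extra_raw:
        extra[str(name)] = conv_interval(f"s_regions.extra.{name}")

    thr_raw = _require(cfg, "thresholds")
    try:
        thresholds = IsotypeThresholds(
            productive_min_len=int(round(float(thr_raw["productive_min_kb"]) * 1000)),
            productive_max_len=int(round(float(thr_raw["productive_max_kb"]) * 1000)),
            label=str(thr_raw.get("label", "")),
        )
    except (TypeError, KeyError, ValueError) as exc:
        raise LocusConfigError(
            "key 'thresholds': expected productive_min_kb < productive_max_kb"
        ) from exc

    bait_raw = _require(cfg, "bait_site")
    bait_g = _coord_from_cfg(bait_raw.get("coord"), "bait_site.coord", convention)
    bait_strand_g = bait_raw.get("strand", "+")
    if strand == "+":
        bait_c = bait_g - g_start
        bait_strand = bait_strand_g
    else:
        bait_c = (g_end - 1) - bait_g
        bait_strand = "-" if bait_strand_g == "+" else "+"

    blocklist = []
    for i, entry in enumerate(cfg.get("blocklist") or []):
        try:
            db_g = _coord_from_cfg(entry["donor"], f"blocklist[{i}].donor", convention)
            ab_g = _coord_from_cfg(entry["acceptor"], f"blocklist[{i}].acceptor", convention)
        except (TypeError, KeyError) as exc:
            raise LocusConfigError(f"key 'blocklist[{i}]': expected donor/acceptor coords") from exc
        if strand == "+":
            blocklist.append((db_g - g_start, ab_g - g_start))
        else:
            blocklist.append((g_end - db_g, g_end - ab_g))

    lm = LocusMap(
        reference_name=reference,
        locus=locus_iv,
        canonical_strand=strand,
        primer5=primer5,
        primer3=primer3,
        donor_S=donor,
        acceptor_S=acceptor,
        extra_S=extra,
        thresholds=thresholds,
        bait_site=BaitSite(bait_c, bait_strand),
        roi_pad=int(cfg.get("roi_pad", 5000)),
        junction_pad=int(cfg.get("junction_pad", 10000)),
        blocklist=blocklist,
        del_strand=str(cfg.get("del_strand", "+")),
    )
    violations = validate_locus(lm)
    if violations:
        raise LocusValidationError(violations)
    return lm


def save_locus_config(locus: LocusMap, path) -> None:
    """Serialize a LocusMap back to YAML (0-based half-open genome frame).

    ``load_locus_config(save_locus_config(lm))`` round-trips.
    """
    def iv_out(iv: GenomicInterval) -> dict:
        gs, ge = locus.interval_to_genome(iv.start, iv.end)
        return {"start": int(gs), "end": int(ge)}

    bait_g = locus.to_genome(locus.bait_site.coord)
    cfg = {
        "coordinate_convention": "0-based-half-open",
        "reference": locus.reference_name,
        "locus": {
            "chrom": locus.locus.chrom,
            "start": int(locus.locus.start),
            "end": int(locus.locus.end),
            "strand": locus.canonical_strand,
        },
        "primer5": iv_out(locus.primer5),
        "primer3": iv_out(locus.primer3),
        "s_regions": {
            "donor": iv_out(locus.donor_S),
            "acceptor": iv_out(locus.acceptor_S),
            "extra": {k: iv_out(v) for k, v in locus.extra_S.items()},
        },
        "roi_pad": int(locus.roi_pad),
        "junction_pad": int(locus.junction_pad),
        "thresholds": {
            "label": locus.thresholds.label,
            "productive_min_kb": locus.thresholds.productive_min_len / 1000,
            "productive_max_kb": locus.thresholds.productive_max_len / 1000,
        },
        "bait_site": {
            "coord": int(bait_g),
            "strand": locus.strand_to_genome(locus.bait_site.strand),
        },
        "del_strand": locus.del_strand,
        "blocklist": [
            {
                "donor": int(locus.break_to_genome(db)),
                "acceptor": int(locus.break_to_genome(ab)),
            }
            for db, ab in locus.blocklist
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
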