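"""Metaphase-aberration statistics and consolidated run reports.

Cytogenetic readouts arrive as per-genotype count tables: total metaphases
scored, metaphases with a locus break, metaphases with a locus
translocation (disjoint classes; a metaphase is counted once).  Contrasts
against a reference genotype use the two-sided Fisher's exact test on 2x2
tables, with three tabulations per comparison: normal vs aberrant
(aberrant = breaks + translocations), break vs others, and translocation
vs others.

The Fisher p-value uses the probability-mass definition (the sum of
hypergeometric probabilities, margins fixed, of every table at most as
probable as the observed one) computed with exact integer arithmetic and a
1e-12 relative tie tolerance, so results are reproducible to full double
precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MetaphaseCounts",
    "fisher_exact_two_sided",
    "aberration_report",
    "run_pipeline",
    "StageError",
]

logger = logging.getLogger(__name__)

_TIE_NUM = 10**12 + 1
_TIE_DEN = 10**12


@dataclass(frozen=True)
class MetaphaseCounts:
    """Aberration counts for one genotype/condition (pooled or per-experiment)."""

    group_id: str
    n_total: int
    n_breaks: int
    n_translocations: int
    experiment_id: str = ""

    def __post_init__(self):
        if min(self.n_total, self.n_breaks, self.n_translocations) < 0:
            raise ValueError("counts must be >= 0")
        if self.n_breaks + self.n_translocations > self.n_total:
            raise ValueError(
                f"{self.group_id}: breaks + translocations exceed total metaphases"
            )

    @property
    def n_aberrant(self) -> int:
        return self.n_breaks + self.n_translocations

    @property
    def n_normal(self) -> int:
        return self.n_total - self.n_aberrant


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Probability-mass method: with margins fixed, sum the hypergeometric
    probabilities of all tables whose probability is at most the observed
    table's probability times (1 + 1e-12).  Exact integer arithmetic; the
    returned float is the correctly rounded quotient.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be >= 0")
    n = a + b + c + d
    if n == 0:
        raise ValueError("Fisher test undefined for the all-zero table")
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    num = 0
    for x in range(lo, hi + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w * _TIE_DEN <= w_obs * _TIE_NUM:
            num += w
    den = comb(n, c1)
    # correctly rounded rational -> float (num/den can be huge integers);
    # p is strictly positive (the observed table always qualifies), so guard
    # against denormal underflow to keep p in (0, 1]
    p = float(Fraction(num, den))
    return p if p > 0.0 else 5e-324


_CONTRASTS = ("normal_vs_aberrant", "break_vs_others", "translocation_vs_others")


def _contrast_table(ref: MetaphaseCounts, grp: MetaphaseCounts, contrast: str):
    if contrast == "normal_vs_aberrant":
        return (ref.n_normal, ref.n_aberrant, grp.n_normal, grp.n_aberrant)
    if contrast == "break_vs_others":
        return (ref.n_total - ref.n_breaks, ref.n_breaks,
                grp.n_total - grp.n_breaks, grp.n_breaks)
    if contrast == "translocation_vs_others":
        return (ref.n_total - ref.n_translocations, ref.n_translocations,
                grp.n_total - grp.n_translocations, grp.n_translocations)
    raise ValueError(f"unknown contrast {contrast!r}")


def aberration_report(tables, reference_group: str) -> dict:
    """Percentages per group and Fisher contrasts against a reference group.

    ``tables`` may contain one pooled row per group or several
    per-experiment rows; per-experiment rows are pooled for the exact tests
    and additionally summarized as mean +/- SEM of per-experiment
    percentages.  Raises on duplicate pooled group ids or a missing
    reference group.
    """
    rows = list(tables)
    seen = set()
    for t in rows:
        key = (t.group_id, t.experiment_id)
        if key in seen:
            raise ValueError(f"duplicate group/experiment id: {key}")
        seen.add(key)

    by_group: dict = {}
    for t in rows:
        by_group.setdefault(t.group_id, []).append(t)
    if reference_group not in by_group:
        raise ValueError(f"reference group {reference_group!r} not present")

    def pooled(group_rows):
        return MetaphaseCounts(
            group_id=group_rows[0].group_id,
            n_total=sum(t.n_total for t in group_rows),
            n_breaks=sum(t.n_breaks for t in group_rows),
            n_translocations=sum(t.n_translocations for t in group_rows),
        )

    ref = pooled(by_group[reference_group])
    report = {"reference_group": reference_group, "groups": {}}
    for gid, group_rows in by_group.items():
        g = pooled(group_rows)
        entry = {
            "n_total": g.n_total,
            "n_breaks": g.n_breaks,
            "n_translocations": g.n_translocations,
            "pct_aberrant": 100.0 * g.n_aberrant / g.n_total if g.n_total else None,
            "pct_breaks": 100.0 * g.n_breaks / g.n_total if g.n_total else None,
            "pct_translocations": (
                100.0 * g.n_translocations / g.n_total if g.n_total else None
            ),
        }
        if len(group_rows) > 1:
            pcts = np.array(
                [100.0 * t.n_aberrant / t.n_total for t in group_rows if t.n_total]
            )
            entry["pct_aberrant_mean"] = float(pcts.mean())
            entry["pct_aberrant_sem"] = float(pcts.std(ddof=1) / np.sqrt(len(pcts)))
        if gid != reference_group:
            entry["p_values"] = {
                contrast: fisher_exact_two_sided(*_contrast_table(ref, g, contrast))
                for contrast in _CONTRASTS
            }
        report["groups"][gid] = entry
    return report


def read_metaphase_csv(path):
    """Read a metaphase count CSV (group_id, [experiment_id,] n_total,
    n_breaks, n_translocations) into MetaphaseCounts rows."""
    df = pd.read_csv(path)
    required = {"group_id", "n_total", "n_breaks", "n_translocations"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metaphase CSV missing columns: {sorted(missing)}")
    return [
        MetaphaseCounts(
            group_id=str(row.group_id),
            n_total=int(row.n_total),
            n_breaks=int(row.n_breaks),
            n_translocations=int(row.n_translocations),
            experiment_id=str(getattr(row, "experiment_id", "") or ""),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# orchestrator


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name prefixes the message."""

    def __init__(self, stage: str, exc: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {exc}")


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run one analysis mode end to end and write its report bundle.

    ``config['mode']`` selects the stage: ``simulate`` (locus + events +
    fixtures), ``lrpcr`` (simulate or load reads, call junctions), ``htgts``
    (classify a TLX table), ``vdj`` (decompose Sanger junctions) or
    ``metaphase`` (aberration statistics).  Outputs go to ``out_dir`` when
    given (tables as TSV/CSV, summary as JSON, plus a run log with seed and
    parameters); the in-memory report dict is returned either way.
    """
    from . import __version__

    mode = config.get("mode")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    try:
        if mode == "simulate":
            report = _stage_simulate(config, out)
        elif mode == "lrpcr":
            report = _stage_lrpcr(config, out)
        elif mode == "htgts":
            report = _stage_htgts(config, out)
        elif mode == "vdj":
            report = _stage_vdj(config, out)
        elif mode == "metaphase":
            report = _stage_metaphase(config, out)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage name must propagate
        raise StageError(mode or "config", exc) from exc

    report["run_log"] = {
        "mode": mode,
        "version": __version__,
        "seed": config.get("sim", {}).get("seed"),
        "params": {k: v for k, v in config.items() if k != "mode"},
    }
    if out is not None:
        with open(out / "summary.json", "w") as fh:
            json.dump(report, fh, indent=2, default=str)
    return report


def _sim_params(config):
    from .simulate import SimParams

    return SimParams(**config.get("sim", {}))


def _simulate_inputs(config):
    from .simulate import make_synthetic_locus, sample_events

    params = _sim_params(config)
    record, locus = make_synthetic_locus(params)
    events = sample_events(params, locus, str(record.seq))
    return params, record, locus, events


def _stage_simulate(config, out):
    from .simulate import (
        events_to_frame,
        render_htgts_table,
        render_lrpcr_reads,
        write_fastq,
        write_tlx,
    )
    from .locus import save_locus_config

    params, record, locus, events = _simulate_inputs(config)
    report = {
        "n_events": len(events),
        "n_inv": sum(1 for e in events if e.orientation == "INV"),
        "n_resected": sum(1 for e in events if e.region_class == "RESECTED"),
    }
    if out is not None:
        with open(out / "reference.fasta", "w") as fh:
            fh.write(f">{record.id}\n{record.seq}\n")
        save_locus_config(locus, out / "locus.yaml")
        events_to_frame(events).to_csv(out / "truth.csv", index=False)
        reads, _ = render_lrpcr_reads(events, str(record.seq), locus, params)
        report["n_reads"] = write_fastq(reads, out / "reads.fastq")
        write_tlx(render_htgts_table(events, str(record.seq), locus, params),
                  out / "junctions.tlx.tsv")
    return report


def _stage_lrpcr(config, out):
    from .lrpcr import junctions_to_frame, run_lrpcr
    from .simulate import render_lrpcr_reads

    cfg = config.get("lrpcr", {})
    if "reads" in config or "bam" in config:
        from .align import read_alignment_chains
        from .locus import load_locus_config
        from .lrpcr import calls_from_chains, dedup_and_filter, summarize_lrpcr

        locus = load_locus_config(config["locus_config"])
        chains = read_alignment_chains(config["bam"], locus)
        calls, lengths, n_complex, n_failed = calls_from_chains(chains, locus)
        junctions = dedup_and_filter(
            calls, min_depth=cfg.get("min_depth", 10), locus=locus
        )
        summary = summarize_lrpcr(
            lengths, junctions, locus, cfg.get("bin_width", 250),
            n_reads_in=len(chains),
        )
        result_junctions = junctions
        report = {"summary": summary.to_dict(),
                  "n_complex": n_complex, "n_failed": n_failed}
        locus_for_frame = locus
    else:
        params, record, locus, events = _simulate_inputs(config)
        reads, unamplified = render_lrpcr_reads(events, str(record.seq), locus, params)
        result = run_lrpcr(
            reads, str(record.seq), locus,
            min_depth=cfg.get("min_depth", 10),
            bin_width=cfg.get("bin_width", 250),
        )
        result_junctions = result.junctions
        report = {
            "summary": result.summary.to_dict(),
            "n_unamplified_inv_events": len(unamplified),
            "n_complex": result.n_complex,
        }
        locus_for_frame = locus
    if out is not None:
        junctions_to_frame(result_junctions, locus_for_frame).to_csv(
            out / "unique_junctions.tsv", sep="\t", index=False
        )
        _write_junction_bed(result_junctions, locus_for_frame, out / "junctions.bed")
    return report


def _write_junction_bed(junctions, locus, path):
    with open(path, "w") as fh:
        for j in junctions:
            for name, b in (("donor", j.donor_break), ("acceptor", j.acceptor_break)):
                g = locus.break_to_genome(b)
                fh.write(
                    f"{locus.locus.chrom}\t{g}\t{g + 1}\t"
                    f"{name}:{j.donor_break}-{j.acceptor_break}\t{j.depth}\t.\n"
                )


def _stage_htgts(config, out):
    from .htgts import classified_to_frame, classify_record, read_tlx, summarize_htgts

    if "tlx" in config:
        from .locus import load_locus_config

        locus = load_locus_config(config["locus_config"])
        records = read_tlx(config["tlx"], config.get("dialect", "switchjoint"))
        reference = None
        if config.get("reference_fasta"):
            from Bio import SeqIO

            rec = next(SeqIO.parse(config["reference_fasta"], "fasta"))
            reference = str(rec.seq)
    else:
        from .simulate import render_htgts_table, write_tlx

        params, record, locus, events = _simulate_inputs(config)
        table = render_htgts_table(events, str(record.seq), locus, params)
        if out is not None:
            write_tlx(table, out / "junctions.tlx.tsv")
        import io

        buf = io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        records = read_tlx(buf)
        reference = str(record.seq)
    classified = [classify_record(r, locus, reference) for r in records]
    summary = summarize_htgts(classified, locus)
    if out is not None:
        classified_to_frame(classified).to_csv(
            out / "classified_junctions.tsv", sep="\t", index=False
        )
    return {"summary": summary.to_dict()}


def _stage_vdj(config, out):
    from .signature import analyze_vdj_junction
    from .simulate import render_vdj_junctions

    params = _sim_params(config)
    n = config.get("vdj", {}).get("n", params.n_events)
    v_ref, j_ref, junctions, truth = render_vdj_junctions(params, n=n)
    rows = []
    for sid, seq in junctions:
        sig = analyze_vdj_junction(seq, v_ref, j_ref)
        rows.append(
            {"seq_id": sid, "v_resection": sig.v_resection,
             "j_resection": sig.j_resection, "mh": sig.mh_len,
             "ins_len": sig.ins_len}
        )
    result = pd.DataFrame(rows)
    merged = truth.merge(result, on="seq_id", suffixes=("_truth", ""))
    exact = bool(
        (merged["v_resection_truth"] == merged["v_resection"]).all()
        and (merged["j_resection_truth"] == merged["j_resection"]).all()
        and (merged["mh_truth"] == merged["mh"]).all()
        and (merged["ins_len_truth"] == merged["ins_len"]).all()
    )
    if out is not None:
        result.to_csv(out / "vdj_signatures.tsv", sep="\t", index=False)
        truth.to_csv(out / "vdj_truth.tsv", sep="\t", index=False)
    return {
        "n_junctions": len(result),
        "mean_v_resection": float(result["v_resection"].mean()),
        "mean_j_resection": float(result["j_resection"].mean()),
        "pct_with_mh": float(100.0 * (result["mh"] > 0).mean()),
        "pct_with_insertion": float(100.0 * (result["ins_len"] > 0).mean()),
        "truth_recovered_exactly": exact,
    }


def _stage_metaphase(config, out):
    counts = read_metaphase_csv(config["counts"])
    report = aberration_report(counts, config["reference_group"])
    if out is not None:
        rows = []
        for gid, entry in report["groups"].items():
            for contrast, p in entry.get("p_values", {}).items():
                rows.append({"group": gid, "contrast": contrast, "p_value": p})
        pd.DataFrame(rows).to_csv(out / "fisher_tests.tsv", sep="\t", index=False)
    return report
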