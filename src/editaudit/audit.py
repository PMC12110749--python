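"""End-to-end audit driver: chains every stage and aggregates the report.

The report is a plain dict (JSON-serializable) with one section per stage:
on-target allele tables with the wild-type certificate, the off-target
summary, insertion calls split into masked and headline, the copy-number
table, the coverage-anomaly table, and a provenance block (inputs, config
hash, seed, version).  Every number in the report is recomputed from the
stage outputs it aggregates; ``verify_report`` asserts the internal totals.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .config import AuditConfig, default_config
from .coverage import copy_number, depth_track, scan_anomalies
from .fixtures import ReadPair
from .hybridref import ReferenceSet, build_reference, compute_homology_mask
from .microalign import (
    Scoring,
    align_reads,
    build_index,
    extract_gapped_inserts,
    extract_softclips,
)
from .offtarget import audit_offtargets
from .ontarget import AlignmentIndex, call_alleles, discordant_span_support, locate_guides
from .rearrange import cluster_breakpoints, collect_discordant_pairs, headline_calls
from .seqio import AlignedRead, Interval, SeqRecord

logger = logging.getLogger(__name__)

__all__ = ["AuditInputs", "run_audit", "verify_report"]


@dataclass
class AuditInputs:
    host: list[SeqRecord]
    plasmids: list[SeqRecord] = field(default_factory=list)
    contaminant: list[SeqRecord] = field(default_factory=list)
    guides: list[tuple[str, str]] = field(default_factory=list)
    annotation: list[Interval] = field(default_factory=list)
    pairs: list[ReadPair] = field(default_factory=list)
    alignments: list[AlignedRead] | None = None
    #: copy-number intervals in raw plasmid (circle) coordinates
    copy_intervals: list[Interval] = field(default_factory=list)


def _interval_dict(iv: Interval) -> dict:
    return {"seq_id": iv.seq_id, "start": iv.start, "end": iv.end, "name": iv.name}


def _stage(name: str, t0: float, count: int) -> None:
    logger.info("stage %-12s %6.2fs  %d records", name, time.perf_counter() - t0, count)


def run_audit(config: AuditConfig | None = None, inputs: AuditInputs | None = None) -> dict:
    """Run every stage in dependency order and return the audit report."""
    cfg = config or default_config()
    if inputs is None or not inputs.host:
        raise ValueError("audit inputs incomplete: host references required")
    if not inputs.pairs and inputs.alignments is None:
        raise ValueError("audit inputs incomplete: reads or alignments required")

    t0 = time.perf_counter()
    hybrid = build_reference(
        inputs.host, inputs.plasmids, inputs.contaminant, cfg.plasmid_overhang
    )
    mask = compute_homology_mask(hybrid, cfg.mask_min_match)
    _stage("build-ref", t0, len(hybrid.records))

    t0 = time.perf_counter()
    if inputs.alignments is not None:
        alignments = inputs.alignments
    else:
        index = build_index(hybrid)
        alignments = align_reads(inputs.pairs, index, hybrid, Scoring(proper_max_tlen=cfg.read_len + int(cfg.insert_mean + 4 * cfg.insert_sd)))
    _stage("align", t0, len(alignments))
    aln_index = AlignmentIndex(alignments)
    n_reads = sum(1 for a in alignments if not a.is_secondary)
    n_mapped = sum(1 for a in aln_index.all_primary if not a.is_unmapped)
    alignment_rate = n_mapped / n_reads if n_reads else 0.0

    # --- on-target ---------------------------------------------------------
    t0 = time.perf_counter()
    ontarget_section = []
    if inputs.guides:
        loci = locate_guides(hybrid, inputs.guides, cfg)
        for locus in loci:
            entry = {
                "guide": locus.guide_id,
                "seq_id": locus.seq_id,
                "cut_pos": locus.cut_pos,
                "strand": locus.strand,
            }
            try:
                alleles, wt = call_alleles(aln_index, locus, cfg, hybrid)
                entry["assessable"] = True
                entry["wt_read_count"] = wt
                entry["completely_edited"] = wt == 0
                entry["alleles"] = [
                    {
                        "signature": [list(e) for e in a.signature],
                        "supporting_reads": a.supporting_reads,
                        "fraction": round(a.fraction, 4),
                        "source": _interval_dict(a.source) if a.source else None,
                    }
                    for a in alleles
                ]
                spans = discordant_span_support(
                    aln_index, locus, cfg.max_distal_distance, cfg
                )
                entry["distant_pair_support"] = len(spans)
            except ValueError:
                entry["assessable"] = False
                entry["wt_read_count"] = None
                entry["alleles"] = []
            ontarget_section.append(entry)
    _stage("ontarget", t0, len(ontarget_section))

    # --- off-target --------------------------------------------------------
    t0 = time.perf_counter()
    track = depth_track(aln_index.all_primary, hybrid)
    hits, summary = audit_offtargets(
        hybrid, aln_index, inputs.guides, inputs.annotation, cfg, track
    )
    offtarget_section = {
        "summary": summary.to_dict(orient="records"),
        "n_sites_total": len(hits),
        "n_assessable": sum(h.assessable for h in hits),
        "n_with_changes": sum(bool(h.variants) for h in hits),
    }
    _stage("offtarget", t0, len(hits))

    # --- rearrangements ----------------------------------------------------
    t0 = time.perf_counter()
    clips = extract_softclips(alignments, cfg.min_clip_len) + extract_gapped_inserts(
        alignments, cfg.min_clip_len
    )
    pairs = collect_discordant_pairs(alignments)
    calls = cluster_breakpoints(clips, pairs, mask, cfg, hybrid)
    headline = headline_calls(calls)
    rearrange_section = {
        "n_softclips": len(clips),
        "n_discordant_pairs": len(pairs),
        "n_calls": len(calls),
        "n_masked": sum(c.in_mask for c in calls),
        "n_weak": sum(c.weak and not c.in_mask for c in calls),
        "headline": [
            {
                "breakpoint": _interval_dict(c.host_breakpoint),
                "source": c.source_id,
                "source_interval": _interval_dict(c.source_interval) if c.source_interval else None,
                "clip_support": c.clip_support,
                "pair_support": c.pair_support,
                "microhomology_len": c.microhomology_len,
            }
            for c in headline
        ],
    }
    _stage("rearrange", t0, len(calls))

    # --- coverage ----------------------------------------------------------
    t0 = time.perf_counter()
    copy_rows = []
    copy_ivs = list(inputs.copy_intervals)
    if not copy_ivs:
        copy_ivs = [
            Interval(p.id, 0, len(p), ".", p.id) for p in inputs.plasmids
        ]
    for iv in copy_ivs:
        # shift circle coordinates onto the overhung hybrid sequence
        shifted = Interval(
            iv.seq_id, iv.start + cfg.plasmid_overhang, iv.end + cfg.plasmid_overhang, iv.strand, iv.name
        )
        est = copy_number(track, shifted, cfg)
        copy_rows.append(
            {"name": est.name, "mean_cov": round(est.mean_cov, 5), "copies_per_diploid": est.copies_per_diploid}
        )
    anomalies = scan_anomalies(track, inputs.annotation, cfg)
    coverage_section = {
        "genome_mean": round(track.genome_mean, 5),
        "copy_number": copy_rows,
        "anomalies": [
            {
                "interval": _interval_dict(a.interval),
                "type": a.type,
                "length": a.length,
                "cds": a.cds_names,
                "likely_artifact": a.likely_artifact,
            }
            for a in anomalies
        ],
    }
    _stage("coverage", t0, len(anomalies))

    cfg_yaml = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    report = {
        "ontarget": ontarget_section,
        "offtarget": offtarget_section,
        "rearrange": rearrange_section,
        "coverage": coverage_section,
        "alignment_rate": round(alignment_rate, 4),
        "provenance": {
            "version": __version__,
            "seed": cfg.rng_seed,
            "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
            "config": cfg.to_dict(),
            "inputs": {
                "host": {r.id: len(r) for r in inputs.host},
                "plasmids": {r.id: len(r) for r in inputs.plasmids},
                "contaminant": {r.id: len(r) for r in inputs.contaminant},
                "n_read_pairs": len(inputs.pairs),
                "guides": dict(inputs.guides),
            },
        },
    }
    verify_report(report)
    return report


def verify_report(report: dict) -> None:
    """Internal consistency: section totals equal the table lengths."""
    rr = report["rearrange"]
    if rr["n_calls"] < rr["n_masked"] + rr["n_weak"] + len(rr["headline"]):
        raise AssertionError("rearrangement call counts inconsistent")
    ot = report["offtarget"]
    if ot["n_sites_total"] != sum(row["n_sites"] for row in ot["summary"]):
        raise AssertionError("off-target site totals inconsistent")
    if ot["n_assessable"] != sum(row["n_assessable"] for row in ot["summary"]):
        raise AssertionError("off-target assessable totals inconsistent")


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))
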