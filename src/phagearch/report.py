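"""Consolidated genome report: every analysis section from one genome.

The report is a pure function of (genome, annotation, config); repeated
runs produce byte-identical JSON.  Sections needing an annotation are
marked skipped when none is supplied.
"""

from __future__ import annotations

import json
from typing import Sequence

from . import __version__
from .annotation_stats import (
    TerminatorParams,
    codon_summary_dict,
    codon_tally,
    find_overlaps,
    find_terminator,
    partition_units,
)
from .config import AnalysisConfig
from .genome_io import Feature, GenomeRecord
from .nick_analysis import (
    NickConsensus,
    half_distribution,
    percent_position,
    scan_core_with_substitutions,
    scan_motif,
)
from .promoter_scan import TOY_TRAINING, model_from_pairs, scan_promoters
from .terminal_architecture import find_dtr


def gc_percent(g: GenomeRecord) -> float:
    s = g.sequence
    acgt = sum(s.count(b) for b in "ACGT")
    return round(100 * (s.count("G") + s.count("C")) / acgt, 1)


def build_report(
    g: GenomeRecord,
    annotation: Sequence[Feature] | None = None,
    config: AnalysisConfig | None = None,
) -> dict:
    cfg = config or AnalysisConfig()
    consensus = NickConsensus(cfg.consensus_core, cfg.consensus_pattern, cfg.cut_offset)
    report: dict = {
        "tool_version": __version__,
        "config_digest": cfg.digest(),
        "genome": {"id": g.id, "length_bp": g.length, "gc_percent": gc_percent(g)},
    }

    dtr = find_dtr(g, min_len=cfg.dtr_min_len)
    report["dtr"] = (
        {"length": dtr.length, "left_span": list(dtr.left_span), "right_span": list(dtr.right_span)}
        if dtr
        else None
    )

    sites = scan_motif(g, cfg.consensus_pattern, strands=("top",), consensus=consensus)
    left, right = half_distribution(sites, g.length)
    by_variant: dict[str, int] = {}
    for s in sites:
        by_variant[s.variant] = by_variant.get(s.variant, 0) + 1
    from .nick_analysis import expand_iupac

    consensus_variants = expand_iupac(cfg.consensus_pattern)
    grouped = scan_core_with_substitutions(g, cfg.consensus_core, cfg.cut_offset)
    n_d1_only = sum(
        len(v)
        for k, v in grouped.items()
        if v and v[0].mismatches_vs_core == 1 and k not in consensus_variants
    )
    report["nick_sites"] = {
        "n_consensus_sites": len(sites),
        "by_variant": dict(sorted(by_variant.items())),
        "left_half": left,
        "right_half": right,
        "positions_percent": [percent_position(s.start, g.length) for s in sites],
        "n_single_substitution_loci": n_d1_only,
    }

    model = model_from_pairs(
        TOY_TRAINING,
        pseudocount=cfg.promoter_pseudocount,
        spacer_min=cfg.spacer_min,
        spacer_max=cfg.spacer_max,
        cutoff=cfg.promoter_cutoff,
    )
    hits = scan_promoters(g, model)
    report["promoters"] = {
        "n_hits": len(hits),
        "hits": [
            {
                "strand": h.strand,
                "box35_start": h.box35_start,
                "spacer": h.spacer,
                "box10_start": h.box10_start,
                "score": round(h.score, 2),
            }
            for h in hits
        ],
    }

    if annotation is not None:
        cds = [f for f in annotation if f.kind == "CDS"]
        if cds:
            summary = codon_tally(g, cds)
            report["codon_usage"] = codon_summary_dict(summary)
            if len(cds) >= 2:
                ov = find_overlaps(cds)
                report["overlaps"] = {
                    "n_overlapping_pairs": len(ov.pairs),
                    "max_pair": list(ov.max_pair) if ov.max_pair else None,
                }
            units = partition_units(cds)
            report["transcription_units"] = {
                "left_unit_genes": len(units.left_unit),
                "right_unit_genes": len(units.right_unit),
                "boundary_gap": list(units.boundary_gap) if units.boundary_gap else None,
                "strand_violations": len(units.violations),
                "single_unit": units.single_unit,
            }
            if units.boundary_gap:
                params = TerminatorParams(
                    cfg.term_min_stem,
                    cfg.term_max_stem,
                    cfg.term_min_loop,
                    cfg.term_max_loop,
                    cfg.term_max_mismatch,
                    cfg.term_min_u_run,
                    cfg.term_u_window,
                )
                calls = find_terminator(g, units.boundary_gap, params)
                report["terminators"] = [
                    {
                        "span": list(c.span),
                        "stem_len": c.stem_len,
                        "loop_len": c.loop_len,
                        "u_tract_len": c.u_tract_len,
                        "bidirectional": c.bidirectional,
                    }
                    for c in calls[:5]
                ]
    else:
        report["codon_usage"] = "skipped (no annotation)"
        report["overlaps"] = "skipped (no annotation)"
        report["transcription_units"] = "skipped (no annotation)"

    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)


def report_to_text(report: dict) -> str:
    lines = [f"Genome {report['genome']['id']}"]
    g = report["genome"]
    lines.append(f"  length: {g['length_bp']} bp; G+C: {g['gc_percent']}%")
    if report.get("dtr"):
        lines.append(f"  direct terminal repeat: {report['dtr']['length']} bp")
    ns = report["nick_sites"]
    lines.append(
        f"  nick-consensus sites (top strand): {ns['n_consensus_sites']} "
        f"({ns['left_half']} left half / {ns['right_half']} right half)"
    )
    for variant, n in ns["by_variant"].items():
        lines.append(f"    {variant}: {n}")
    lines.append(f"  promoter hits: {report['promoters']['n_hits']}")
    cu = report.get("codon_usage")
    if isinstance(cu, dict):
        lines.append(
            f"  CDS: {cu['n_cds']}; starts {cu['start_counts']}; stops {cu['stop_counts']}"
        )
        tu = report["transcription_units"]
        lines.append(
            f"  transcription units: {tu['left_unit_genes']} left / {tu['right_unit_genes']} right"
        )
        if isinstance(report.get("overlaps"), dict) and report["overlaps"]["max_pair"]:
            a, b, n = report["overlaps"]["max_pair"]
            lines.append(f"  max gene overlap: {n} bp ({a} vs {b})")
    else:
        lines.append("  annotation-dependent sections skipped (no annotation)")
    return "\n".join(lines) + "\n"
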