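#!/usr/bin/env python
"""Promoter scan and annotation statistics of the study genome.

Runs the bidirectional two-box sigma70 scan (spacer 16-19, cutoff 5.31)
with the built-in toy training matrices, then computes start/stop codon
tallies, the gene-overlap report, the convergent transcription-unit
partition, and rho-independent terminator calls in the inter-unit gap.

Writes results/promoters.tsv and results/annotation_stats.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from phagearch.annotation_stats import (
    codon_summary_dict,
    codon_tally,
    find_overlaps,
    find_terminator,
    partition_units,
)
from phagearch.genome_io import read_annotation, read_fasta
from phagearch.promoter_scan import TOY_TRAINING, model_from_pairs, scan_promoters


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fasta", type=Path, default=Path("results/fixture/genome.fasta"))
    ap.add_argument("--gff3", type=Path, default=Path("results/fixture/features.gff3"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    (g,) = read_fasta(args.fasta)
    feats = read_annotation(args.gff3, "gff3", genome_length=g.length)
    cds = [f for f in feats if f.kind == "CDS"]

    model = model_from_pairs(TOY_TRAINING)
    hits = scan_promoters(g, model)
    mid = g.length / 2
    n_left = sum(1 for h in hits if h.strand == "top" and h.span[1] <= mid)
    n_right = sum(1 for h in hits if h.strand == "bottom" and h.span[0] > mid)
    print(f"{len(hits)} promoters >= {model.default_cutoff}: {n_left} top-strand left half, "
          f"{n_right} bottom-strand right half")

    summary = codon_tally(g, cds)
    print(f"{summary.n_cds} CDS; starts {summary.start_counts}; stops {summary.stop_counts}")
    overlaps = find_overlaps(cds)
    a, b, n = overlaps.max_pair
    print(f"max gene overlap: {n} bp between {a} and {b}")
    units = partition_units(cds)
    print(f"transcription units: {len(units.left_unit)} left / {len(units.right_unit)} right; "
          f"boundary gap {units.boundary_gap}")
    calls = find_terminator(g, units.boundary_gap)
    exact = [c for c in calls if c.mismatches == 0]
    if exact:
        c = exact[0]
        print(f"terminator: span {c.span}, stem {c.stem_len}, loop {c.loop_len}, "
              f"U-tract {c.u_tract_len}, bidirectional={c.bidirectional}")

    args.out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "strand": h.strand,
                "box35_start": h.box35_start,
                "spacer": h.spacer,
                "box10_start": h.box10_start,
                "score": round(h.score, 2),
            }
            for h in hits
        ]
    ).to_csv(args.out_dir / "promoters.tsv", sep="\t", index=False)
    payload = {
        "codon_usage": codon_summary_dict(summary),
        "max_overlap": list(overlaps.max_pair),
        "units": {"left": len(units.left_unit), "right": len(units.right_unit)},
        "terminators": [
            {
                "span": list(c.span),
                "stem_len": c.stem_len,
                "loop_len": c.loop_len,
                "bidirectional": c.bidirectional,
                "mismatches": c.mismatches,
            }
            for c in calls[:5]
        ],
    }
    (args.out_dir / "annotation_stats.json").write_text(
        json.dumps(payload, indent=2, sort_keys=True) + "\n"
    )
    print(f"wrote {args.out_dir / 'promoters.tsv'} and annotation_stats.json")


if __name__ == "__main__":
    main()
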