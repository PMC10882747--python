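"""Run the NRS discovery funnel: extract walk-deviation candidates passing
the four retention criteria, remove redundant and reference-like sequences,
classify cNRS/pNRS, anchor to the reference, annotate genomic context and
report interval densities.

Writes results/nrs_table.tsv, results/nrs_funnel.tsv,
results/nrs_density.tsv and the mapping targets scratch/workspace/nrs.fa.
"""

import argparse
import sys
from collections import Counter
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from nrskit.config import DEFAULT_CONFIG
from nrskit.graphio import load_fasta, parse_rgfa, parse_walks, write_nrs_fasta
from nrskit.labeling import label_nodes
from nrskit.nrs import (
    annotate_context,
    classify_and_anchor,
    extract_candidates,
    filter_reference_like,
    interval_density,
    records_table,
    remove_redundant,
)


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=ROOT / "scratch" / "workspace")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    parser.add_argument("--backbone", default="ref")
    args = parser.parse_args(argv)
    args.results.mkdir(parents=True, exist_ok=True)

    topology = parse_rgfa(args.workspace / "graph.gfa")
    parse_walks(args.workspace / "walks.tsv", topology)
    labeling = label_nodes(topology, args.backbone)
    reference = load_fasta(args.workspace / "reference.fa")

    raw = extract_candidates(topology, labeling, backbone_name=args.backbone)
    kept, redundant = remove_redundant(raw)
    kept, reference_like = filter_reference_like(kept, reference)
    final = classify_and_anchor(kept, topology, labeling)

    klass_counts = Counter(r.klass for r in final)
    print(f"raw candidates passing the four criteria: {len(raw)}")
    print(f"  removed as redundant: {len(redundant)}")
    print(f"  removed as reference-like: {len(reference_like)}")
    print(f"retained NRSs: {len(final)} "
          f"({klass_counts['cNRS']} cNRS, {klass_counts['pNRS']} pNRS), "
          f"total {sum(r.total_bp for r in final):,} bp")
    assert len(raw) == len(redundant) + len(reference_like) + len(final)

    contexts = annotate_context(final, args.workspace / "annotation.gff3")
    context_counts = Counter(contexts.values())
    print(f"genomic context of anchors: {dict(context_counts)}")

    funnel = pd.DataFrame(
        [
            {"stage": "raw", "count": len(raw)},
            {"stage": "redundant", "count": len(redundant)},
            {"stage": "reference_like", "count": len(reference_like)},
            {"stage": "retained", "count": len(final)},
        ]
    )
    funnel.to_csv(args.results / "nrs_funnel.tsv", sep="\t", index=False)
    records_table(final, contexts).to_csv(args.results / "nrs_table.tsv", sep="\t", index=False)
    write_nrs_fasta(final, args.workspace / "nrs.fa", reference=reference,
                    flank_bp=DEFAULT_CONFIG.flank_bp)

    density_rows = []
    for chrom, seq in reference.items():
        count, density, span_mb = interval_density(final, (chrom, 0, len(seq)), span_decimals=2)
        density_rows.append({"chrom": chrom, "count": count, "span_mb": span_mb,
                             "density_per_mb": round(density, 2)})
        print(f"  {chrom}: {count} NRSs over {span_mb} Mb = {density:.1f} per Mb")
    pd.DataFrame(density_rows).to_csv(args.results / "nrs_density.tsv", sep="\t", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
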