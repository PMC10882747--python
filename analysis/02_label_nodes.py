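"""Parse the pangenome graph and walks, label every node as reference /
non-reference / skeptical, and summarize the non-reference node (NRN) load
per assembly and its sharing spectrum.

Writes results/node_labels.tsv and results/nrn_summary.tsv.
"""

import argparse
import sys
from collections import Counter
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from nrskit.graphio import parse_rgfa, parse_walks
from nrskit.labeling import label_nodes, labeling_summary, write_label_report


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

    counts = Counter(labeling.label.values())
    print(f"segments: {len(topology.segments)} "
          f"({counts['reference']} reference, {counts['non_reference']} non-reference, "
          f"{counts['skeptical']} skeptical)")
    print(f"credible NRNs: {len(labeling.nrn_ids)} with cumulative length "
          f"{labeling.nrn_total_bp:,} bp")

    write_label_report(labeling, topology, args.results / "node_labels.tsv")
    per_asm, spectrum = labeling_summary(labeling, topology, backbone_name=args.backbone)
    per_asm.to_csv(args.results / "nrn_summary.tsv", sep="\t", index=False)
    for row in per_asm.itertuples(index=False):
        print(f"  {row.assembly}: {row.nrn_count} NRNs, {row.nrn_bp:,} bp")
    shared = {k: v for k, v in spectrum.items() if v}
    print(f"sharing spectrum (k assemblies -> NRN count): {shared}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
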