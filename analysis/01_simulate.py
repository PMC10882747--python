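"""Generate the synthetic study workspace: reference genome, pangenome
graph, per-assembly walks, gene annotation, per-sample coverage intervals,
group labels and the ground-truth table.

Bulky inputs (FASTA/rGFA/TSV) land under scratch/workspace; everything
downstream reads from there.  The truth table records what every later
stage should find.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from nrskit.synthetic import SimulationConfig, generate_dataset, simulate_coverage, truth_table_frame


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=42)
    parser.add_argument("--workspace", type=Path, default=ROOT / "scratch" / "workspace")
    args = parser.parse_args(argv)

    config = SimulationConfig(seed=args.seed)
    dataset = generate_dataset(config, args.workspace)
    simulate_coverage(dataset.truth, config, args.workspace)

    truth = truth_table_frame(dataset.truth)
    n_retainable = int((truth["expected_final"] == "retained").sum())
    print(f"workspace: {args.workspace}")
    print(f"reference: {config.n_chroms} chromosomes x {config.chrom_len_bp:,} bp")
    print(
        f"graph: {len(dataset.topology.segments)} segments, "
        f"{len(dataset.topology.links)} links, "
        f"{len(dataset.topology.walks)} walks (incl. backbone)"
    )
    print(
        f"planted insertions: {len(truth)} "
        f"({n_retainable} expected retained, "
        f"{(truth['expected_final'] == 'dropped').sum()} sub-threshold, "
        f"{(truth['expected_final'] == 'redundant').sum()} redundant decoys, "
        f"{(truth['expected_final'] == 'reference_like').sum()} reference-like decoys)"
    )
    print(
        f"samples: {sum(config.n_samples_per_group)} in two groups at "
        f"depth {config.depth}x, read length {config.read_len_bp} bp"
    )
    return 0


if __name__ == "__main__":
    sys.exit(main())
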