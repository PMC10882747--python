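"""Contrast NRS presence frequencies between the two sample groups with
two-sided Fisher exact tests under Bonferroni correction, and report the
genes overlapped by significant NRS anchors.

Writes results/group_comparison.tsv and prints a headline summary in the
shape of a frequency-comparison table.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from nrskit.nrs import NrsRecord
from nrskit.pav import PavMatrix, classify_frequencies
from nrskit.popstats import compare_groups, genes_overlapping, results_table, summarize_comparison


def load_records(nrs_table: pd.DataFrame) -> list[NrsRecord]:
    records = []
    for row in nrs_table.itertuples(index=False):
        records.append(
            NrsRecord(
                id=row.id, node_path=(), sequence="", total_bp=row.total_bp,
                nrn_bp=row.nrn_bp, supporters=frozenset(str(row.supporters).split(",")),
                klass=row.klass, anchor=(row.chrom, row.pos_1based - 1),
                source_interval=(row.pos_1based - 1, row.pos_1based - 1),
            )
        )
    return records


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=ROOT / "scratch" / "workspace")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args(argv)

    pav = pd.read_csv(args.results / "pav_matrix.tsv", sep="\t", index_col="sample")
    categories = pd.read_csv(args.results / "pav_categories.tsv", sep="\t")
    groups_frame = pd.read_csv(args.workspace / "groups.tsv", sep="\t", comment="#")
    nrs_table = pd.read_csv(args.results / "nrs_table.tsv", sep="\t")

    matrix = PavMatrix(
        samples=list(pav.index),
        nrs_ids=list(pav.columns),
        present=pav.to_numpy(dtype=bool),
    )
    classify_frequencies(matrix)
    groups = dict(zip(groups_frame["sample"], groups_frame["group"]))

    results = compare_groups(matrix, groups)
    summary = summarize_comparison(results)
    n1 = sum(1 for g in groups.values() if g == "group1")
    n2 = len(groups) - n1
    print(f"comparison: group1 (n={n1}) vs group2 (n={n2})")
    print(f"NRSs tested: {summary['n_tested']}, significant after Bonferroni "
          f"(adjusted P < 0.01): {summary['n_significant']}")
    print(f"  higher frequency in group1: {summary['higher_in_group1']}")
    print(f"  higher frequency in group2: {summary['higher_in_group2']}")

    records = load_records(nrs_table)
    genes = genes_overlapping(results, records, args.workspace / "annotation.gff3")
    print(f"genes overlapped by significant NRS anchors: {genes if genes else 'none'}")

    by_id = {r.id: r for r in records}
    gene_hits = {}
    for res in results:
        if res.significant:
            hits = genes_overlapping([res], records, args.workspace / "annotation.gff3")
            gene_hits[res.nrs_id] = hits
    table = results_table(results, records, gene_hits)
    table.to_csv(args.results / "group_comparison.tsv", sep="\t", index=False)

    for res in sorted(results, key=lambda r: r.p_raw)[:3]:
        f1 = res.a / (res.a + res.b)
        f2 = res.c / (res.c + res.d)
        print(f"  {res.nrs_id}: {res.a}/{res.a + res.b} vs {res.c}/{res.c + res.d} "
              f"(freq {f1:.2f} vs {f2:.2f}), raw P = {res.p_raw:.3g}, "
              f"adjusted P = {res.p_adj:.3g}"
              + (" *" if res.significant else ""))
    return 0


if __name__ == "__main__":
    sys.exit(main())
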