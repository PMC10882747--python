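"""Genotype NRS presence/absence across the population from coverage
breadth, classify frequency categories, and run PCA of the PAV matrix.

Joins the retained NRS records (03) to the simulated per-sample coverage
intervals via their reference anchors, calls presence at breadth > 70%,
and writes results/pav_matrix.tsv, results/pav_categories.tsv and
results/pav_pca_scores.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from nrskit.pav import (
    build_profiles,
    call_presence,
    category_counts,
    classify_frequencies,
    non_skeptical_total,
    pav_pca,
)


def main(argv=None):
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workspace", type=Path, default=ROOT / "scratch" / "workspace")
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args(argv)
    args.results.mkdir(parents=True, exist_ok=True)

    nrs = pd.read_csv(args.results / "nrs_table.tsv", sep="\t")
    truth = pd.read_csv(args.workspace / "truth.tsv", sep="\t", comment="#")
    intervals = pd.read_csv(args.workspace / "intervals.tsv", sep="\t", comment="#")
    groups = pd.read_csv(args.workspace / "groups.tsv", sep="\t", comment="#")

    # intervals are keyed by planted-insertion id; join records via anchors
    anchor_to_truth = {
        (row.chrom, row.breakpoint + 1): row.id for row in truth.itertuples(index=False)
    }
    record_of_truth = {
        anchor_to_truth[(row.chrom, row.pos_1based)]: row.id
        for row in nrs.itertuples(index=False)
        if (row.chrom, row.pos_1based) in anchor_to_truth
    }
    intervals = intervals[intervals["nrs_id"].isin(record_of_truth)].copy()
    intervals["nrs_id"] = intervals["nrs_id"].map(record_of_truth)
    lengths = dict(zip(nrs["id"], nrs["total_bp"]))

    samples = list(groups["sample"])
    profiles = build_profiles(intervals, lengths, samples)
    matrix = call_presence(profiles)
    classify_frequencies(matrix)

    counts = category_counts(matrix)
    print(f"PAV matrix: {len(matrix.samples)} samples x {len(matrix.nrs_ids)} NRSs")
    print(f"categories: {counts}")
    print(f"NRSs for downstream analysis after removing skeptical: "
          f"{non_skeptical_total(counts)}")

    matrix.to_dataframe().to_csv(args.results / "pav_matrix.tsv", sep="\t",
                                 index_label="sample")
    pd.DataFrame(
        {
            "nrs_id": matrix.nrs_ids,
            "freq": [matrix.freq[n] for n in matrix.nrs_ids],
            "category": [matrix.category[n] for n in matrix.nrs_ids],
        }
    ).to_csv(args.results / "pav_categories.tsv", sep="\t", index=False)

    n_components = min(4, len(matrix.samples) - 1, len(matrix.nrs_ids))
    scores, eigvals = pav_pca(matrix, n_components)
    frame = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(n_components)])
    frame.insert(0, "sample", matrix.samples)
    frame = frame.merge(groups, on="sample")
    frame.to_csv(args.results / "pav_pca_scores.tsv", sep="\t", index=False)
    explained = eigvals[:n_components] / eigvals.sum() * 100
    print("PCA variance explained: "
          + ", ".join(f"PC{i + 1} {v:.1f}%" for i, v in enumerate(explained)))
    return 0


if __name__ == "__main__":
    sys.exit(main())
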