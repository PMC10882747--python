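"""Group comparison of NRS frequencies: two-sided Fisher exact tests with
Bonferroni correction, plus extraction of genes overlapping significant
NRS anchors.

The two-sided p-value follows the probability-mass convention: it sums the
hypergeometric probabilities of every 2x2 table with the observed margins
whose probability does not exceed that of the observed table.  Table
probabilities are computed with exact integer binomial weights (cached per
margin triple), so ties are resolved exactly and the result is accurate to
floating-point rounding of a single division.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Mapping, Sequence

import pandas as pd

from .config import DEFAULT_CONFIG, ThresholdConfig
from .exceptions import PipelineError
from .pav import PavMatrix


@dataclass
class ContingencyResult:
    """Per-NRS 2x2 contingency outcome for one group comparison."""

    nrs_id: str
    a: int  # present in group 1
    b: int  # absent in group 1
    c: int  # present in group 2
    d: int  # absent in group 2
    p_raw: float
    p_adj: float
    significant: bool
    higher_in: str  # group1 | group2 | tie


@lru_cache(maxsize=100_000)
def _hypergeom_weights(n1: int, n2: int, k: int) -> tuple[tuple[int, ...], int, int]:
    """Integer weights C(n1, x) * C(n2, k - x) over the support of x.

    Returns (weights, x_lo, total) where total = C(n1 + n2, k).
    """
    x_lo = max(0, k - n2)
    x_hi = min(n1, k)
    weights = tuple(comb(n1, x) * comb(n2, k - x) for x in range(x_lo, x_hi + 1))
    return weights, x_lo, comb(n1 + n2, k)


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the table [[a, b], [c, d]].

    Both row margins must be positive.  The p-value is exact up to one
    float division (integer numerator and denominator).
    """
    for name, v in (("a", a), ("b", b), ("c", c), ("d", d)):
        if v < 0 or int(v) != v:
            raise ValueError(f"table entry {name} must be a non-negative integer, got {v}")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both row margins must be positive")
    k = a + c
    weights, x_lo, total = _hypergeom_weights(n1, n2, k)
    w_obs = weights[a - x_lo]
    numerator = sum(w for w in weights if w <= w_obs)
    return numerator / total


def bonferroni_adjust(pvals: Sequence[float], m: int | None = None) -> list[float]:
    """Bonferroni correction: p_adj = min(1, m * p), order preserved."""
    if m is None:
        m = len(pvals)
    if m < 1:
        raise ValueError("m must be at least 1")
    for p in pvals:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p} outside (0, 1]")
    return [min(1.0, m * p) for p in pvals]


def compare_groups(
    matrix: PavMatrix,
    groups: Mapping[str, str],
    config: ThresholdConfig = DEFAULT_CONFIG,
    group_names: tuple[str, str] = ("group1", "group2"),
) -> list[ContingencyResult]:
    """Per-NRS Fisher tests between two sample groups.

    Skeptical NRSs (population frequency 0) are excluded before testing and
    the Bonferroni factor is the number of NRSs actually tested.  A result
    is significant when its adjusted p-value falls below
    ``config.significance_adj_p``.
    """
    g1, g2 = group_names
    for sample in matrix.samples:
        if sample not in groups:
            raise PipelineError(f"sample '{sample}' has no group assignment")
        if groups[sample] not in (g1, g2):
            raise PipelineError(
                f"sample '{sample}' assigned to unknown group '{groups[sample]}'"
            )
    idx1 = [i for i, s in enumerate(matrix.samples) if groups[s] == g1]
    idx2 = [i for i, s in enumerate(matrix.samples) if groups[s] == g2]
    if not idx1 or not idx2:
        raise PipelineError("each group needs at least one sample")

    if matrix.category:
        tested = [
            (j, nid) for j, nid in enumerate(matrix.nrs_ids)
            if matrix.category[nid] != "skeptical"
        ]
    else:
        tested = list(enumerate(matrix.nrs_ids))

    raw: list[tuple[str, int, int, int, int, float]] = []
    for j, nid in tested:
        col = matrix.present[:, j]
        a = int(col[idx1].sum())
        c = int(col[idx2].sum())
        b, d = len(idx1) - a, len(idx2) - c
        raw.append((nid, a, b, c, d, fisher_exact_two_sided(a, b, c, d)))

    adjusted = bonferroni_adjust([r[5] for r in raw]) if raw else []
    results = []
    for (nid, a, b, c, d, p), p_adj in zip(raw, adjusted):
        f1, f2 = a / (a + b), c / (c + d)
        if f1 > f2:
            higher = g1
        elif f2 > f1:
            higher = g2
        else:
            higher = "tie"
        results.append(
            ContingencyResult(
                nrs_id=nid, a=a, b=b, c=c, d=d, p_raw=p, p_adj=p_adj,
                significant=p_adj < config.significance_adj_p, higher_in=higher,
            )
        )
    return results


def summarize_comparison(
    results: Sequence[ContingencyResult],
    group_names: tuple[str, str] = ("group1", "group2"),
) -> dict[str, int]:
    """Headline counts: significant NRSs with higher frequency per group."""
    g1, g2 = group_names
    sig = [r for r in results if r.significant]
    return {
        "n_tested": len(results),
        "n_significant": len(sig),
        f"higher_in_{g1}": sum(1 for r in sig if r.higher_in == g1),
        f"higher_in_{g2}": sum(1 for r in sig if r.higher_in == g2),
        "ties": sum(1 for r in sig if r.higher_in == "tie"),
    }


def genes_overlapping(results, records, annotation) -> list[str]:
    """Gene ids whose bodies contain any significant NRS anchor (sorted, unique)."""
    from .nrs import _feature_trees, _gff_db  # local import to avoid cycle

    sig_ids = {r.nrs_id for r in results if r.significant}
    trees = _feature_trees(_gff_db(annotation))
    genes: set[str] = set()
    for rec in records:
        if rec.id not in sig_ids:
            continue
        chrom, pos = rec.anchor
        gene_tree = trees.get(chrom, {}).get("gene")
        if gene_tree is not None:
            genes.update(iv.data for iv in gene_tree[pos])
    return sorted(genes)


def results_table(
    results: Sequence[ContingencyResult],
    records=None,
    gene_hits: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Flat TSV-ready table of contingency results."""
    anchors = {r.id: r.anchor for r in records} if records else {}
    rows = []
    for r in results:
        chrom, pos = anchors.get(r.nrs_id, ("", -1))
        rows.append(
            {
                "nrs_id": r.nrs_id,
                "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                "p_raw": r.p_raw,
                "p_adj": r.p_adj,
                "significant": r.significant,
                "higher_in": r.higher_in,
                "chrom": chrom,
                "pos_1based": pos + 1 if chrom else "",
                "overlapping_genes": ",".join((gene_hits or {}).get(r.nrs_id, [])),
            }
        )
    return pd.DataFrame(rows)
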