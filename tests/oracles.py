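"""Independent oracles used only by the test suite.

Each oracle recomputes a quantity by a route disjoint from the library
implementation: full Smith-Waterman dynamic programming (biotite's C
aligner) instead of seed-and-extend, exact rational hypergeometric
enumeration instead of integer-weight summation, and a per-base boolean
array instead of interval sweeping.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
from biotite.sequence import NucleotideSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal

_ALPH = NucleotideSequence.alphabet_unamb
# megablast-like scoring: match +1, mismatch -2, gap open -2, gap extend -1
_MATRIX = SubstitutionMatrix(
    _ALPH, _ALPH, np.where(np.eye(4, dtype=bool), 1, -2).astype(np.int32)
)
_GAP = (-2, -1)

_RC = str.maketrans("ACGTN", "TGCAN")


def _sw_one_strand(a: str, b: str) -> tuple[float, float]:
    seq_a, seq_b = NucleotideSequence(a), NucleotideSequence(b)
    alns = align_optimal(seq_a, seq_b, _MATRIX, gap_penalty=_GAP, local=True, max_number=1)
    trace = alns[0].trace
    if len(trace) == 0:
        return 0.0, 0.0
    codes_a, codes_b = np.asarray(seq_a.code), np.asarray(seq_b.code)
    aligned = (trace[:, 0] >= 0) & (trace[:, 1] >= 0)
    matches = int(np.sum(codes_a[trace[aligned, 0]] == codes_b[trace[aligned, 1]]))
    identity = matches / len(trace)
    shorter_col = 0 if len(a) <= len(b) else 1
    idx = trace[:, shorter_col]
    idx = idx[idx >= 0]
    coverage = (idx.max() - idx.min() + 1) / min(len(a), len(b))
    return identity, coverage


def sw_identity_coverage(a: str, b: str, both_strands: bool = True) -> tuple[float, float]:
    """Identity and shorter-sequence coverage of the optimal local alignment."""
    best = _sw_one_strand(a, b)
    if both_strands:
        rc = _sw_one_strand(a.translate(_RC)[::-1], b)
        if rc[0] * rc[1] > best[0] * best[1]:
            best = rc
    return best


def sw_redundant_partition(records, identity_thr=0.90, coverage_thr=0.90):
    """Greedy longest-first redundancy partition judged by full DP alignment."""
    ordered = sorted(records, key=lambda r: (-r.total_bp, r.id))
    retained, redundant = [], []
    for rec in ordered:
        dup = any(
            identity >= identity_thr and coverage >= coverage_thr
            for kept in retained
            for identity, coverage in [sw_identity_coverage(rec.sequence, kept.sequence)]
        )
        (redundant if dup else retained).append(rec)
    return {r.id for r in retained}, {r.id for r in redundant}


def fisher_two_sided_fraction(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p by rational enumeration of all tables."""
    n1, n2, k = a + b, c + d, a + c
    denom = comb(n1 + n2, k)
    p_obs = Fraction(comb(n1, a) * comb(n2, k - a), denom)
    total = Fraction(0)
    for x in range(max(0, k - n2), min(n1, k) + 1):
        p = Fraction(comb(n1, x) * comb(n2, k - x), denom)
        if p <= p_obs:
            total += p
    return float(total)


def fisher_distribution_fraction(n1: int, n2: int, k: int) -> list[tuple[int, float]]:
    """(a, two-sided p) for every table with row margins n1, n2 and k successes."""
    denom = comb(n1 + n2, k)
    support = range(max(0, k - n2), min(n1, k) + 1)
    pmf = {x: Fraction(comb(n1, x) * comb(n2, k - x), denom) for x in support}
    out = []
    for a in support:
        out.append((a, float(sum(p for p in pmf.values() if p <= pmf[a]))))
    return out


def breadth_boolean_oracle(intervals, length: int) -> float:
    """Coverage breadth by marking a per-base boolean array."""
    covered = np.zeros(length, dtype=bool)
    for start, end in intervals:
        covered[start:end] = True
    return covered.mean()
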