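"""Seed-and-extend pairwise screening used by the redundancy and
reference-alignment filters.

The filters only need two quantities per sequence pair: the identity of the
best local match (matches / alignment columns, gaps included) and the
coverage of that match measured on the shorter sequence.  Exact 15-mer
seeding finds candidate homologous regions; seeds on compatible diagonals
are clustered into a chain, and the chained windows are aligned end-to-end
with edlib to produce an exact unit-cost alignment path.  Sequence pairs
with no shared 15-mer — in particular unrelated random sequences — score
``(0.0, 0.0)`` without any alignment work.

This is a screening engine driven by thresholds, not a scoring-compatible
BLAST reimplementation; tests validate its accept/reject decisions against
a full Smith-Waterman oracle.
"""

from __future__ import annotations

import re
from collections import defaultdict

import edlib

from .sequence import revcomp, validate_dna

DEFAULT_K = 15
# Seeds within this many diagonals are considered part of one gapped match.
_DIAG_BAND = 32
# Window slack added around a seed chain before the final alignment.
_WINDOW_PAD = 30

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class KmerIndex:
    """Exact k-mer index over one target sequence (built once, queried often)."""

    def __init__(self, sequence: str, k: int = DEFAULT_K):
        self.sequence = sequence
        self.k = k
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(sequence) - k + 1):
            kmer = sequence[i : i + k]
            if "N" not in kmer:
                index[kmer].append(i)
        self._index = dict(index)

    def seeds(self, query: str) -> list[tuple[int, int]]:
        """(query_pos, target_pos) pairs of exact k-mer matches."""
        k = self.k
        out: list[tuple[int, int]] = []
        for q in range(len(query) - k + 1):
            hits = self._index.get(query[q : q + k])
            if hits:
                out.extend((q, t) for t in hits)
        return out


def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(matches, columns) from an edlib extended cigar."""
    matches = columns = 0
    for count_s, op in _CIGAR_RE.findall(cigar):
        count = int(count_s)
        columns += count
        if op == "=":
            matches += count
    return matches, columns


def _chain_windows(
    seeds: list[tuple[int, int]], k: int, qlen: int, tlen: int
) -> list[tuple[int, int, int, int]]:
    """Cluster seeds into diagonal bands and return candidate windows.

    Each window is (q_start, q_end, t_start, t_end), padded by
    ``_WINDOW_PAD`` and clipped to the sequence bounds.
    """
    by_band: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for q, t in seeds:
        by_band[(t - q) // _DIAG_BAND].append((q, t))
    # merge adjacent bands so a chain crossing a band boundary stays whole
    bands = sorted(by_band)
    merged: list[list[tuple[int, int]]] = []
    prev_band = None
    for band in bands:
        if prev_band is not None and band == prev_band + 1:
            merged[-1].extend(by_band[band])
        else:
            merged.append(list(by_band[band]))
        prev_band = band
    windows = []
    for cluster in merged:
        q_lo = min(q for q, _ in cluster)
        q_hi = max(q for q, _ in cluster) + k
        t_lo = min(t for _, t in cluster)
        t_hi = max(t for _, t in cluster) + k
        windows.append(
            (
                max(0, q_lo - _WINDOW_PAD),
                min(qlen, q_hi + _WINDOW_PAD),
                max(0, t_lo - _WINDOW_PAD),
                min(tlen, t_hi + _WINDOW_PAD),
            )
        )
    return windows


def _best_window_alignment(query: str, target: str, index: KmerIndex) -> tuple[float, float]:
    seeds = index.seeds(query)
    if not seeds:
        return 0.0, 0.0
    best = (0.0, 0.0)
    best_key = -1.0
    for q_lo, q_hi, t_lo, t_hi in _chain_windows(seeds, index.k, len(query), len(target)):
        res = edlib.align(query[q_lo:q_hi], target[t_lo:t_hi], task="path", mode="HW")
        if res["cigar"] is None:  # pragma: no cover - edlib always returns a path here
            continue
        matches, columns = _cigar_stats(res["cigar"])
        if columns == 0:
            continue
        identity = matches / columns
        coverage = (q_hi - q_lo) / len(query)
        key = identity * coverage
        if key > best_key:
            best_key = key
            best = (identity, coverage)
    return best


def align_pair(
    a: str,
    b: str,
    k: int = DEFAULT_K,
    both_strands: bool = True,
    index: KmerIndex | None = None,
) -> tuple[float, float]:
    """Best local-match (identity, coverage) between two DNA sequences.

    Coverage is measured on the shorter sequence (``a`` on ties).  With
    ``both_strands`` the reverse complement of the query is also tried and
    the better strand reported.  ``(0.0, 0.0)`` means no shared seed.

    An optional prebuilt :class:`KmerIndex` over the *longer* sequence lets
    callers amortize indexing across many queries (the reference-alignment
    screen indexes each chromosome once).
    """
    if not a or not b:
        raise ValueError("align_pair requires two non-empty sequences")
    a = validate_dna(a)
    b = validate_dna(b)
    if len(a) <= len(b):
        query, target = a, b
    else:
        query, target = b, a
    if index is None:
        index = KmerIndex(target, k=k)
    elif index.sequence != target:
        raise ValueError("prebuilt index does not match the longer sequence")
    best = _best_window_alignment(query, target, index)
    if both_strands:
        rc = _best_window_alignment(revcomp(query), target, index)
        if rc[0] * rc[1] > best[0] * best[1]:
            best = rc
    return best
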