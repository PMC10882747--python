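"""Presence/absence variation (PAV): coverage breadth, presence calls,
frequency categories and PCA of the PAV matrix.

A sample carries an NRS when alignment intervals cover more than 70% of the
NRS body (flanks excluded).  Column frequencies over all samples place each
NRS into core (> 99%), softcore (90-99%), shell (1% to < 90%), cloud
(< 1%) or skeptical (absent from every sample); skeptical NRSs are dropped
before any downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ThresholdConfig
from .exceptions import PipelineError

CATEGORIES = ("core", "softcore", "shell", "cloud", "skeptical")


@dataclass
class CoverageProfile:
    """Alignment intervals over one NRS body for one sample.

    Intervals are 0-based half-open over the NRS body; flank alignments
    must already be trimmed away.
    """

    nrs_id: str
    intervals: list[tuple[int, int]]
    nrs_len: int

    def __post_init__(self) -> None:
        if self.nrs_len <= 0:
            raise ValueError(f"{self.nrs_id}: non-positive NRS length")
        for start, end in self.intervals:
            if not (0 <= start < end <= self.nrs_len):
                raise PipelineError(
                    f"{self.nrs_id}: interval [{start}, {end}) out of bounds for "
                    f"length {self.nrs_len}"
                )


@dataclass
class PavMatrix:
    """Samples x NRS presence booleans with per-NRS frequency and category."""

    samples: list[str]
    nrs_ids: list[str]
    present: np.ndarray  # bool, shape (n_samples, n_nrs)
    freq: dict[str, float] = field(default_factory=dict)
    category: dict[str, str] = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.present.astype(int), index=self.samples, columns=self.nrs_ids
        )


def coverage_breadth(profile: CoverageProfile) -> float:
    """Fraction of the NRS body covered by the union of intervals."""
    if not profile.intervals:
        return 0.0
    covered = 0
    cur_start, cur_end = None, None
    for start, end in sorted(profile.intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    covered += cur_end - cur_start
    return covered / profile.nrs_len


def build_profiles(
    intervals: pd.DataFrame,
    nrs_lengths: dict[str, int],
    samples: list[str],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> dict[str, dict[str, CoverageProfile]]:
    """Materialize per-(sample, NRS) coverage profiles from an interval table.

    ``intervals`` columns: sample, nrs_id, start, end, mapq.  Records below
    ``config.min_mapq`` are discarded.  Every (sample, NRS) pair in the
    cross product gets a profile, possibly empty.
    """
    profiles: dict[str, dict[str, CoverageProfile]] = {
        sample: {
            nid: CoverageProfile(nrs_id=nid, intervals=[], nrs_len=length)
            for nid, length in nrs_lengths.items()
        }
        for sample in samples
    }
    kept = intervals[intervals["mapq"] >= config.min_mapq]
    for row in kept.itertuples(index=False):
        if row.sample not in profiles or row.nrs_id not in nrs_lengths:
            continue
        profiles[row.sample][row.nrs_id].intervals.append((int(row.start), int(row.end)))
    # re-validate bounds after appending
    for per_sample in profiles.values():
        for profile in per_sample.values():
            CoverageProfile(profile.nrs_id, profile.intervals, profile.nrs_len)
    return profiles


def call_presence(
    profiles: dict[str, dict[str, CoverageProfile]],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> PavMatrix:
    """Presence calls: breadth strictly above ``presence_breadth``.

    ``profiles`` maps sample -> nrs_id -> profile; every sample must carry
    a profile for every NRS (possibly empty), and the NRS universe must
    agree across samples.  A flat iterable of (sample, profile) pairs is
    also accepted; a duplicate (sample, nrs_id) pair is an error.
    """
    if not isinstance(profiles, dict):
        nested: dict[str, dict[str, CoverageProfile]] = {}
        for sample, profile in profiles:
            per_sample = nested.setdefault(sample, {})
            if profile.nrs_id in per_sample:
                raise PipelineError(
                    f"duplicate profile for sample '{sample}', NRS '{profile.nrs_id}'"
                )
            per_sample[profile.nrs_id] = profile
        profiles = nested
    samples = list(profiles)
    if not samples:
        raise PipelineError("no samples")
    nrs_ids = list(profiles[samples[0]])
    id_set = set(nrs_ids)
    for sample in samples:
        if set(profiles[sample]) != id_set:
            raise PipelineError(f"sample '{sample}' profile universe mismatch")
    present = np.zeros((len(samples), len(nrs_ids)), dtype=bool)
    for i, sample in enumerate(samples):
        for j, nid in enumerate(nrs_ids):
            present[i, j] = coverage_breadth(profiles[sample][nid]) > config.presence_breadth
    return PavMatrix(samples=samples, nrs_ids=nrs_ids, present=present)


def classify_frequencies(
    matrix: PavMatrix, config: ThresholdConfig = DEFAULT_CONFIG
) -> PavMatrix:
    """Fill per-NRS frequency and category (in place; also returned).

    Boundaries: f > 0.99 core; 0.90 <= f <= 0.99 softcore; 0.01 <= f < 0.90
    shell; 0 < f < 0.01 cloud; f == 0 skeptical.  This resolves the
    overlapping published ranges into a true partition.
    """
    freqs = matrix.present.mean(axis=0)
    for nid, f in zip(matrix.nrs_ids, freqs):
        matrix.freq[nid] = float(f)
        if f == 0:
            cat = "skeptical"
        elif f > config.core_freq:
            cat = "core"
        elif f >= config.softcore_freq:
            cat = "softcore"
        elif f >= config.cloud_freq:
            cat = "shell"
        else:
            cat = "cloud"
        matrix.category[nid] = cat
    return matrix


def category_counts(matrix: PavMatrix) -> dict[str, int]:
    counts = {cat: 0 for cat in CATEGORIES}
    for cat in matrix.category.values():
        counts[cat] += 1
    return counts


def non_skeptical_total(counts: dict[str, int]) -> int:
    """Size of the downstream analysis set: every category except skeptical.

    The five categories partition the NRS set, so this equals the sum of
    core + softcore + shell + cloud.
    """
    for cat, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for category '{cat}'")
    return sum(n for cat, n in counts.items() if cat != "skeptical")


def pav_pca(matrix: PavMatrix, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the PAV matrix by eigendecomposition of the sample covariance.

    Skeptical NRS columns (frequency 0) are dropped; remaining columns are
    mean-centered but not scaled (booleans share a scale).  Returns
    (scores, eigenvalues): scores has shape (n_samples, n_components) and
    eigenvalues (length min(n_samples - 1, n_nrs), non-increasing) sum to
    the total column variance.
    """
    n = len(matrix.samples)
    if n < 2:
        raise PipelineError("PCA requires at least 2 samples")
    if matrix.category:
        keep = [j for j, nid in enumerate(matrix.nrs_ids) if matrix.category[nid] != "skeptical"]
    else:
        keep = list(range(len(matrix.nrs_ids)))
    x = matrix.present[:, keep].astype(float)
    max_comp = min(n - 1, x.shape[1])
    if n_components > max_comp or n_components < 1:
        raise ValueError(f"n_components must lie in [1, {max_comp}], got {n_components}")
    xc = x - x.mean(axis=0)
    gram = xc @ xc.T / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(gram)
    order = np.argsort(eigvals)[::-1][:max_comp]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    scores = eigvecs * np.sqrt(eigvals * (n - 1))
    return scores[:, :n_components], eigvals
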