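"""Numeric thresholds that drive every filtering decision in the pipeline.

All thresholds are collected in one frozen dataclass so a run's stringency
is a single auditable object.  Defaults follow the discovery protocol the
pipeline implements: a retained non-reference sequence (NRS) must be longer
than 500 bp with more than half its bases from non-reference nodes;
redundancy and reference-likeness are judged at 90% identity / 90% coverage;
a sample carries an NRS when alignments cover more than 70% of its body.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds for NRS retention, PAV calling and group testing.

    Attributes
    ----------
    min_nrs_bp:
        Minimum NRS length, exclusive ("greater than 500 bp").
    min_nrn_fraction:
        Minimum fraction of NRS bases contributed by non-reference nodes,
        exclusive ("over 50%").
    redundancy_identity, redundancy_coverage:
        Inclusive thresholds for collapsing near-duplicate NRSs; coverage is
        measured on the shorter sequence of the pair.
    reference_like_identity, reference_like_coverage:
        Inclusive thresholds for discarding NRSs that align back to the
        linear reference; coverage is measured on the NRS.
    flank_bp:
        Reference flank appended to each side of an NRS when exporting
        mapping targets.
    presence_breadth:
        Coverage breadth above which an NRS is called present in a sample,
        exclusive ("more than 70%").
    core_freq, softcore_freq, cloud_freq:
        Population-frequency boundaries of the core / softcore / shell /
        cloud categories.
    significance_adj_p:
        Bonferroni-adjusted p-value below which a group-frequency contrast
        is significant.
    min_mapq:
        Alignment records below this mapping quality are discarded before
        coverage profiles are built.
    """

    min_nrs_bp: int = 500
    min_nrn_fraction: float = 0.5
    redundancy_identity: float = 0.90
    redundancy_coverage: float = 0.90
    reference_like_identity: float = 0.90
    reference_like_coverage: float = 0.90
    flank_bp: int = 100
    presence_breadth: float = 0.70
    core_freq: float = 0.99
    softcore_freq: float = 0.90
    cloud_freq: float = 0.01
    significance_adj_p: float = 0.01
    min_mapq: int = 10

    def __post_init__(self) -> None:
        fractions = {
            "min_nrn_fraction": self.min_nrn_fraction,
            "redundancy_identity": self.redundancy_identity,
            "redundancy_coverage": self.redundancy_coverage,
            "reference_like_identity": self.reference_like_identity,
            "reference_like_coverage": self.reference_like_coverage,
            "presence_breadth": self.presence_breadth,
            "core_freq": self.core_freq,
            "softcore_freq": self.softcore_freq,
            "cloud_freq": self.cloud_freq,
            "significance_adj_p": self.significance_adj_p,
        }
        for name, value in fractions.items():
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {value}")
        if not self.cloud_freq < self.softcore_freq < self.core_freq:
            raise ValueError(
                "frequency boundaries must satisfy "
                "cloud_freq < softcore_freq < core_freq"
            )
        for name, value in (
            ("min_nrs_bp", self.min_nrs_bp),
            ("flank_bp", self.flank_bp),
        ):
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if int(self.min_mapq) != self.min_mapq or self.min_mapq < 0:
            raise ValueError(f"min_mapq must be a non-negative integer, got {self.min_mapq}")


DEFAULT_CONFIG = ThresholdConfig()
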