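"""Non-reference sequence (NRS) extraction, filtering and annotation.

An NRS candidate is a walk bubble whose oriented node path differs from the
backbone's path over the same reference interval.  Candidates survive when
they (1) are supported by at least one assembly, (2) contain at least one
non-reference node (NRN), (3) are longer than ``min_nrs_bp`` and (4) draw
more than ``min_nrn_fraction`` of their bases from NRNs.  The surviving set
is then pruned of near-duplicates (greedy, longest kept) and of sequences
that align back to the linear reference, and finally classified as complete
(cNRS: no reference node in the path) or partial (pNRS) and anchored at the
left breakpoint of their bubble's reference interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from .align import KmerIndex, align_pair
from .config import DEFAULT_CONFIG, ThresholdConfig
from .exceptions import FormatError, PipelineError
from .graphio import GraphTopology
from .labeling import NON_REFERENCE, REFERENCE, SKEPTICAL, NodeLabeling
from .sequence import revcomp

logger = logging.getLogger(__name__)

RAW = "raw"
REDUNDANT = "redundant"
REFERENCE_LIKE = "reference_like"
CNRS = "cNRS"
PNRS = "pNRS"

GENOMIC_CONTEXTS = ("CDS", "five_prime_UTR", "three_prime_UTR", "intron", "intergenic")


@dataclass
class NrsRecord:
    """One candidate or retained non-reference sequence."""

    id: str
    node_path: tuple[tuple[str, str], ...]  # (segment_id, orient), anchors excluded
    sequence: str
    total_bp: int
    nrn_bp: int
    supporters: frozenset[str]
    klass: str
    anchor: tuple[str, int]  # (chrom, 0-based insertion breakpoint)
    source_interval: tuple[int, int]  # reference interval of the bubble

    @property
    def nrn_fraction(self) -> float:
        return self.nrn_bp / self.total_bp if self.total_bp else 0.0

    @property
    def anchor_pos_1based(self) -> int:
        return self.anchor[1] + 1


def passes_criteria(
    total_bp: int, nrn_bp: int, n_nrn_nodes: int, n_supporters: int,
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> bool:
    """The four retention criteria (all strict inequalities)."""
    return (
        n_supporters >= 1
        and n_nrn_nodes >= 1
        and total_bp > config.min_nrs_bp
        and total_bp > 0
        and nrn_bp / total_bp > config.min_nrn_fraction
    )


def _backbone_path_over(
    backbone_segments: dict[str, list], chrom: str, start: int, end: int
) -> tuple[tuple[str, str], ...] | None:
    """Oriented backbone segment ids fully inside [start, end) on ``chrom``."""
    if chrom not in backbone_segments:
        return None
    segs = backbone_segments[chrom]
    path = tuple(
        (seg.id, "+") for seg in segs if seg.offset >= start and seg.offset + seg.length <= end
    )
    return path


def extract_candidates(
    topology: GraphTopology,
    labeling: NodeLabeling,
    config: ThresholdConfig = DEFAULT_CONFIG,
    backbone_name: str = "ref",
) -> list[NrsRecord]:
    """Extract raw NRS records from walk deviations against the backbone.

    Candidates identical in (chrom, source interval, node path) across
    assemblies are merged, accumulating supporters.  Bubbles containing a
    skeptical node are excluded from consideration.  Only candidates
    passing all four retention criteria are returned (klass ``raw``), in
    deterministic (chrom, interval, path) order with sequential ids.
    """
    if backbone_name not in topology.walks:
        raise PipelineError(f"backbone assembly '{backbone_name}' has no walk")
    backbone_segments: dict[str, list] = {}
    for step in topology.walks[backbone_name]:
        seg = topology.segments[step.segment_id]
        backbone_segments.setdefault(seg.chrom, []).append(seg)
    for segs in backbone_segments.values():
        segs.sort(key=lambda s: s.offset)

    merged: dict[tuple, dict] = {}
    for assembly, _ in topology.walks.items():
        if assembly == backbone_name:
            continue
        for chrom, start, end, steps in topology.walk_bubbles(assembly):
            path = tuple((s.segment_id, s.orient) for s in steps)
            ref_path = _backbone_path_over(backbone_segments, chrom, start, end)
            if ref_path is None:
                raise PipelineError(
                    f"bubble {chrom}:{start}-{end} of '{assembly}' has no backbone counterpart"
                )
            if path == ref_path:
                continue
            if any(labeling.label[sid] == SKEPTICAL for sid, _ in path):
                logger.debug(
                    "skipping bubble %s:%d-%d of %s: contains skeptical node",
                    chrom, start, end, assembly,
                )
                continue
            key = (chrom, start, end, path)
            entry = merged.setdefault(key, {"supporters": set()})
            entry["supporters"].add(assembly)

    records: list[NrsRecord] = []
    for (chrom, start, end, path) in sorted(merged, key=lambda k: (k[0], k[1], k[2], k[3])):
        supporters = merged[(chrom, start, end, path)]["supporters"]
        seq_parts = []
        nrn_bp = 0
        n_nrn = 0
        for sid, orient in path:
            seg = topology.segments[sid]
            seq_parts.append(seg.sequence if orient == "+" else revcomp(seg.sequence))
            if labeling.label[sid] == NON_REFERENCE:
                nrn_bp += seg.length
                n_nrn += 1
        sequence = "".join(seq_parts)
        if not passes_criteria(len(sequence), nrn_bp, n_nrn, len(supporters), config):
            continue
        records.append(
            NrsRecord(
                id=f"nrs_{len(records) + 1:05d}",
                node_path=path,
                sequence=sequence,
                total_bp=len(sequence),
                nrn_bp=nrn_bp,
                supporters=frozenset(supporters),
                klass=RAW,
                anchor=(chrom, start),
                source_interval=(start, end),
            )
        )
    return records


def remove_redundant(
    records: Sequence[NrsRecord],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> tuple[list[NrsRecord], list[NrsRecord]]:
    """Greedy redundancy sweep in descending length (ties by id).

    A record is redundant when it matches an already-retained record at
    identity >= ``redundancy_identity`` and coverage (of the shorter
    sequence) >= ``redundancy_coverage``.  Returns (retained, redundant);
    the two lists partition the input.
    """
    ordered = sorted(records, key=lambda r: (-r.total_bp, r.id))
    retained: list[NrsRecord] = []
    redundant: list[NrsRecord] = []
    indexes: dict[str, KmerIndex] = {}
    for rec in ordered:
        is_dup = False
        for kept in retained:
            # rec is never longer than kept (sweep order), so kept is the target
            index = indexes.setdefault(kept.id, KmerIndex(kept.sequence))
            identity, coverage = align_pair(rec.sequence, kept.sequence, index=index)
            if identity >= config.redundancy_identity and coverage >= config.redundancy_coverage:
                is_dup = True
                break
        if is_dup:
            redundant.append(replace(rec, klass=REDUNDANT))
        else:
            retained.append(rec)
    return retained, redundant


def filter_reference_like(
    records: Sequence[NrsRecord],
    reference: dict[str, str],
    config: ThresholdConfig = DEFAULT_CONFIG,
) -> tuple[list[NrsRecord], list[NrsRecord]]:
    """Screen records against the linear reference.

    A record is reference-like when it aligns to any reference chromosome
    at identity >= ``reference_like_identity`` with coverage (of the NRS)
    >= ``reference_like_coverage``.  Returns (retained, reference_like).
    """
    if not reference:
        raise PipelineError("empty reference")
    chrom_indexes = {name: KmerIndex(seq) for name, seq in reference.items()}
    retained: list[NrsRecord] = []
    ref_like: list[NrsRecord] = []
    for rec in records:
        hit = False
        for name, seq in reference.items():
            if len(rec.sequence) > len(seq):
                identity, coverage = align_pair(rec.sequence, seq)
            else:
                identity, coverage = align_pair(rec.sequence, seq, index=chrom_indexes[name])
            if (
                identity >= config.reference_like_identity
                and coverage >= config.reference_like_coverage
            ):
                hit = True
                break
        if hit:
            ref_like.append(replace(rec, klass=REFERENCE_LIKE))
        else:
            retained.append(rec)
    return retained, ref_like


def classify_and_anchor(
    records: Sequence[NrsRecord],
    topology: GraphTopology,
    labeling: NodeLabeling,
) -> list[NrsRecord]:
    """Assign cNRS/pNRS class; the anchor is the bubble's left breakpoint.

    A record is a complete NRS (cNRS) iff its node path contains no
    reference-labeled segment; otherwise it is a partial NRS (pNRS).
    """
    out: list[NrsRecord] = []
    for rec in records:
        if rec.source_interval is None or rec.anchor[0] is None:
            raise PipelineError(f"record {rec.id} has no resolvable source interval")
        has_ref = any(labeling.label[sid] == REFERENCE for sid, _ in rec.node_path)
        klass = PNRS if has_ref else CNRS
        out.append(replace(rec, klass=klass, anchor=(rec.anchor[0], rec.source_interval[0])))
    return out


def funnel_retained(n_raw: int, n_redundant: int, n_reference_like: int) -> int:
    """Count conservation over the filtering funnel.

    The raw candidate set is partitioned into redundant, reference-like and
    retained records, so retained = raw - redundant - reference_like.
    """
    for name, n in (("raw", n_raw), ("redundant", n_redundant), ("reference_like", n_reference_like)):
        if n < 0:
            raise ValueError(f"negative {name} count")
    retained = n_raw - n_redundant - n_reference_like
    if retained < 0:
        raise ValueError("removed counts exceed the raw count")
    return retained


# ---------------------------------------------------------------------------
# annotation


def _gff_db(annotation: str | Path | gffutils.FeatureDB) -> gffutils.FeatureDB:
    if isinstance(annotation, gffutils.FeatureDB):
        return annotation
    try:
        return gffutils.create_db(
            str(annotation), ":memory:", merge_strategy="create_unique", keep_order=True
        )
    except Exception as exc:
        raise FormatError(f"malformed GFF3 '{annotation}': {exc}") from exc


def _feature_trees(db: gffutils.FeatureDB) -> dict[str, dict[str, IntervalTree]]:
    trees: dict[str, dict[str, IntervalTree]] = {}
    wanted = {
        "CDS": "CDS",
        "five_prime_UTR": "five_prime_UTR",
        "three_prime_UTR": "three_prime_UTR",
        "gene": "gene",
    }
    for ftype, key in wanted.items():
        for feat in db.features_of_type(ftype):
            tree = trees.setdefault(feat.seqid, {}).setdefault(key, IntervalTree())
            # GFF is 1-based inclusive; convert to 0-based half-open
            tree[feat.start - 1 : feat.end] = feat.id
    return trees


def annotate_context(
    records: Sequence[NrsRecord],
    annotation: str | Path | gffutils.FeatureDB,
) -> dict[str, str]:
    """Classify each record's anchor breakpoint against gene annotation.

    Priority: CDS > UTR > intron (inside a gene body with no CDS/UTR hit)
    > intergenic.
    """
    db = _gff_db(annotation)
    trees = _feature_trees(db)
    out: dict[str, str] = {}
    for rec in records:
        chrom, pos = rec.anchor
        chrom_trees = trees.get(chrom, {})

        def hit(key: str) -> bool:
            tree = chrom_trees.get(key)
            return bool(tree is not None and tree[pos])

        if hit("CDS"):
            out[rec.id] = "CDS"
        elif hit("five_prime_UTR"):
            out[rec.id] = "five_prime_UTR"
        elif hit("three_prime_UTR"):
            out[rec.id] = "three_prime_UTR"
        elif hit("gene"):
            out[rec.id] = "intron"
        else:
            out[rec.id] = "intergenic"
    return out


def interval_density(
    records: Sequence[NrsRecord],
    interval: tuple[str, int, int],
    span_decimals: int | None = None,
) -> tuple[int, float, float]:
    """NRS anchors per megabase inside a half-open genomic interval.

    Returns (count, density in NRS/Mb, span_mb).  ``span_decimals`` rounds
    the reported span (1 decimal echoes headline-style figures, 2 decimals
    is the default report precision); density uses the rounded span when
    rounding is requested.
    """
    chrom, start, end = interval
    if end <= start:
        raise ValueError(f"invalid interval [{start}, {end}): end must exceed start")
    count = sum(1 for rec in records if rec.anchor[0] == chrom and start <= rec.anchor[1] < end)
    span_mb = (end - start) / 1e6
    if span_decimals is not None:
        span_mb = round(span_mb, span_decimals)
    density = count / span_mb if span_mb else 0.0
    return count, density, span_mb


def records_table(
    records: Sequence[NrsRecord], contexts: dict[str, str] | None = None
) -> pd.DataFrame:
    """Flat TSV-ready table of NRS records."""
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.id,
                "chrom": rec.anchor[0],
                "pos_1based": rec.anchor_pos_1based,
                "total_bp": rec.total_bp,
                "nrn_bp": rec.nrn_bp,
                "klass": rec.klass,
                "supporters": ",".join(sorted(rec.supporters)),
                "context": (contexts or {}).get(rec.id, ""),
            }
        )
    return pd.DataFrame(rows)
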