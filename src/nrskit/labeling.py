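"""Node labeling: reference vs non-reference vs skeptical.

Segments start with a rank-derived label (rank 0 = reference, rank > 0 =
non-reference).  The labels are then validated against the per-assembly
walks: a node visited by no walk at all, a rank-0 node the backbone walk
never visits, or a rank>0 node the backbone walk does visit, is demoted to
*skeptical* and excluded from all downstream analysis.  The surviving
non-reference nodes form the NRN set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .exceptions import PipelineError
from .graphio import GraphTopology

REFERENCE = "reference"
NON_REFERENCE = "non_reference"
SKEPTICAL = "skeptical"


@dataclass
class NodeLabeling:
    """Per-segment label partition plus the derived NRN set."""

    label: dict[str, str]
    nrn_ids: set[str] = field(default_factory=set)
    nrn_total_bp: int = 0


def label_nodes(
    topology: GraphTopology,
    backbone_name: str,
    strict_backbone_consistency: bool = True,
) -> NodeLabeling:
    """Label every segment and flag skeptical nodes.

    Parameters
    ----------
    topology:
        Graph with walks attached (the backbone walk must be present).
    backbone_name:
        Name of the backbone assembly's walk.
    strict_backbone_consistency:
        When True (default), a rank>0 node visited by the backbone walk is
        flagged skeptical; when False, such a node keeps its rank-derived
        label and only backbone-absent rank-0 nodes are demoted.
    """
    if backbone_name not in topology.walks:
        raise PipelineError(f"backbone assembly '{backbone_name}' has no walk")
    visitors: dict[str, set[str]] = {seg_id: set() for seg_id in topology.segments}
    for assembly, steps in topology.walks.items():
        for step in steps:
            visitors[step.segment_id].add(assembly)

    labels: dict[str, str] = {}
    for seg_id, seg in topology.segments.items():
        label = REFERENCE if seg.rank == 0 else NON_REFERENCE
        seen_by = visitors[seg_id]
        on_backbone = backbone_name in seen_by
        if not seen_by:
            label = SKEPTICAL
        elif seg.rank == 0 and not on_backbone:
            label = SKEPTICAL
        elif seg.rank > 0 and on_backbone and strict_backbone_consistency:
            label = SKEPTICAL
        labels[seg_id] = label

    nrn_ids = {sid for sid, lab in labels.items() if lab == NON_REFERENCE}
    nrn_total_bp = sum(topology.segments[sid].length for sid in nrn_ids)
    return NodeLabeling(label=labels, nrn_ids=nrn_ids, nrn_total_bp=nrn_total_bp)


def labeling_summary(
    labeling: NodeLabeling,
    topology: GraphTopology,
    backbone_name: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-assembly NRN load and the NRN sharing spectrum.

    Returns a dataframe (assembly, nrn_count, nrn_bp) over non-backbone
    assemblies, and a series indexed by k = 1..n giving the number of NRNs
    visited by exactly k of those assemblies.
    """
    assemblies = [a for a in topology.walks if a != backbone_name]
    visited: dict[str, set[str]] = {a: set() for a in assemblies}
    for assembly in assemblies:
        for step in topology.walks[assembly]:
            if step.segment_id in labeling.nrn_ids:
                visited[assembly].add(step.segment_id)
    rows = [
        {
            "assembly": a,
            "nrn_count": len(visited[a]),
            "nrn_bp": sum(topology.segments[s].length for s in visited[a]),
        }
        for a in assemblies
    ]
    sharing_counts: dict[str, int] = {}
    for a in assemblies:
        for seg in visited[a]:
            sharing_counts[seg] = sharing_counts.get(seg, 0) + 1
    spectrum = pd.Series(
        {k: sum(1 for v in sharing_counts.values() if v == k) for k in range(1, len(assemblies) + 1)},
        name="nrn_count",
        dtype=int,
    )
    spectrum.index.name = "n_assemblies"
    return pd.DataFrame(rows), spectrum


def write_label_report(
    labeling: NodeLabeling, topology: GraphTopology, path: str | Path
) -> None:
    """TSV report: segment_id, length, rank, label, n_assemblies_visiting."""
    visitors: dict[str, int] = {sid: 0 for sid in topology.segments}
    for steps in topology.walks.values():
        for sid in {step.segment_id for step in steps}:
            visitors[sid] += 1
    rows = [
        {
            "segment_id": sid,
            "length": seg.length,
            "rank": seg.rank,
            "label": labeling.label[sid],
            "n_assemblies_visiting": visitors[sid],
        }
        for sid, seg in topology.segments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
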