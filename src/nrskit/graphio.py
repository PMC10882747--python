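"""On-disk formats: rGFA graphs, per-assembly walk files, FASTA export.

The graph substrate is rGFA: GFA1 ``S``/``L`` records where every segment
carries the origin tags ``SN`` (source sequence name), ``SO`` (0-based source
offset) and ``SR`` (rank; 0 marks the reference backbone).  Per-assembly
bubble calls arrive in a small TSV dialect (one row per bubble)::

    assembly  chrom  ref_start  ref_end  seg1+,seg2-,...

with 0-based half-open reference coordinates and ``.`` for a deletion walk
(zero steps over the interval).  All internal coordinates are 0-based
half-open; 1-based positions appear only in FASTA headers and reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import RgfaFormatError, WalkFormatError
from .sequence import validate_dna

logger = logging.getLogger(__name__)

_ORIENTS = ("+", "-")


@dataclass(frozen=True)
class SegmentRecord:
    """One rGFA segment (graph node)."""

    id: str
    sequence: str
    chrom: str
    offset: int
    rank: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class WalkStep:
    """One oriented segment visit inside a bubble of an assembly's walk.

    ``chrom``/``ref_start``/``ref_end`` give the reference interval the
    bubble replaces; every step of a bubble shares them.
    """

    segment_id: str
    orient: str
    chrom: str
    ref_start: int
    ref_end: int


@dataclass
class GraphTopology:
    """Segments, links and named per-assembly walks of a pangenome graph."""

    segments: dict[str, SegmentRecord] = field(default_factory=dict)
    links: set[tuple[str, str, str, str]] = field(default_factory=set)
    walks: dict[str, list[WalkStep]] = field(default_factory=dict)

    def total_bp(self) -> int:
        return sum(s.length for s in self.segments.values())

    def backbone_bp(self) -> int:
        return sum(s.length for s in self.segments.values() if s.rank == 0)

    def walk_bubbles(self, assembly: str) -> list[tuple[str, int, int, list[WalkStep]]]:
        """Group an assembly's walk into bubbles.

        Consecutive steps sharing (chrom, ref_start, ref_end) form one
        bubble; returns them in walk order.
        """
        bubbles: list[tuple[str, int, int, list[WalkStep]]] = []
        for step in self.walks[assembly]:
            key = (step.chrom, step.ref_start, step.ref_end)
            if bubbles and (bubbles[-1][0], bubbles[-1][1], bubbles[-1][2]) == key:
                bubbles[-1][3].append(step)
            else:
                bubbles.append((step.chrom, step.ref_start, step.ref_end, [step]))
        return bubbles


def _parse_tags(fields: Sequence[str]) -> dict[str, str]:
    tags = {}
    for raw in fields:
        parts = raw.split(":", 2)
        if len(parts) == 3:
            tags[parts[0]] = parts[2]
    return tags


def parse_rgfa(path: str | Path) -> GraphTopology:
    """Parse an rGFA file into a :class:`GraphTopology` (walks left empty).

    Raises
    ------
    RgfaFormatError
        On a missing SN/SO/SR tag (naming the line number), a duplicate
        segment id, or a link referencing an unknown segment.
    """
    topo = GraphTopology()
    path = Path(path)
    pending_links: list[tuple[int, tuple[str, str, str, str]]] = []
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            if kind == "S":
                if len(fields) < 3:
                    raise RgfaFormatError(f"{path}:{lineno}: S line with fewer than 3 fields")
                seg_id, seq = fields[1], fields[2]
                tags = _parse_tags(fields[3:])
                for tag in ("SN", "SO", "SR"):
                    if tag not in tags:
                        raise RgfaFormatError(
                            f"{path}:{lineno}: S line for segment '{seg_id}' lacks {tag} tag"
                        )
                if seg_id in topo.segments:
                    raise RgfaFormatError(f"{path}:{lineno}: duplicate segment id '{seg_id}'")
                seq = validate_dna(seq, context=f"{path}:{lineno}")
                offset, rank = int(tags["SO"]), int(tags["SR"])
                if offset < 0 or rank < 0:
                    raise RgfaFormatError(f"{path}:{lineno}: negative SO or SR tag")
                topo.segments[seg_id] = SegmentRecord(
                    id=seg_id, sequence=seq, chrom=tags["SN"], offset=offset, rank=rank
                )
            elif kind == "L":
                if len(fields) < 5:
                    raise RgfaFormatError(f"{path}:{lineno}: L line with fewer than 5 fields")
                frm, fo, to, too = fields[1], fields[2], fields[3], fields[4]
                if fo not in _ORIENTS or too not in _ORIENTS:
                    raise RgfaFormatError(f"{path}:{lineno}: bad orientation in L line")
                pending_links.append((lineno, (frm, fo, to, too)))
            else:
                logger.warning("%s:%d: ignoring unknown rGFA record type '%s'", path, lineno, kind)
    for lineno, link in pending_links:
        for endpoint in (link[0], link[2]):
            if endpoint not in topo.segments:
                raise RgfaFormatError(
                    f"{path}:{lineno}: L line references unknown segment '{endpoint}'"
                )
        topo.links.add(link)
    return topo


def write_rgfa(topology: GraphTopology, path: str | Path, header_comment: str | None = None) -> None:
    """Write segments and links back to rGFA (S lines first, then L lines)."""
    path = Path(path)
    with path.open("w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        for seg in topology.segments.values():
            handle.write(
                f"S\t{seg.id}\t{seg.sequence}\t"
                f"SN:Z:{seg.chrom}\tSO:i:{seg.offset}\tSR:i:{seg.rank}\n"
            )
        for frm, fo, to, too in sorted(topology.links):
            handle.write(f"L\t{frm}\t{fo}\t{to}\t{too}\t0M\n")


def parse_walks(path: str | Path, topology: GraphTopology) -> GraphTopology:
    """Attach per-assembly walks from a walk TSV to ``topology`` (in place).

    Each row is one bubble; rows are kept in file order per assembly.  A
    ``.`` segment list denotes a deletion walk and contributes zero steps.
    """
    path = Path(path)
    n_rows = 0
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise WalkFormatError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            assembly, chrom, start_s, end_s, seg_list = fields
            try:
                ref_start, ref_end = int(start_s), int(end_s)
            except ValueError as exc:
                raise WalkFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if ref_start > ref_end or ref_start < 0:
                raise WalkFormatError(
                    f"{path}:{lineno}: invalid interval [{ref_start}, {ref_end})"
                )
            steps = topology.walks.setdefault(assembly, [])
            n_rows += 1
            if seg_list == ".":
                continue
            for token in seg_list.split(","):
                if len(token) < 2 or token[-1] not in _ORIENTS:
                    raise WalkFormatError(f"{path}:{lineno}: bad oriented segment '{token}'")
                seg_id, orient = token[:-1], token[-1]
                if seg_id not in topology.segments:
                    raise WalkFormatError(
                        f"{path}:{lineno}: walk references unknown segment '{seg_id}'"
                    )
                steps.append(
                    WalkStep(
                        segment_id=seg_id,
                        orient=orient,
                        chrom=chrom,
                        ref_start=ref_start,
                        ref_end=ref_end,
                    )
                )
    if n_rows == 0:
        logger.warning("%s: walk file contained no rows", path)
    return topology


def write_walks(
    topology: GraphTopology, path: str | Path, header_comment: str | None = None
) -> None:
    """Write walks back to the walk TSV dialect, one bubble per row."""
    path = Path(path)
    with path.open("w") as handle:
        if header_comment:
            handle.write(f"# {header_comment}\n")
        handle.write("# assembly\tchrom\tref_start\tref_end\tsegments\n")
        for assembly, _steps in topology.walks.items():
            for chrom, start, end, steps in topology.walk_bubbles(assembly):
                seg_list = ",".join(f"{s.segment_id}{s.orient}" for s in steps)
                handle.write(f"{assembly}\t{chrom}\t{start}\t{end}\t{seg_list}\n")


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered name -> uppercase sequence mapping."""
    return {
        rec.id: validate_dna(str(rec.seq), context=str(path))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path, descriptions: dict[str, str] | None = None) -> None:
    """Write sequences to FASTA with 60-column wrapping."""
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description=(descriptions or {}).get(name, ""),
        )
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_nrs_fasta(
    records: Iterable,
    path: str | Path,
    reference: dict[str, str] | None = None,
    flank_bp: int = 0,
) -> None:
    """Write NRS records to FASTA.

    Headers are ``nrs_id|chrom|anchor_pos_1based|class``.  With ``flank_bp``
    > 0 and a reference, up to ``flank_bp`` reference bases are prepended and
    appended around the insertion breakpoint and the realized flank lengths
    are recorded as ``|lf=<n>|rf=<n>`` in the header.
    """
    if flank_bp and reference is None:
        raise ValueError("flank mode requires a reference")
    out: dict[str, str] = {}
    for rec in records:
        chrom, pos = rec.anchor
        header = f"{rec.id}|{chrom}|{pos + 1}|{rec.klass}"
        seq = rec.sequence
        if flank_bp:
            ref_seq = reference[chrom]
            left = ref_seq[max(0, pos - flank_bp) : pos]
            right = ref_seq[pos : pos + flank_bp]
            header += f"|lf={len(left)}|rf={len(right)}"
            seq = left + seq + right
        out[header] = seq
    write_fasta(out, path)


def read_nrs_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA written by :func:`write_nrs_fasta`; id -> sequence."""
    return load_fasta(path)
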