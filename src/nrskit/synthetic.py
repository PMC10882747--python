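"""Ground-truthed synthetic data: reference, graph, walks, coverage, groups.

The generator emulates the data regime the pipeline is built for: a linear
backbone genome, a handful of assemblies carrying planted insertions whose
lengths straddle the 500 bp retention cutoff and whose non-reference base
fraction straddles 50%, per-insertion population carrier frequencies
(including group-differential insertions), and per-sample read coverage at
a configurable depth.  Every planted insertion is recorded in a truth table
from which the expected behaviour of every pipeline stage is recomputable.

Random DNA is i.i.d. uniform over ACGT — there is no repeat model, which
keeps the redundancy and reference-alignment screens unambiguous.  One
integer seed drives all randomness; every output file records it in a
header comment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, ThresholdConfig
from .graphio import GraphTopology, SegmentRecord, WalkStep, write_fasta, write_rgfa, write_walks
from .nrs import passes_criteria

_BASES = np.array(list("ACGT"))

# mixture of uniform length ranges (weight, low, high), straddling the
# 500 bp retention cutoff
DEFAULT_LENGTH_MIXTURE = ((0.30, 300, 490), (0.45, 520, 1500), (0.25, 1500, 3500))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    ``n_insertions`` counts ordinary planted insertions; redundant and
    reference-like decoys (planted to exercise the filtering funnel) are
    configured separately and appear in the truth table like any other
    insertion, with their expected fate recorded.
    """

    seed: int = 42
    n_chroms: int = 2
    chrom_len_bp: int = 100_000
    n_assemblies: int = 4
    n_insertions: int = 12
    insertion_len_distribution: tuple[tuple[float, int, int], ...] = DEFAULT_LENGTH_MIXTURE
    ref_reuse_prob: float = 0.35
    n_samples_per_group: tuple[int, int] = (75, 75)
    carrier_freq_spec: tuple[tuple[float, float], ...] | None = None
    depth: float = 21.0
    read_len_bp: int = 150
    flank_bp: int = 100
    n_redundant_decoys: int = 1
    n_reference_like_decoys: int = 1
    n_skeptical_orphans: int = 1
    backbone_name: str = "ref"

    def __post_init__(self) -> None:
        if self.n_chroms < 1 or self.chrom_len_bp < 5_000 or self.n_assemblies < 1:
            raise ValueError("degenerate genome configuration")
        weights = [w for w, _, _ in self.insertion_len_distribution]
        if abs(sum(weights) - 1.0) > 1e-9 or any(w < 0 for w in weights):
            raise ValueError("length mixture weights must be non-negative and sum to 1")
        if not 0.0 <= self.ref_reuse_prob <= 1.0:
            raise ValueError("ref_reuse_prob must lie in [0, 1]")
        if self.depth < 0 or self.read_len_bp <= 0:
            raise ValueError("depth must be >= 0 and read_len_bp positive")


@dataclass
class InsertionTruth:
    """Ground truth for one planted insertion."""

    id: str
    chrom: str
    breakpoint: int  # 0-based insertion breakpoint
    total_bp: int
    nrn_bp: int
    ref_reuse_bp: int
    novel_segments: tuple[str, ...]
    node_path: tuple[tuple[str, str], ...]
    carriers: tuple[str, ...]
    retainable: bool
    expected_klass: str  # cNRS | pNRS
    expected_final: str  # retained | redundant | reference_like | dropped
    group_freqs: tuple[float, float]
    sequence: str


@dataclass
class TruthTable:
    insertions: list[InsertionTruth]
    # sample -> insertion id -> carrier status (filled by simulate_coverage)
    sample_carriers: dict[str, dict[str, bool]] = field(default_factory=dict)

    def by_id(self) -> dict[str, InsertionTruth]:
        return {ins.id: ins for ins in self.insertions}

    def retainable(self) -> list[InsertionTruth]:
        return [i for i in self.insertions if i.retainable and i.expected_final == "retained"]


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    reference: dict[str, str]
    topology: GraphTopology
    truth: TruthTable
    paths: dict[str, Path] = field(default_factory=dict)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _draw_length(rng: np.random.Generator, mixture) -> int:
    weights = np.array([w for w, _, _ in mixture])
    idx = rng.choice(len(mixture), p=weights / weights.sum())
    _, lo, hi = mixture[idx]
    return int(rng.integers(lo, hi + 1))


def _mutate(rng: np.random.Generator, seq: str, rate: float = 0.02) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _plan_breakpoints(
    rng: np.random.Generator, config: SimulationConfig, n_total: int, max_span: int
) -> list[tuple[str, int]]:
    """Distinct breakpoints kept well apart and away from chromosome ends."""
    step = 2 * (config.flank_bp + 200 + max_span)
    margin = config.flank_bp + 100
    slots: list[tuple[str, int]] = []
    for c in range(config.n_chroms):
        chrom = f"chr{c + 1}"
        slots.extend(
            (chrom, pos)
            for pos in range(margin, config.chrom_len_bp - margin - max_span - step // 4, step)
        )
    if n_total > len(slots):
        raise ValueError(
            f"cannot place {n_total} insertions on {config.n_chroms} x "
            f"{config.chrom_len_bp} bp without breakpoint collisions"
        )
    chosen = rng.choice(len(slots), size=n_total, replace=False)
    picked = [slots[i] for i in chosen]
    # jitter within half a step so breakpoints are not grid-locked
    jitter = rng.integers(0, step // 4, size=n_total)
    return sorted(
        (chrom, int(pos + j)) for (chrom, pos), j in zip(picked, jitter)
    )


def generate_dataset(config: SimulationConfig, outdir: str | Path | None = None) -> SyntheticDataset:
    """Build reference, graph, walks, annotation and truth for one seed.

    Outputs are byte-identical for equal configs.  When ``outdir`` is given,
    reference.fa, graph.gfa, walks.tsv, annotation.gff3 and truth.tsv are
    written there.
    """
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{c + 1}" for c in range(config.n_chroms)]
    reference = {chrom: _random_dna(rng, config.chrom_len_bp) for chrom in chrom_names}
    assemblies = [f"asm{i + 1:02d}" for i in range(config.n_assemblies)]

    max_span = max(hi for _, _, hi in config.insertion_len_distribution)
    n_total = config.n_insertions + config.n_redundant_decoys + config.n_reference_like_decoys
    breakpoints = _plan_breakpoints(rng, config, n_total, max_span)

    # --- plan ordinary insertions -----------------------------------------
    plans: list[dict] = []
    for i in range(config.n_insertions):
        chrom, bp = breakpoints[i]
        total = _draw_length(rng, config.insertion_len_distribution)
        is_pnrs = bool(rng.random() < config.ref_reuse_prob)
        if is_pnrs:
            nrn_fraction = float(rng.uniform(0.30, 0.70))
            nrn_bp = max(1, round(total * nrn_fraction))
            reuse = total - nrn_bp
            if reuse < 20:  # too small to be a meaningful reference segment
                is_pnrs, nrn_bp, reuse = False, total, 0
        else:
            nrn_bp, reuse = total, 0
        n_carriers = int(rng.integers(1, config.n_assemblies + 1))
        carriers = tuple(sorted(rng.choice(assemblies, size=n_carriers, replace=False)))
        plans.append(
            {
                "id": f"ins_{i + 1:03d}",
                "chrom": chrom,
                "bp": bp,
                "novel_seq": _random_dna(rng, nrn_bp),
                "reuse": reuse,
                "carriers": carriers,
                "expected_final": None,  # decided by the retention criteria
            }
        )

    # --- decoys ------------------------------------------------------------
    dup_sources = [
        p for p in plans
        if p["reuse"] == 0 and len(p["novel_seq"]) > DEFAULT_CONFIG.min_nrs_bp + 120
    ]
    idx = config.n_insertions
    for d in range(config.n_redundant_decoys):
        if not dup_sources:
            break
        source = dup_sources[int(rng.integers(0, len(dup_sources)))]
        chrom, bp = breakpoints[idx]
        trimmed = source["novel_seq"][: int(len(source["novel_seq"]) * rng.uniform(0.92, 0.97))]
        n_carriers = int(rng.integers(1, config.n_assemblies + 1))
        plans.append(
            {
                "id": f"dup_{d + 1:03d}",
                "chrom": chrom,
                "bp": bp,
                "novel_seq": _mutate(rng, trimmed),
                "reuse": 0,
                "carriers": tuple(sorted(rng.choice(assemblies, size=n_carriers, replace=False))),
                "expected_final": "redundant",
            }
        )
        idx += 1
    for d in range(config.n_reference_like_decoys):
        chrom, bp = breakpoints[idx]
        src_chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        length = int(rng.integers(700, 1500))
        # copy a reference window far from any planted breakpoint
        start = int(rng.integers(config.chrom_len_bp // 2 - 5_000, config.chrom_len_bp // 2))
        plans.append(
            {
                "id": f"reflike_{d + 1:03d}",
                "chrom": chrom,
                "bp": bp,
                "novel_seq": reference[src_chrom][start : start + length],
                "reuse": 0,
                "carriers": (assemblies[int(rng.integers(0, config.n_assemblies))],),
                "expected_final": "reference_like",
            }
        )
        idx += 1

    plans.sort(key=lambda p: (p["chrom"], p["bp"]))

    # --- build graph segments ----------------------------------------------
    topo = GraphTopology()
    seg_counter = 0

    def new_seg(seq: str, chrom: str, offset: int, rank: int) -> SegmentRecord:
        nonlocal seg_counter
        seg_counter += 1
        seg = SegmentRecord(id=f"s{seg_counter:05d}", sequence=seq, chrom=chrom, offset=offset, rank=rank)
        topo.segments[seg.id] = seg
        return seg

    backbone_pieces: dict[str, list[SegmentRecord]] = {}
    ref_mid_by_plan: dict[str, SegmentRecord] = {}
    for chrom in chrom_names:
        cuts = {0, config.chrom_len_bp}
        for p in plans:
            if p["chrom"] != chrom:
                continue
            cuts.add(p["bp"])
            if p["reuse"]:
                cuts.add(p["bp"] + p["reuse"])
        ordered = sorted(cuts)
        pieces = []
        for lo, hi in zip(ordered, ordered[1:]):
            pieces.append(new_seg(reference[chrom][lo:hi], chrom, lo, 0))
        backbone_pieces[chrom] = pieces
        for p in plans:
            if p["chrom"] == chrom and p["reuse"]:
                mid = next(s for s in pieces if s.offset == p["bp"])
                assert mid.length == p["reuse"]
                ref_mid_by_plan[p["id"]] = mid

    truth_rows: list[InsertionTruth] = []
    for p in plans:
        novel = p["novel_seq"]
        if len(novel) > 1000:
            cut = int(len(novel) // 2 + rng.integers(-100, 100))
            nov_segs = [
                new_seg(novel[:cut], p["carriers"][0], 0, 1),
                new_seg(novel[cut:], p["carriers"][0], 0, 1),
            ]
        else:
            nov_segs = [new_seg(novel, p["carriers"][0], 0, 1)]
        path = [(s.id, "+") for s in nov_segs]
        if p["reuse"]:
            mid = ref_mid_by_plan[p["id"]]
            if rng.random() < 0.5:
                path = path + [(mid.id, "+")]
            else:
                path = [(mid.id, "+")] + path
        p["path"] = tuple(path)
        p["nov_segs"] = nov_segs
        total = len(novel) + p["reuse"]
        retainable = passes_criteria(total, len(novel), len(nov_segs), len(p["carriers"]))
        if p["expected_final"] is None:
            expected_final = "retained" if retainable else "dropped"
        else:
            expected_final = p["expected_final"] if retainable else "dropped"
        seq = "".join(
            topo.segments[sid].sequence for sid, _ in path
        )
        truth_rows.append(
            InsertionTruth(
                id=p["id"],
                chrom=p["chrom"],
                breakpoint=p["bp"],
                total_bp=total,
                nrn_bp=len(novel),
                ref_reuse_bp=p["reuse"],
                novel_segments=tuple(s.id for s in nov_segs),
                node_path=p["path"],
                carriers=p["carriers"],
                retainable=retainable,
                expected_klass="pNRS" if p["reuse"] else "cNRS",
                expected_final=expected_final,
                group_freqs=(0.0, 0.0),  # filled below
                sequence=seq,
            )
        )

    # --- links --------------------------------------------------------------
    for chrom in chrom_names:
        pieces = backbone_pieces[chrom]
        for left, right in zip(pieces, pieces[1:]):
            topo.links.add((left.id, "+", right.id, "+"))
    by_offset = {
        (chrom, seg.offset): seg for chrom in chrom_names for seg in backbone_pieces[chrom]
    }
    for p in plans:
        chrom, bp = p["chrom"], p["bp"]
        left = max(
            (s for s in backbone_pieces[chrom] if s.offset + s.length <= bp),
            key=lambda s: s.offset,
        )
        after = bp + p["reuse"] if p["reuse"] else bp
        right = by_offset[(chrom, after)]
        chain = [left.id] + [sid for sid, _ in p["path"] if topo.segments[sid].rank == 1]
        # novel chain links, then into the right backbone piece
        for a, b in zip(chain, chain[1:]):
            topo.links.add((a, "+", b, "+"))
        topo.links.add((chain[-1], "+", right.id, "+"))

    # --- orphan (skeptical) segments ----------------------------------------
    for o in range(config.n_skeptical_orphans):
        new_seg(_random_dna(rng, int(rng.integers(100, 300))), "orphan", 0, 1)

    # --- walks ---------------------------------------------------------------
    backbone = config.backbone_name
    topo.walks[backbone] = [
        WalkStep(seg.id, "+", chrom, seg.offset, seg.offset + seg.length)
        for chrom in chrom_names
        for seg in backbone_pieces[chrom]
    ]
    plans_by_chrom: dict[str, list[dict]] = {}
    for p in plans:
        plans_by_chrom.setdefault(p["chrom"], []).append(p)
    for assembly in assemblies:
        steps: list[WalkStep] = []
        for chrom in chrom_names:
            carried = [p for p in plans_by_chrom.get(chrom, []) if assembly in p["carriers"]]
            cnrs_at = {p["bp"]: p for p in carried if not p["reuse"]}
            pnrs_mid = {ref_mid_by_plan[p["id"]].id: p for p in carried if p["reuse"]}
            for seg in backbone_pieces[chrom]:
                if seg.offset in cnrs_at:
                    p = cnrs_at[seg.offset]
                    steps.extend(
                        WalkStep(sid, orient, chrom, p["bp"], p["bp"])
                        for sid, orient in p["path"]
                    )
                if seg.id in pnrs_mid:
                    p = pnrs_mid[seg.id]
                    steps.extend(
                        WalkStep(sid, orient, chrom, p["bp"], p["bp"] + p["reuse"])
                        for sid, orient in p["path"]
                    )
                else:
                    steps.append(WalkStep(seg.id, "+", chrom, seg.offset, seg.offset + seg.length))
        topo.walks[assembly] = steps

    truth = TruthTable(insertions=truth_rows)
    _assign_group_freqs(truth, config, rng)

    dataset = SyntheticDataset(config=config, reference=reference, topology=topo, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed_note = f"seed={config.seed}"
        ref_path = outdir / "reference.fa"
        write_fasta(reference, ref_path, descriptions={c: seed_note for c in reference})
        write_rgfa(topo, outdir / "graph.gfa", header_comment=seed_note)
        write_walks(topo, outdir / "walks.tsv", header_comment=seed_note)
        write_annotation(
            {c: config.chrom_len_bp for c in chrom_names}, outdir / "annotation.gff3",
            seed_note=seed_note,
        )
        truth_path = outdir / "truth.tsv"
        with truth_path.open("w") as handle:
            handle.write(f"# {seed_note}\n")
            truth_table_frame(truth).to_csv(handle, sep="\t", index=False)
        dataset.paths = {
            "reference": ref_path,
            "rgfa": outdir / "graph.gfa",
            "walks": outdir / "walks.tsv",
            "annotation": outdir / "annotation.gff3",
            "truth": truth_path,
        }
    return dataset


def _assign_group_freqs(truth: TruthTable, config: SimulationConfig, rng: np.random.Generator) -> None:
    """Per-insertion (group1, group2) carrier frequencies.

    With no explicit spec, the first two truth-retainable insertions get
    strongly differential frequencies (gaps >= 0.4) so group comparison has
    planted positives; all other insertions share one frequency in both
    groups.
    """
    if config.carrier_freq_spec is not None:
        if len(config.carrier_freq_spec) != len(truth.insertions):
            raise ValueError("carrier_freq_spec length must match the number of insertions")
        for ins, freqs in zip(truth.insertions, config.carrier_freq_spec):
            ins.group_freqs = (float(freqs[0]), float(freqs[1]))
        return
    differential = [(0.10, 0.70), (0.80, 0.20)]
    n_assigned = 0
    for ins in truth.insertions:
        if n_assigned < len(differential) and ins.retainable and ins.expected_final == "retained":
            ins.group_freqs = differential[n_assigned]
            n_assigned += 1
        else:
            f = float(rng.uniform(0.10, 0.90))
            ins.group_freqs = (f, f)


def truth_table_frame(truth: TruthTable) -> pd.DataFrame:
    rows = []
    for ins in truth.insertions:
        rows.append(
            {
                "id": ins.id,
                "chrom": ins.chrom,
                "breakpoint": ins.breakpoint,
                "total_bp": ins.total_bp,
                "nrn_bp": ins.nrn_bp,
                "ref_reuse_bp": ins.ref_reuse_bp,
                "novel_segments": ",".join(ins.novel_segments),
                "carriers": ",".join(ins.carriers),
                "retainable": ins.retainable,
                "expected_klass": ins.expected_klass,
                "expected_final": ins.expected_final,
                "group1_freq": ins.group_freqs[0],
                "group2_freq": ins.group_freqs[1],
            }
        )
    return pd.DataFrame(rows)


def write_annotation(
    chrom_lengths: dict[str, int], path: str | Path, seed_note: str = ""
) -> None:
    """Deterministic synthetic gene models (GFF3).

    Three-exon protein-coding genes tiled every 8 kb: 150 bp 5'UTR, three
    CDS blocks separated by introns, 200 bp 3'UTR.  Coordinates are 1-based
    inclusive as GFF3 requires.
    """
    path = Path(path)
    with path.open("w") as handle:
        handle.write("##gff-version 3\n")
        if seed_note:
            handle.write(f"# {seed_note}\n")
        for chrom, length in chrom_lengths.items():
            handle.write(f"##sequence-region {chrom} 1 {length}\n")
            gene_no = 0
            for g0 in range(2_000, length - 4_000, 8_000):
                gene_no += 1
                gid = f"gene_{chrom}_{gene_no:03d}"
                g1 = g0 + 1  # 1-based start
                gend = g0 + 3_000
                parts = [
                    ("gene", g1, gend, gid, "."),
                    ("mRNA", g1, gend, f"{gid}.t1", gid),
                    ("exon", g1, g0 + 400, f"{gid}.e1", f"{gid}.t1"),
                    ("five_prime_UTR", g1, g0 + 150, f"{gid}.u5", f"{gid}.t1"),
                    ("CDS", g0 + 151, g0 + 400, f"{gid}.c1", f"{gid}.t1"),
                    ("exon", g0 + 1_201, g0 + 1_800, f"{gid}.e2", f"{gid}.t1"),
                    ("CDS", g0 + 1_201, g0 + 1_800, f"{gid}.c2", f"{gid}.t1"),
                    ("exon", g0 + 2_601, gend, f"{gid}.e3", f"{gid}.t1"),
                    ("CDS", g0 + 2_601, g0 + 2_800, f"{gid}.c3", f"{gid}.t1"),
                    ("three_prime_UTR", g0 + 2_801, gend, f"{gid}.u3", f"{gid}.t1"),
                ]
                for ftype, start, end, fid, parent in parts:
                    attrs = f"ID={fid}" + (f";Parent={parent}" if parent != "." else "")
                    handle.write(
                        f"{chrom}\tnrskit\t{ftype}\t{start}\t{end}\t.\t+\t.\t{attrs}\n"
                    )


def simulate_coverage(
    truth: TruthTable,
    config: SimulationConfig,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample alignment intervals over each insertion body, plus groups.

    Carrier status per (sample, insertion) is Bernoulli in the sample
    group's carrier frequency.  Carriers receive read-length intervals at
    Poisson-distributed depth tiling the insertion body; non-carriers
    receive only sparse flank-spill intervals (at most half a read length
    per end, expected breadth well below the presence threshold).  About
    10% of (sample, insertion) pairs also get one low-quality (MAPQ < 10)
    interval that the quality screen must remove.

    Fills ``truth.sample_carriers`` and returns (intervals, groups) frames;
    written as intervals.tsv / groups.tsv when ``outdir`` is given.
    """
    rng = np.random.default_rng([config.seed, 1])
    n1, n2 = config.n_samples_per_group
    samples = [f"g1_s{i + 1:03d}" for i in range(n1)] + [f"g2_s{i + 1:03d}" for i in range(n2)]
    group_of = {s: ("group1" if s.startswith("g1") else "group2") for s in samples}
    read_len = config.read_len_bp

    interval_rows = []
    truth.sample_carriers = {s: {} for s in samples}
    for ins in truth.insertions:
        length = ins.total_bp
        for sample in samples:
            freq = ins.group_freqs[0] if group_of[sample] == "group1" else ins.group_freqs[1]
            carrier = bool(rng.random() < freq)
            truth.sample_carriers[sample][ins.id] = carrier
            if carrier and config.depth > 0:
                n_reads = rng.poisson(config.depth * (length + read_len - 1) / read_len)
                starts = rng.integers(-(read_len - 1), length, size=n_reads)
                for s in starts:
                    lo, hi = max(0, int(s)), min(length, int(s) + read_len)
                    if hi > lo:
                        interval_rows.append((sample, ins.id, lo, hi, 60))
            else:
                for edge in (0, 1):
                    if rng.random() < 0.5:
                        w = int(rng.integers(1, read_len // 2 + 1))
                        w = min(w, length)
                        lo, hi = (0, w) if edge == 0 else (length - w, length)
                        interval_rows.append((sample, ins.id, lo, hi, 60))
            if rng.random() < 0.1:
                lo = int(rng.integers(0, length))
                hi = min(length, lo + read_len)
                if hi > lo:
                    interval_rows.append((sample, ins.id, lo, hi, int(rng.integers(0, 10))))

    intervals = pd.DataFrame(
        interval_rows, columns=["sample", "nrs_id", "start", "end", "mapq"]
    )
    groups = pd.DataFrame({"sample": samples, "group": [group_of[s] for s in samples]})
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in (("intervals.tsv", intervals), ("groups.tsv", groups)):
            with (outdir / name).open("w") as handle:
                handle.write(f"# seed={config.seed}\n")
                frame.to_csv(handle, sep="\t", index=False)
    return intervals, groups


def match_records_to_truth(records, truth: TruthTable) -> dict[str, str]:
    """Map retained NRS record ids to truth insertion ids via their anchors."""
    by_anchor = {(ins.chrom, ins.breakpoint): ins.id for ins in truth.insertions}
    return {
        rec.id: by_anchor[rec.anchor] for rec in records if rec.anchor in by_anchor
    }
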