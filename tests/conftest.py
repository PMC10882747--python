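"""Shared fixtures: handcrafted micro-graphs and cached synthetic datasets."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from nrskit.graphio import GraphTopology, SegmentRecord, WalkStep
from nrskit.synthetic import SimulationConfig, generate_dataset


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_topology(segments, links=(), walks=None) -> GraphTopology:
    """Build a topology from (id, seq, chrom, offset, rank) tuples and
    walks given as {assembly: [(seg_id, orient, chrom, start, end), ...]}."""
    topo = GraphTopology()
    for seg_id, seq, chrom, offset, rank in segments:
        topo.segments[seg_id] = SegmentRecord(
            id=seg_id, sequence=seq, chrom=chrom, offset=offset, rank=rank
        )
    topo.links = set(links)
    for assembly, steps in (walks or {}).items():
        topo.walks[assembly] = [WalkStep(*step) for step in steps]
    return topo


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at the default study conditions."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def bubble_topology():
    rng = np.random.default_rng(555)
    """A micro-graph with one reference chromosome and four bubbles:

    - b600: 600 bp all-novel insertion at 300, carried by asmA and asmB
      (retained cNRS)
    - b400: 400 bp all-novel insertion at 900, carried by asmA (dropped:
      too short)
    - bfrac: bubble replacing [300, 900) in asmC with a 400 bp novel node
      followed by the 600 bp reference piece (dropped: NRN fraction 0.4)
    - bpnrs: bubble replacing [900, 1100) in asmB with an 800 bp novel node
      plus the 200 bp reference piece (retained pNRS, fraction 0.8)
    """
    ref = random_dna(rng, 1400)
    segs = [
        ("sA", ref[0:300], "chr1", 0, 0),
        ("sB", ref[300:900], "chr1", 300, 0),
        ("sC", ref[900:1100], "chr1", 900, 0),
        ("sD", ref[1100:1400], "chr1", 1100, 0),
        ("n600", random_dna(rng, 600), "asmA", 0, 1),
        ("n400", random_dna(rng, 400), "asmA", 0, 1),
        ("nfrac", random_dna(rng, 400), "asmC", 0, 1),
        ("npnrs", random_dna(rng, 800), "asmB", 0, 1),
    ]
    tiles = [
        ("sA", "+", "chr1", 0, 300),
        ("sB", "+", "chr1", 300, 900),
        ("sC", "+", "chr1", 900, 1100),
        ("sD", "+", "chr1", 1100, 1400),
    ]
    walks = {
        "ref": list(tiles),
        "asmA": [
            tiles[0],
            ("n600", "+", "chr1", 300, 300),
            tiles[1],
            ("n400", "+", "chr1", 900, 900),
            tiles[2],
            tiles[3],
        ],
        "asmB": [
            tiles[0],
            ("n600", "+", "chr1", 300, 300),
            tiles[1],
            ("npnrs", "+", "chr1", 900, 1100),
            ("sC", "+", "chr1", 900, 1100),
            tiles[3],
        ],
        "asmC": [
            tiles[0],
            ("nfrac", "+", "chr1", 300, 900),
            ("sB", "+", "chr1", 300, 900),
            tiles[2],
            tiles[3],
        ],
    }
    topo = make_topology(segs, walks=walks)
    return topo, ref
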