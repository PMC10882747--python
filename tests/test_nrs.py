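"""Candidate extraction, the four retention criteria, redundancy and
reference screens, classification, anchoring, context and density."""

import numpy as np
import pytest

from nrskit.config import ThresholdConfig
from nrskit.exceptions import PipelineError
from nrskit.labeling import label_nodes
from nrskit.nrs import (
    CNRS,
    PNRS,
    NrsRecord,
    annotate_context,
    classify_and_anchor,
    extract_candidates,
    filter_reference_like,
    funnel_retained,
    interval_density,
    remove_redundant,
)

from conftest import random_dna
from oracles import sw_redundant_partition


def _record(rid, seq, chrom="chr1", pos=0, nrn_bp=None, klass="raw"):
    return NrsRecord(
        id=rid, node_path=((rid + "_n", "+"),), sequence=seq, total_bp=len(seq),
        nrn_bp=len(seq) if nrn_bp is None else nrn_bp,
        supporters=frozenset({"asmA"}), klass=klass,
        anchor=(chrom, pos), source_interval=(pos, pos),
    )


class TestExtractCandidates:
    def test_retention_criteria_on_constructed_bubbles(self, bubble_topology):
        topo, _ = bubble_topology
        labeling = label_nodes(topo, "ref")
        records = extract_candidates(topo, labeling, backbone_name="ref")
        by_interval = {r.source_interval: r for r in records}
        # 600 bp all-novel deviation: retained, full NRN fraction
        assert (300, 300) in by_interval
        r600 = by_interval[(300, 300)]
        assert r600.total_bp == 600 and r600.nrn_fraction == 1.0
        # identical deviation in asmA and asmB merged with both supporters
        assert r600.supporters == {"asmA", "asmB"}
        # 400 bp deviation dropped (not greater than 500 bp)
        assert all(r.total_bp > 500 for r in records)
        # 1000 bp deviation at NRN fraction 0.4 dropped (not over 50%)
        assert (300, 900) not in by_interval
        # the partial bubble (800 novel + 200 reference) is retained
        assert (900, 1100) in by_interval
        assert by_interval[(900, 1100)].nrn_bp == 800
        assert len(records) == 2

    def test_every_output_record_satisfies_all_criteria(self, default_dataset):
        ds = default_dataset
        labeling = label_nodes(ds.topology, "ref")
        records = extract_candidates(ds.topology, labeling, backbone_name="ref")
        assert records
        for rec in records:
            assert rec.total_bp > 500
            assert rec.nrn_fraction > 0.5
            assert rec.nrn_bp >= 1
            assert rec.supporters

    def test_unanchorable_bubble_is_an_error(self, bubble_topology):
        topo, _ = bubble_topology
        labeling = label_nodes(topo, "ref")
        from nrskit.graphio import WalkStep

        topo.walks["asmA"].append(WalkStep("n600", "+", "chrUn", 0, 0))
        labeling.label.setdefault("n600", "non_reference")
        with pytest.raises(PipelineError, match="chrUn"):
            extract_candidates(topo, labeling, backbone_name="ref")


class TestRemoveRedundant:
    def test_identical_pair_keeps_first_by_tie_break(self, rng):
        seq = random_dna(rng, 800)
        retained, redundant = remove_redundant([_record("a", seq), _record("b", seq)])
        assert [r.id for r in retained] == ["a"]
        assert [r.id for r in redundant] == ["b"]
        assert redundant[0].klass == "redundant"

    def test_pair_below_identity_threshold_both_kept(self, rng):
        seq = random_dna(rng, 800)
        out = list(seq)
        idx = rng.choice(len(seq), size=int(0.15 * len(seq)), replace=False)
        for i in idx:
            out[i] = "ACGT"[("ACGT".index(out[i]) + 1) % 4]
        retained, redundant = remove_redundant([_record("a", seq), _record("b", "".join(out))])
        assert len(retained) == 2 and not redundant

    def test_nested_substring_chain_keeps_only_longest(self, rng):
        a = random_dna(rng, 1500)
        b, c = a[:1100], a[:700]
        records = [_record("c", c), _record("a", a), _record("b", b)]
        retained, redundant = remove_redundant(records)
        assert {r.id for r in retained} == {"a"}
        # brute-force DP partition agrees
        oracle_kept, oracle_dup = sw_redundant_partition(records)
        assert oracle_kept == {"a"} and oracle_dup == {"b", "c"}

    def test_partition_property(self, rng):
        records = [_record(f"r{i}", random_dna(rng, int(rng.integers(550, 900)))) for i in range(6)]
        retained, redundant = remove_redundant(records)
        assert len(retained) + len(redundant) == len(records)
        assert {r.id for r in retained} | {r.id for r in redundant} == {r.id for r in records}


class TestReferenceScreen:
    def test_verbatim_reference_substring_flagged(self, rng):
        ref = {"chr1": random_dna(rng, 5000)}
        planted = _record("novel", random_dna(rng, 800))
        embedded = _record("reflike", ref["chr1"][1000:1800])
        retained, reflike = filter_reference_like([planted, embedded], ref)
        assert [r.id for r in retained] == ["novel"]
        assert [r.id for r in reflike] == ["reflike"]
        assert reflike[0].klass == "reference_like"

    def test_count_conservation(self, rng):
        ref = {"chr1": random_dna(rng, 3000)}
        records = [_record(f"r{i}", random_dna(rng, 700)) for i in range(4)]
        retained, reflike = filter_reference_like(records, ref)
        assert len(retained) + len(reflike) == len(records)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(PipelineError):
            filter_reference_like([_record("a", "ACGT" * 200)], {})


class TestClassifyAndAnchor:
    def test_classes_and_anchor_convention(self, bubble_topology):
        topo, _ = bubble_topology
        labeling = label_nodes(topo, "ref")
        records = extract_candidates(topo, labeling, backbone_name="ref")
        final = classify_and_anchor(records, topo, labeling)
        by_interval = {r.source_interval: r for r in final}
        cnrs = by_interval[(300, 300)]
        pnrs = by_interval[(900, 1100)]
        assert cnrs.klass == CNRS and pnrs.klass == PNRS
        # anchor is the left breakpoint; reported 1-based adds one
        assert cnrs.anchor == ("chr1", 300) and cnrs.anchor_pos_1based == 301
        assert pnrs.anchor == ("chr1", 900)
        # no cNRS path contains a reference-labeled node
        for rec in final:
            if rec.klass == CNRS:
                assert all(labeling.label[sid] != "reference" for sid, _ in rec.node_path)


class TestFunnel:
    def test_retained_is_raw_minus_removals(self):
        assert funnel_retained(100, 30, 20) == 50
        with pytest.raises(ValueError):
            funnel_retained(10, 20, 0)

    def test_funnel_conservation_on_synthetic_run(self, default_dataset):
        ds = default_dataset
        labeling = label_nodes(ds.topology, "ref")
        raw = extract_candidates(ds.topology, labeling, backbone_name="ref")
        kept1, redundant = remove_redundant(raw)
        kept2, reflike = filter_reference_like(kept1, ds.reference)
        final = classify_and_anchor(kept2, ds.topology, labeling)
        assert len(raw) == len(redundant) + len(reflike) + len(final)
        assert funnel_retained(len(raw), len(redundant), len(reflike)) == len(final)


GFF_MINI = """##gff-version 3
chr1\ttest\tgene\t101\t1000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t101\t1000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\texon\t101\t300\t.\t+\t.\tID=geneA.e1;Parent=geneA.t1
chr1\ttest\tfive_prime_UTR\t101\t150\t.\t+\t.\tID=geneA.u5;Parent=geneA.t1
chr1\ttest\tCDS\t151\t300\t.\t+\t.\tID=geneA.c1;Parent=geneA.t1
chr1\ttest\texon\t601\t1000\t.\t+\t.\tID=geneA.e2;Parent=geneA.t1
chr1\ttest\tCDS\t601\t800\t.\t+\t.\tID=geneA.c2;Parent=geneA.t1
chr1\ttest\tthree_prime_UTR\t801\t1000\t.\t+\t.\tID=geneA.u3;Parent=geneA.t1
"""


class TestAnnotateContext:
    @pytest.mark.parametrize(
        "pos, expected",
        [
            (200, "CDS"),            # inside first CDS
            (120, "five_prime_UTR"),
            (900, "three_prime_UTR"),
            (400, "intron"),          # gene body, between exons
            (5000, "intergenic"),
        ],
    )
    def test_priority_classification(self, tmp_path, pos, expected):
        gff = tmp_path / "mini.gff3"
        gff.write_text(GFF_MINI)
        rec = _record("r1", "ACGT" * 200, pos=pos)
        assert annotate_context([rec], gff) == {"r1": expected}


class TestIntervalDensity:
    def test_headline_span_one_decimal(self):
        # an 11.64 Mb window reported at one decimal
        count, density, span = interval_density(
            [], ("chrX", 45_231_665, 56_875_949), span_decimals=1
        )
        assert span == 11.6 and count == 0 and density == 0.0

    def test_density_counts_anchors_in_half_open_window(self):
        records = [_record(f"r{i}", "A" * 600, pos=100_000 * i) for i in range(10)]
        count, density, span = interval_density(records, ("chr1", 0, 2_000_000))
        assert count == 10 and span == 2.0 and density == 5.0

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_density([], ("chr1", 10, 10))
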