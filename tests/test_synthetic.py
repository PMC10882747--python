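"""Generator contracts: determinism, truth bookkeeping, coverage regimes,
and end-to-end recovery of planted insertions."""

import numpy as np
import pytest

from nrskit.graphio import load_fasta, parse_rgfa, parse_walks
from nrskit.labeling import label_nodes
from nrskit.nrs import classify_and_anchor, extract_candidates, filter_reference_like, remove_redundant
from nrskit.pav import build_profiles, call_presence, classify_frequencies, coverage_breadth
from nrskit.synthetic import (
    SimulationConfig,
    generate_dataset,
    match_records_to_truth,
    simulate_coverage,
)


def run_extraction(ds):
    labeling = label_nodes(ds.topology, ds.config.backbone_name)
    raw = extract_candidates(ds.topology, labeling, backbone_name=ds.config.backbone_name)
    kept, redundant = remove_redundant(raw)
    kept, reflike = filter_reference_like(kept, ds.reference)
    final = classify_and_anchor(kept, ds.topology, labeling)
    return raw, redundant, reflike, final


class TestDeterminism:
    def test_equal_seeds_give_byte_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=42, n_samples_per_group=(10, 10))
        files = {}
        for run in ("a", "b"):
            out = tmp_path / run
            ds = generate_dataset(cfg, out)
            simulate_coverage(ds.truth, cfg, out)
            files[run] = {
                p.name: p.read_bytes() for p in sorted(out.iterdir())
            }
        assert files["a"] == files["b"]
        assert set(files["a"]) == {
            "reference.fa", "graph.gfa", "walks.tsv", "annotation.gff3",
            "truth.tsv", "intervals.tsv", "groups.tsv",
        }

    def test_seed_recorded_in_every_output_header(self, tmp_path):
        cfg = SimulationConfig(seed=99, n_samples_per_group=(5, 5))
        ds = generate_dataset(cfg, tmp_path)
        simulate_coverage(ds.truth, cfg, tmp_path)
        for path in tmp_path.iterdir():
            head = path.read_text().splitlines()[:3]
            assert any("seed=99" in line for line in head), path.name


class TestTruthBookkeeping:
    def test_single_insertion_construction(self):
        cfg = SimulationConfig(
            seed=1, n_chroms=1, chrom_len_bp=30_000, n_assemblies=3, n_insertions=1,
            insertion_len_distribution=((1.0, 600, 600),), ref_reuse_prob=0.0,
            n_redundant_decoys=0, n_reference_like_decoys=0, n_skeptical_orphans=0,
        )
        ds = generate_dataset(cfg)
        (ins,) = ds.truth.insertions
        assert ins.total_bp == 600 and ins.nrn_bp == 600
        assert ins.retainable and ins.expected_klass == "cNRS"
        rank1 = [s for s in ds.topology.segments.values() if s.rank == 1]
        assert len(rank1) == 1 and rank1[0].length == 600

    def test_sub_threshold_insertion_marked_non_retainable(self):
        cfg = SimulationConfig(
            seed=2, n_chroms=1, chrom_len_bp=30_000, n_insertions=1,
            insertion_len_distribution=((1.0, 300, 300),), ref_reuse_prob=0.0,
            n_redundant_decoys=0, n_reference_like_decoys=0,
        )
        (ins,) = generate_dataset(cfg).truth.insertions
        assert not ins.retainable and ins.expected_final == "dropped"

    def test_retention_flag_recomputable_from_criteria(self, default_dataset):
        from nrskit.nrs import passes_criteria

        for ins in default_dataset.truth.insertions:
            assert ins.retainable == passes_criteria(
                ins.total_bp, ins.nrn_bp, len(ins.novel_segments), len(ins.carriers)
            )

    def test_truth_sequence_matches_graph_segments(self, default_dataset):
        topo = default_dataset.topology
        for ins in default_dataset.truth.insertions:
            seq = "".join(topo.segments[sid].sequence for sid, _ in ins.node_path)
            assert seq == ins.sequence
            assert len(seq) == ins.total_bp


class TestCoverageRegimes:
    def test_carrier_and_noncarrier_breadths_separate(self):
        cfg = SimulationConfig(
            seed=3, n_chroms=1, chrom_len_bp=40_000, n_insertions=2,
            insertion_len_distribution=((1.0, 1000, 1000),), ref_reuse_prob=0.0,
            n_samples_per_group=(250, 250),
            n_redundant_decoys=0, n_reference_like_decoys=0,
        )
        ds = generate_dataset(cfg)
        intervals, groups = simulate_coverage(ds.truth, cfg)
        lengths = {i.id: i.total_bp for i in ds.truth.insertions}
        profiles = build_profiles(intervals, lengths, list(groups["sample"]))
        carrier_breadths, noncarrier_breadths = [], []
        for sample, per_nrs in profiles.items():
            for nid, profile in per_nrs.items():
                breadth = coverage_breadth(profile)
                if ds.truth.sample_carriers[sample][nid]:
                    carrier_breadths.append(breadth)
                else:
                    noncarrier_breadths.append(breadth)
        assert len(carrier_breadths) >= 200
        assert np.mean([b > 0.70 for b in carrier_breadths]) >= 0.999
        assert max(noncarrier_breadths) < 0.70

    def test_zero_depth_carriers_have_no_intervals(self):
        cfg = SimulationConfig(
            seed=4, n_chroms=1, chrom_len_bp=30_000, n_insertions=1, depth=0.0,
            insertion_len_distribution=((1.0, 800, 800),), ref_reuse_prob=0.0,
            n_samples_per_group=(5, 5),
            n_redundant_decoys=0, n_reference_like_decoys=0,
        )
        ds = generate_dataset(cfg)
        intervals, _ = simulate_coverage(ds.truth, cfg)
        hq = intervals[intervals["mapq"] >= 10]
        # with zero depth even carriers get at most flank spill
        assert (hq.groupby("sample")["end"].count() <= 4).all()


class TestFrequencyDesign:
    def test_observed_carrier_freqs_within_binomial_bounds(self, default_dataset):
        from scipy.stats import binom

        ds = default_dataset
        simulate_coverage(ds.truth, ds.config)
        n = sum(ds.config.n_samples_per_group)
        n1, n2 = ds.config.n_samples_per_group
        # family-wise 95%: split the test level across the planted insertions
        alpha = 0.05 / len(ds.truth.insertions)
        for ins in ds.truth.insertions:
            carried = [ds.truth.sample_carriers[s][ins.id] for s in ds.truth.sample_carriers]
            k = sum(carried)
            f1, f2 = ins.group_freqs
            expected = (n1 * f1 + n2 * f2) / n
            lo = binom.ppf(alpha / 2, n, expected)
            hi = binom.ppf(1 - alpha / 2, n, expected)
            assert lo <= k <= hi, (ins.id, k, expected)


class TestEndToEndRecovery:
    def test_parsed_files_equal_in_memory_topology(self, tmp_path):
        cfg = SimulationConfig(seed=6)
        ds = generate_dataset(cfg, tmp_path)
        topo = parse_rgfa(ds.paths["rgfa"])
        parse_walks(ds.paths["walks"], topo)
        assert topo.segments == ds.topology.segments
        assert topo.walks == ds.topology.walks
        assert load_fasta(ds.paths["reference"]) == ds.reference

    def test_truth_retainable_set_recovered_exactly(self):
        """Every truth-retainable planted insertion appears as exactly one
        retained record with the right class and anchor; every sub-threshold
        or decoy plant is absent."""
        for seed in (21, 22, 23):
            ds = generate_dataset(SimulationConfig(seed=seed))
            raw, redundant, reflike, final = run_extraction(ds)
            assert len(raw) == len(redundant) + len(reflike) + len(final)
            mapping = match_records_to_truth(final, ds.truth)
            assert len(mapping) == len(final)
            truth = ds.truth.by_id()
            expected = {i.id for i in ds.truth.retainable()}
            assert set(mapping.values()) == expected
            for rec in final:
                ins = truth[mapping[rec.id]]
                assert rec.klass == ins.expected_klass
                assert rec.anchor == (ins.chrom, ins.breakpoint)
                assert rec.total_bp == ins.total_bp and rec.nrn_bp == ins.nrn_bp
                assert set(rec.supporters) == set(ins.carriers)

    def test_planted_decoys_funnelled_to_their_expected_fate(self):
        ds = generate_dataset(SimulationConfig(seed=24))
        raw, redundant, reflike, final = run_extraction(ds)
        truth = ds.truth.by_id()
        dup_ids = {i.id for i in ds.truth.insertions if i.expected_final == "redundant"}
        ref_ids = {i.id for i in ds.truth.insertions if i.expected_final == "reference_like"}
        assert dup_ids and ref_ids
        assert {match_records_to_truth(redundant, ds.truth)[r.id] for r in redundant} == dup_ids
        assert {match_records_to_truth(reflike, ds.truth)[r.id] for r in reflike} == ref_ids
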