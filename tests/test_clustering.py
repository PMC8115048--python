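"""ANI computation against the Hamming oracle, thresholds, CsCl retention,
and AMG scaffold merging."""

import numpy as np
import pytest

from amgkit import clustering as cl
from amgkit import synthetic as sy
from amgkit.genetics import revcomp
from conftest import random_dna


class TestPairwiseAni:
    def test_identical_sequences(self, rng):
        seq = random_dna(rng, 10000)
        summary = cl.pairwise_ani(seq, seq)
        assert summary.ani == pytest.approx(100.0)
        assert summary.aligned_fraction_shorter == pytest.approx(1.0)

    @pytest.mark.parametrize("target", [0.99, 0.96, 0.95, 0.92, 0.90])
    def test_matches_hamming_oracle_on_substitution_pairs(self, rng, target):
        seq = random_dna(rng, 10000)
        variant = sy.mutate_to_ani(seq, target, seed=int(target * 1000))
        summary = cl.pairwise_ani(seq, variant)
        oracle = cl.hamming_ani(seq, variant)
        assert summary.ani == pytest.approx(oracle, abs=0.3)
        assert summary.aligned_fraction_shorter > 0.98

    def test_partial_alignment_region(self, rng):
        core = random_dna(rng, 9000)
        seq_a = core + random_dna(rng, 1000)
        variant = sy.mutate_to_ani(core, 1 - 300 / 9000, seed=5)
        seq_b = variant + random_dna(rng, 1000)
        summary = cl.pairwise_ani(seq_a, seq_b)
        assert summary.ani == pytest.approx(100 * (1 - 300 / 9000), abs=0.3)
        assert summary.aligned_fraction_shorter == pytest.approx(0.90, abs=0.02)

    def test_unrelated_sequences_have_negligible_alignment(self, rng):
        summary = cl.pairwise_ani(random_dna(rng, 10000), random_dna(rng, 10000))
        assert summary.aligned_fraction_shorter < 0.10

    def test_reverse_complement_alignment_counted(self, rng):
        seq = random_dna(rng, 8000)
        variant = revcomp(sy.mutate_to_ani(seq, 0.97, seed=1))
        summary = cl.pairwise_ani(seq, variant)
        assert summary.strand == "-"
        assert summary.ani == pytest.approx(97.0, abs=0.3)

    def test_all_n_sequence_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            cl.pairwise_ani("N" * 2000, "ACGT" * 500)


class TestClusterPopulations:
    def test_identical_sequences_form_one_cluster(self, rng):
        seq = random_dna(rng, 6000)
        clusters = cl.cluster_scaffolds({"a": seq, "b": seq, "c": seq})
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b", "c"]

    def test_ani_threshold_separates_outgroup(self, rng):
        ancestor = random_dna(rng, 10000)
        near = sy.mutate_to_ani(ancestor, 0.96, seed=1)
        far = sy.mutate_to_ani(ancestor, 0.90, seed=2)
        clusters = cl.cluster_scaffolds({"anc": ancestor, "near": near, "far": far})
        members = {frozenset(c.member_ids) for c in clusters}
        assert members == {frozenset({"anc", "near"}), frozenset({"far"})}

    def test_coverage_threshold_separates_partial_overlap(self, rng):
        core = random_dna(rng, 5000)
        seq_a = core + random_dna(rng, 5000)
        seq_b = sy.mutate_to_ani(core, 0.97, seed=3) + random_dna(rng, 5000)
        summary = cl.pairwise_ani(seq_a, seq_b, "a", "b")
        assert summary.ani > 95 and summary.aligned_fraction_shorter < 0.8
        clusters = cl.cluster_populations([summary], {"a": 10000, "b": 10000})
        assert len(clusters) == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            cl.cluster_populations([], [("a", 100), ("b", 100), ("a", 200)])

    def test_clustering_is_a_partition(self, rng):
        scaffolds, _ = sy.population_fixture(seed=3, sizes=(4, 3, 1), length=6000)
        clusters = cl.cluster_scaffolds(scaffolds)
        seen = [m for c in clusters for m in c.member_ids]
        assert sorted(seen) == sorted(scaffolds)

    def test_representative_is_longest_member(self, rng):
        long_seq = random_dna(rng, 12000)
        short_seq = sy.mutate_to_ani(long_seq, 0.97, seed=4)[:10000]
        clusters = cl.cluster_scaffolds({"short": short_seq, "long": long_seq})
        assert len(clusters) == 1
        assert clusters[0].representative_id == "long"


class TestCsclRetention:
    @pytest.mark.parametrize(
        "cscl,expected",
        [
            ({"rep": True, "member": False}, ["member", "rep"]),
            ({"rep": False, "member": True}, ["rep"]),
            ({"rep": False, "member": False}, ["member", "rep"]),
        ],
    )
    def test_cscl_scaffolds_survive_only_as_representatives(self, cscl, expected):
        cluster = cl.PopulationCluster(
            cluster_id="VC0001",
            member_ids=["rep", "member"],
            representative_id="rep",
            from_cscl=cscl,
        )
        assert cl.apply_cscl_retention([cluster]) == expected


class TestMergeAmgScaffolds:
    @pytest.fixture()
    def overlapping_pair(self, rng):
        full = random_dna(rng, 14000)
        return full, full[:8000], full[6000:]

    def test_merge_reconstructs_full_sequence(self, overlapping_pair):
        full, a, b = overlapping_pair
        merged, records = cl.merge_amg_scaffolds(
            {"sa": a, "sb": b}, {"sa": "nirA", "sb": "nirA"}
        )
        (record,) = records
        assert record.merged and record.merged_id.endswith("E")
        assert record.overlap_length == 2000
        assert merged[record.merged_id] == full

    def test_short_overlap_not_merged(self, overlapping_pair):
        full, a, _ = overlapping_pair
        b = full[7100:]
        merged, records = cl.merge_amg_scaffolds(
            {"sa": a, "sb": b}, {"sa": "nirA", "sb": "nirA"}
        )
        assert sorted(merged) == ["sa", "sb"]
        assert records and not records[0].merged
        assert "overlap" in records[0].reason

    def test_gap_fill_takes_base_over_n(self, overlapping_pair):
        full, a, b = overlapping_pair
        a_gapped = a[:7000] + "N" * 20 + a[7020:]
        merged, records = cl.merge_amg_scaffolds(
            {"sa": a_gapped, "sb": b}, {"sa": "nirA", "sb": "nirA"}
        )
        (record,) = records
        assert record.merged and len(record.gap_fills) == 20
        assert merged[record.merged_id] == full
        assert "N" not in merged[record.merged_id][6999:7020]

    def test_merging_never_decreases_non_n_bases(self, overlapping_pair):
        full, a, b = overlapping_pair
        a_gapped = a[:7000] + "N" * 20 + a[7020:]
        before = max(
            a_gapped.count("A") + a_gapped.count("C") + a_gapped.count("G") + a_gapped.count("T"),
            len(b) - b.count("N"),
        )
        merged, _ = cl.merge_amg_scaffolds(
            {"sa": a_gapped, "sb": b}, {"sa": "nirA", "sb": "nirA"}
        )
        (seq,) = merged.values()
        assert len(seq) - seq.count("N") >= before

    def test_reverse_complement_partner_merged(self, overlapping_pair):
        full, a, b = overlapping_pair
        merged, records = cl.merge_amg_scaffolds(
            {"sa": a, "sb": revcomp(b)}, {"sa": "nirA", "sb": "nirA"}
        )
        (record,) = records
        assert record.merged
        assert merged[record.merged_id] == full

    def test_different_amg_symbols_never_merged(self, overlapping_pair):
        _, a, b = overlapping_pair
        merged, records = cl.merge_amg_scaffolds(
            {"sa": a, "sb": b}, {"sa": "nirA", "sb": "focA"}
        )
        assert sorted(merged) == ["sa", "sb"]
        assert all(not r.merged for r in records)
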