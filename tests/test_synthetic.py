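"""Generator correctness: layouts, determinism, ANI targeting, read truth."""

import numpy as np
import pytest

from amgkit import synthetic as sy
from amgkit.genetics import CODON_TABLE, revcomp, translate
from conftest import random_dna


def _spec_with_amg(scaffold_id="s1", length=12000, n_genes=20):
    genes = []
    pos = 301
    for i in range(n_genes):
        gene_len = 450
        category = "amg" if i == 4 else "viral_like"
        genes.append(
            sy.Gene(
                gene_id=f"g{i:02d}",
                start=pos,
                end=pos + gene_len - 1,
                strand="+" if i % 3 else "-",
                category=category,
                amg_symbol="nirA" if category == "amg" else None,
            )
        )
        pos += gene_len + 100
    assert pos < length
    return sy.GenomeSpec(scaffold_id=scaffold_id, length=length, genes=genes)


class TestGenerateScaffolds:
    def test_lengths_and_gene_counts_match_spec(self):
        spec = _spec_with_amg()
        scaffolds, gene_table, truth = sy.generate_scaffolds([spec], seed=1)
        assert len(scaffolds["s1"]) == 12000
        assert len(gene_table) == 20
        assert truth.scaffolds.iloc[0]["amg_symbols"] == "nirA"

    def test_same_seed_reproduces_identical_outputs(self):
        spec = _spec_with_amg()
        s1, t1, _ = sy.generate_scaffolds([spec], seed=7)
        s2, t2, _ = sy.generate_scaffolds([_spec_with_amg()], seed=7)
        assert s1 == s2
        assert t1.equals(t2)
        s3, _, _ = sy.generate_scaffolds([_spec_with_amg()], seed=8)
        assert s3 != s1

    def test_overlapping_genes_rejected(self):
        genes = [
            sy.Gene("a", 100, 200, "+"),
            sy.Gene("b", 150, 250, "+"),
        ]
        spec = sy.GenomeSpec("bad", 1000, genes=genes)
        with pytest.raises(sy.LayoutError, match="overlap"):
            sy.generate_scaffolds([spec], seed=0)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_amg_genes_are_real_orfs(self, strand):
        gene = sy.Gene("amg1", 501, 501 + 423 - 1, strand, "amg", "glnK")
        spec = sy.GenomeSpec("s", 2000, genes=[gene])
        scaffolds, _, _ = sy.generate_scaffolds([spec], seed=3)
        segment = scaffolds["s"][500 : 500 + 423]
        cds = segment if strand == "+" else revcomp(segment)
        protein = translate(cds)
        assert protein.startswith("M")
        assert protein.endswith("*")
        assert "*" not in protein[:-1]

    def test_circular_scaffold_has_terminal_repeat(self):
        spec = sy.GenomeSpec("c", 5000, circular=True)
        scaffolds, _, _ = sy.generate_scaffolds([spec], seed=5)
        assert scaffolds["c"][:30] == scaffolds["c"][-30:]


class TestMutateToAni:
    def test_identity_target_returns_same_sequence(self, rng):
        seq = random_dna(rng, 5000)
        assert sy.mutate_to_ani(seq, 1.0, seed=0) == seq

    @pytest.mark.parametrize("target,lo,hi", [(0.95, 480, 520), (0.90, 980, 1020)])
    def test_mismatch_count_matches_target(self, rng, target, lo, hi):
        seq = random_dna(rng, 10000)
        mutated = sy.mutate_to_ani(seq, target, seed=2)
        mismatches = sum(a != b for a, b in zip(seq, mutated))
        assert lo <= mismatches <= hi
        assert len(mutated) == len(seq)

    def test_target_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            sy.mutate_to_ani(random_dna(rng, 2000), 0.5, seed=0)


class TestSimulateReads:
    def test_read_count_tracks_depth_target(self, rng):
        scaffolds = {"s": random_dna(rng, 50000)}
        reads, placements, _ = sy.simulate_reads(
            scaffolds, sy.ReadSimSpec(depth_target=20, read_length=150, seed=1)
        )
        assert len(reads) == pytest.approx(20 * 50000 / 150, rel=0.10)
        depth = np.zeros(50001)
        for row in placements.itertuples(index=False):
            depth[row.start - 1] += 1
            depth[row.end] -= 1
        assert np.cumsum(depth)[:-1].mean() == pytest.approx(20, rel=0.10)

    def test_error_free_reads_match_reference(self, rng):
        seq = random_dna(rng, 4000)
        reads, placements, _ = sy.simulate_reads(
            {"s": seq}, sy.ReadSimSpec(depth_target=5, seed=2)
        )
        seqs = dict((r[0], r[1]) for r in reads)
        for row in placements.itertuples(index=False):
            window = seq[row.start - 1 : row.end]
            observed = seqs[row.read_id]
            if row.strand == "-":
                observed = revcomp(observed)
            assert observed == window

    def test_injected_snps_recovered_at_allele_frequency(self):
        gene = sy.Gene("g1", 301, 301 + 999 - 1, "+", "amg", "focA")
        spec = sy.GenomeSpec("s", 3000, genes=[gene])
        scaffolds, gene_table, _ = sy.generate_scaffolds([spec], seed=4)
        rspec = sy.ReadSimSpec(
            depth_target=60,
            snp_spec=[sy.SnpSpec("g1", n_syn=7, n_nonsyn=0, allele_freq=0.5)],
            seed=5,
        )
        reads, placements, truth = sy.simulate_reads(scaffolds, rspec, gene_table)
        assert len(truth.snps) == 7
        assert set(truth.snps["classification"]) == {"synonymous"}
        seqs = dict((r[0], r[1]) for r in reads)
        for snp in truth.snps.itertuples(index=False):
            alt = total = 0
            for row in placements.itertuples(index=False):
                if not row.start <= snp.scaffold_position <= row.end:
                    continue
                seq = seqs[row.read_id]
                if row.strand == "-":
                    seq = revcomp(seq)
                base = seq[snp.scaffold_position - row.start]
                total += 1
                alt += base == snp.alt_base
            # 3 sigma binomial bound at the realized depth
            sigma = np.sqrt(0.25 * total)
            assert abs(alt - 0.5 * total) < 3 * sigma + 1

    def test_snp_classification_consistent_with_genetic_code(self):
        gene = sy.Gene("g1", 1, 999, "-", "amg", "nirK")
        spec = sy.GenomeSpec("s", 2000, genes=[gene])
        scaffolds, gene_table, _ = sy.generate_scaffolds([spec], seed=9)
        rspec = sy.ReadSimSpec(
            depth_target=5,
            snp_spec=[sy.SnpSpec("g1", n_syn=3, n_nonsyn=3, allele_freq=0.4)],
            seed=9,
        )
        _, _, truth = sy.simulate_reads(scaffolds, rspec, gene_table)
        cds = revcomp(scaffolds["s"][:999])
        for snp in truth.snps.itertuples(index=False):
            pos0 = snp.cds_position - 1
            ci = pos0 // 3
            codon = cds[3 * ci : 3 * ci + 3]
            assert codon[pos0 % 3] == snp.cds_ref_base
            mutated = list(codon)
            mutated[pos0 % 3] = snp.cds_alt_base
            same_aa = CODON_TABLE["".join(mutated)] == CODON_TABLE[codon]
            assert same_aa == (snp.classification == "synonymous")

    def test_too_low_depth_warns_and_returns_empty(self, rng):
        scaffolds = {"s": random_dna(rng, 1500)}
        with pytest.warns(UserWarning, match="no reads"):
            reads, placements, _ = sy.simulate_reads(
                {"s": scaffolds["s"]},
                sy.ReadSimSpec(depth_target=0.01, read_length=150, seed=0),
            )
        assert reads == [] and len(placements) == 0


class TestVirome:
    def test_truth_closure_every_scaffold_has_one_population(self, virome):
        truth = virome.truth.scaffolds
        assert truth["scaffold_id"].is_unique
        assert set(truth["scaffold_id"]) == set(virome.scaffolds)

    def test_motif_truth_sites_present_in_sequence(self, virome):
        for row in virome.truth.motifs.itertuples(index=False):
            window = virome.scaffolds[row.scaffold_id][row.start - 1 : row.end]
            assert window.startswith("GTA") and window.endswith("TAC")

    def test_virome_is_deterministic(self, virome):
        again = sy.simulate_virome(seed=11)
        assert again.scaffolds == virome.scaffolds
        assert again.gene_table.equals(virome.gene_table)
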