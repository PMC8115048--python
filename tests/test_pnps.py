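"""Expected-site counting vs the nine-substitution oracle, SNP calling gates,
and end-to-end pN/pS recovery from simulated reads."""

import itertools
import math

import pandas as pd
import pytest

from amgkit import pnps as pp
from amgkit import synthetic as sy
from amgkit.genetics import BASES, CODON_TABLE, revcomp


def oracle_sites(codon):
    """Enumerate all nine single-base substitutions of a codon."""
    syn = 0
    aa = CODON_TABLE[codon]
    for j, alt in itertools.product(range(3), BASES):
        if alt == codon[j]:
            continue
        if CODON_TABLE[codon[:j] + alt + codon[j + 1 :]] == aa:
            syn += 1
    return 3 - syn / 3, syn / 3


SENSE_CODONS = sorted(c for c, aa in CODON_TABLE.items() if aa != "*")


class TestExpectedSites:
    @pytest.mark.parametrize(
        "codon,n_sites,s_sites",
        [("ATG", 3.0, 0.0), ("TTT", 8 / 3, 1 / 3), ("GGG", 2.0, 1.0)],
    )
    def test_worked_codon_examples(self, codon, n_sites, s_sites):
        table = pp.expected_sites(codon)
        assert table.n_sites == pytest.approx(n_sites)
        assert table.s_sites == pytest.approx(s_sites)

    @pytest.mark.parametrize("codon", SENSE_CODONS)
    def test_every_sense_codon_matches_nine_substitution_oracle(self, codon):
        table = pp.expected_sites(codon)
        n_exp, s_exp = oracle_sites(codon)
        assert table.n_sites == pytest.approx(n_exp)
        assert table.s_sites == pytest.approx(s_exp)
        assert table.n_sites + table.s_sites == pytest.approx(3.0)

    def test_two_codon_gene_totals(self):
        table = pp.expected_sites("ATGTTT")
        assert table.n_sites == pytest.approx(17 / 3)
        assert table.s_sites == pytest.approx(1 / 3)

    def test_terminal_stop_excluded_from_totals(self):
        with_stop = pp.expected_sites("ATGTTTTAA")
        without = pp.expected_sites("ATGTTT")
        assert with_stop.n_sites == pytest.approx(without.n_sites)
        assert with_stop.s_sites == pytest.approx(without.s_sites)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="internal stop"):
            pp.expected_sites("ATGTAAATG")

    def test_non_triplet_length_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            pp.expected_sites("ATGA")


def _pileup(rows):
    return pd.DataFrame(rows, columns=["cds_position", "A", "C", "G", "T"])


class TestCallVariants:
    CDS = "ATGTTTAAACTG"

    def test_half_frequency_snp_called(self):
        pile = _pileup([(6, 0, 25, 0, 25)])  # TTT third position, T->C
        (call,) = pp.call_variants(pile, self.CDS)
        assert call.alt_fraction == pytest.approx(0.5)
        assert call.classification == "synonymous"  # TTC is still Phe

    def test_depth_below_gate_not_called(self):
        pile = _pileup([(6, 0, 4, 0, 4)])
        assert pp.call_variants(pile, self.CDS) == []

    def test_nonsynonymous_classification(self):
        pile = _pileup([(5, 0, 30, 0, 70)])  # TTT -> TCT, Phe -> Ser
        (call,) = pp.call_variants(pile, self.CDS)
        assert call.classification == "nonsynonymous"

    def test_min_alt_reads_gate(self):
        pile = _pileup([(6, 0, 1, 0, 199)])
        assert pp.call_variants(pile, self.CDS) == []

    def test_multiallelic_site_counts_each_allele(self):
        pile = _pileup([(6, 10, 10, 0, 80)])
        calls = pp.call_variants(pile, self.CDS)
        assert len(calls) == 2
        assert {c.alt_base for c in calls} == {"A", "C"}

    def test_position_beyond_cds_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            pp.call_variants(_pileup([(13, 10, 0, 0, 10)]), self.CDS)


class TestPnps:
    def test_single_synonymous_snp_gives_zero_ratio(self):
        sites = pp.expected_sites("ATGTTT")
        variants = [pp.VariantCall("g", 6, "T", "C", 50, 0.5, "synonymous")]
        result = pp.pnps("g", variants, sites, min_gene_coverage=50)
        assert result.ps == pytest.approx(3.0)  # 1 / (1/3)
        assert result.ratio == 0.0
        assert result.purifying

    def test_mixed_snps_ratio_arithmetic(self):
        sites = pp.expected_sites("ATGTTT")
        variants = [
            pp.VariantCall("g", 5, "T", "C", 50, 0.4, "nonsynonymous"),
            pp.VariantCall("g", 6, "T", "C", 50, 0.5, "synonymous"),
        ]
        result = pp.pnps("g", variants, sites, min_gene_coverage=50)
        assert result.pn == pytest.approx(3 / 17)
        assert result.ratio == pytest.approx((3 / 17) / 3.0)
        assert result.purifying

    def test_no_synonymous_snps_leaves_ratio_undefined(self):
        sites = pp.expected_sites("ATGTTT")
        variants = [pp.VariantCall("g", 5, "T", "C", 50, 0.4, "nonsynonymous")]
        result = pp.pnps("g", variants, sites, min_gene_coverage=50)
        assert math.isnan(result.ratio)
        assert not result.purifying

    def test_low_coverage_result_suppressed(self):
        sites = pp.expected_sites("ATGTTT")
        variants = [pp.VariantCall("g", 6, "T", "C", 9, 0.5, "synonymous")]
        result = pp.pnps("g", variants, sites, min_gene_coverage=9)
        assert result.suppressed and not result.purifying
        table = pp.pnps_table([result])
        assert math.isnan(table.loc[0, "ratio"])

    def test_ratio_invariant_under_uniform_depth_scaling(self):
        sites = pp.expected_sites("ATGTTTAAACTG")
        for scale in (1, 2, 10):
            variants = [
                pp.VariantCall("g", 6, "T", "C", 50 * scale, 0.5, "synonymous"),
                pp.VariantCall("g", 5, "T", "C", 50 * scale, 0.3, "nonsynonymous"),
            ]
            result = pp.pnps("g", variants, sites, min_gene_coverage=50 * scale)
            assert result.ratio == pytest.approx(
                (1 / sites.n_sites) / (1 / sites.s_sites)
            )


def _run_pipeline(n_syn, n_nonsyn, seed, depth=50):
    """Simulate reads over a 999-nt gene and recover pN/pS end to end."""
    gene = sy.Gene("g1", 501, 501 + 999 - 1, "+", "amg", "focA")
    spec = sy.GenomeSpec("s", 2500, genes=[gene])
    scaffolds, gene_table, _ = sy.generate_scaffolds([spec], seed=seed)
    rspec = sy.ReadSimSpec(
        depth_target=depth,
        snp_spec=[sy.SnpSpec("g1", n_syn=n_syn, n_nonsyn=n_nonsyn, allele_freq=0.5)],
        seed=seed,
    )
    reads, placements, truth = sy.simulate_reads(scaffolds, rspec, gene_table)
    pile = pp.pileup_from_placements(reads, placements, "s", 501, 1499, "+")
    cds = scaffolds["s"][500:1499]
    variants = pp.call_variants(pile, cds)
    sites = pp.expected_sites(cds)
    min_cov = float(pile[list(BASES)].sum(axis=1).min())
    return pp.pnps("g1", variants, sites, min_gene_coverage=min_cov), truth, sites


class TestEndToEndRecovery:
    def test_pure_synonymous_snps_give_ratio_exactly_zero(self):
        result, truth, _ = _run_pipeline(n_syn=7, n_nonsyn=0, seed=21)
        assert result.n_snps == 7
        assert result.s_obs == 7 and result.n_obs == 0
        assert result.ratio == 0.0
        assert result.purifying
        assert result.min_gene_coverage > 10

    def test_mixed_snps_recover_analytic_ratio(self):
        result, truth, sites = _run_pipeline(n_syn=12, n_nonsyn=1, seed=22)
        analytic = (1 / sites.n_sites) / (12 / sites.s_sites)
        assert result.ratio == pytest.approx(analytic, rel=0.15)
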