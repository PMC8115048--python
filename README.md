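# amgkit

Analysis toolkit for discovering and validating **nitrogen-cycle auxiliary
metabolic genes (AMGs)** in viral metagenomes — the kinds of genes (e.g.
*focA*, *nirA*, *nirK*, *norB*, *amoC*, *glnK*) that phages carry from their
microbial hosts and may express during infection, rewiring nitrogen cycling
in oxygen-depleted oceanic waters.

It is written for virome bioinformaticians who want the analytical core of
an AMG survey as a tested, importable library rather than a stack of
one-off wrapper scripts. Every stage can be exercised end-to-end on a
built-in synthetic virome generator with ground truth, so nothing requires
downloading external datasets.

## What it computes

- **Population clustering** — viral populations defined as scaffolds sharing
  ≥ 95% average nucleotide identity (ANI) over ≥ 80% of the shorter
  sequence; ANI from consolidated local alignment blocks (seed-and-chain +
  edit-distance alignment), greedy longest-first centroid clustering,
  CsCl-sample retention rules, and merging of AMG-sharing scaffolds that
  overlap > 1 kb at ≥ 99% identity (with N-gap filling).
- **Viral triage** — scaffolds > 5 kb (or circular and > 1.5 kb) are viral
  when an external classifier supports them (category ∈ {1,2}, or
  score > 0.9 with p < 0.05); AMGs are only reported from scaffolds ≥ 10 kb.
- **Annotation-confidence ranking** — the A–E scale over KEGG / UniRef90 /
  InterPro homology evidence (A: reciprocal KEGG hit, bitscore > 350 … E:
  best bitscore < 60), plus catalog-driven shortlisting of N-cycle genes.
- **Regulatory motifs** — exhaustive scanning for the NtcA consensus
  GTA-N8-TAC, positional filtering (intergenic or within 10 bp of a gene
  boundary), and score gates for external promoter (LDF > 2.75) and
  terminator (confidence > 90%) calls.
- **Abundance profiling** — per-base depth from SAM/BAM or placement
  tables; coverage as the trimmed mean (*tpmean*, 10% trimmed per side);
  detection requires breadth ≥ 80% and tpmean ≥ 5×; coverages normalised
  per Gb of sample sequencing.
- **Selection analysis** — per-gene pN/pS from pileups:
  `pN = n_obs / N_sites`, `pS = s_obs / S_sites`, with expected site counts
  from per-codon enumeration of all nine single-base substitutions; a
  ratio < 0.3 is read as strong purifying selection (10× minimum gene
  coverage gate).
- **Denitrification bioenergetics** — ΔG°′ of each denitrification step
  (NO₃⁻ → NO₂⁻ → NO → N₂O → N₂) coupled to pyruvate oxidation, standardized
  per mol of electron acceptor, from half-reaction stoichiometry and an
  editable formation-energy constants table.
- **Synthetic virome generator** — phage-like scaffolds with gene layouts,
  AMG cassettes with planted NtcA sites, population variants at controlled
  ANI, and reads carrying strain SNPs with controlled
  synonymous/non-synonymous composition, depth, and allele frequency — all
  with truth tables.

## Worked example

Selection analysis on a simulated 999-nt viral *focA* gene carrying seven
strain SNPs, all synonymous, at 50% allele frequency
(`python examples/07_pnps_selection.py`):

```
SNPs called: 7 (7 syn, 0 nonsyn)
expected sites: N=750.3  S=245.7
pN=0.0000  pS=0.0285  pN/pS=0.0000
min gene coverage: 41x  purifying selection: True
```

All seven SNPs are recovered from the pileup and classified synonymous, so
pN/pS is exactly 0 — polymorphism that never changes the protein, the
signature of strong purifying selection on a functional gene.

Denitrification energetics (`python examples/08_denitrification_thermo.py`):

```
                         step      acceptor  electrons  dG kJ/mol acceptor  dG kJ/e-
           nitrate_to_nitrite       nitrate          2             -131.00    -65.50
      nitrite_to_nitric_oxide       nitrite          1             -105.00   -105.00
nitric_oxide_to_nitrous_oxide  nitric_oxide          1             -139.00   -139.00
  nitrous_oxide_to_dinitrogen nitrous_oxide          2             -314.00   -157.00
             complete_pathway       nitrate          5             -532.00   -106.40
```

Every step is exergonic, so even partial denitrifiers occupying a single
step gain energy; the pathway total equals the chained step sum (the N₂O
step weighted ½ per mol nitrate) by Hess's law.

The other `examples/*.py` scripts each demonstrate one capability
(simulation, clustering, triage, ranking, motifs, abundance). A thin CLI
(`amgkit simulate|cluster|triage|annotate-rank|motifs|abundance|pnps|thermo`)
wraps the same library functions for shell use.

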