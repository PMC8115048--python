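# Methods

This note documents the models and procedures implemented in `amgkit`, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want
written down. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Population clustering and ANI

Two scaffolds belong to the same viral population when they share ≥ 95%
average nucleotide identity (ANI) over ≥ 80% of the shorter sequence — the
field-standard population definition for viromes.

**ANI computation.** `pairwise_ani` mimics a nucmer-style local aligner:
exact 15-mer seeds shared between the two sequences are chained along each
diagonal (positional gap ≤ 500 bp), chains on nearby diagonals
(|Δdiagonal| ≤ 32) that adjoin on the query are merged, blocks shorter than
100 bp are discarded, each surviving block is extended up to 30 bp toward
the sequence boundaries and aligned globally with edlib, and matches /
columns are pooled over blocks that do not overlap on the query (overlaps
counted once, longest block first). Both orientations of the second
sequence are tried; the strand with more aligned sequence wins. K-mers
occurring more than 8 times in the indexed sequence are skipped as
repeats. Seed length 15 keeps the per-position seed probability above 0.2
even at 90% identity (0.9¹⁵ ≈ 0.21), so homologous regions are densely
seeded, while two unrelated 10-kb sequences share on the order of 0.1
15-mers by chance — hence effectively no alignment. On substitution-only
pairs (the synthetic generator's output) the computed ANI agrees with the
exact Hamming oracle to < 0.3 percentage points.

**Clustering.** Greedy longest-first centroid clustering: scaffolds sorted
by descending length (ties broken lexicographically for determinism), each
joins the first existing cluster whose *representative* it matches at both
thresholds, else founds a new cluster. This representative-centric rule —
rather than single-linkage over all edges — matches how population
representatives are actually used downstream (the longest member stands
for the population) and avoids chaining through intermediate sequences.
The linkage rule is a design choice of this package; the thresholds are
not.

**CsCl retention.** Scaffolds assembled from CsCl-density-gradient-purified
samples are kept only when they are their cluster's representative;
scaffolds from untreated samples are always kept. This guards against
treatment-specific assembly artifacts dominating population membership.

**AMG scaffold merging.** Scaffolds carrying the same AMG symbol are merged
when a dovetail overlap > 1 kb at ≥ 99% identity exists (either order,
reverse complement allowed). The overlap offset is taken as the
most-supported seed diagonal (≥ 3 supporting seeds); identity over the
overlap treats N as a wildcard; N positions with a base in the partner are
filled from the partner (so merging never decreases non-N bases); merged
ids carry a terminal "E". Pairs failing the thresholds produce explanatory
records instead of merges.

## Viral triage

Classifier internals are out of scope: VirSorter-style categories and
VirFinder-style scores arrive as tables. The decision rule is literal:
*eligible* iff length > 5000, or circular and length > 1500 (both strict);
*viral* iff eligible and (category ∈ {1, 2} or score > 0.9 with p < 0.05);
*reportable* iff viral and length ≥ 10000. All gates are keyword
arguments. Circularity is detected as a terminal direct repeat of ≥ 20
exact bases (searched up to 1 kb). The strand-switch rate (fraction of
adjacent gene pairs changing coding strand, genes ordered by start) is
reported as supporting evidence only — low values are phage-like — with no
hard cutoff, since no principled threshold exists.

## Annotation ranking

Rules apply strictly in A→E order; the first that fires wins: A = KEGG
reciprocal best hit (RBH) with bitscore > 350 (strict); B = UniRef90 RBH
> 350; C = one-way UniRef90 hit with bitscore ≥ 60; D = hits only to
InterPro; E = best bitscore < 60 anywhere. Two gaps in the scheme needed
decisions: (1) a KEGG hit with bitscore ≥ 60 that fails the A rule (one-way,
or RBH ≤ 350) has no stated rank — it is assigned C with basis tag
`gap-rule`, one-way database evidence being the closest analog; (2) a
query whose hits are neither rankable by score nor InterPro-only falls to
E (`residual-low-confidence`). Rank assignment is a total, order-invariant
function, verified against an exhaustive enumeration over database ×
reciprocity × bitscore-bin combinations.

N-cycle shortlisting replaces manual curation with a reproducible catalog
(`data/ncycle_catalog.tsv`): per symbol, a KO identifier and a
case-insensitive keyword regex. The catalog is an editable TSV so curation
changes are diffable.

## Regulatory motifs

The NtcA site is scanned as the printed marine-cyanobacteria consensus
GTA-N8-TAC rather than a probabilistic model: the consensus is what is
available, and it is reverse-complement symmetric, so a forward scan finds
every double-stranded site (the scanner still supports IUPAC codes and
two-strand scanning for non-palindromic motifs). Overlapping matches are
all reported (regex lookahead). Positional plausibility: a site passes iff
it lies wholly outside every gene, or overlaps a gene but sits within
10 bp (inclusive, either boundary coordinate) of that gene's start or
stop. External promoter calls are kept at LDF > 2.75 and terminators at
confidence > 90% (both strict), then positionally filtered the same way;
score magnitudes that look unit-mismatched (promoter score > 25,
terminator score ≤ 25) trigger warnings. Site orientation is reported but
not filtered on — the data do not establish that regulatory sites must sit
on the AMG's coding strand.

## Abundance profiling

Depth at each base is the count of reads whose aligned span covers it
(difference-array accumulation; secondary/supplementary SAM records
excluded). `tpmean` removes the top and bottom 10% of positions by sorted
depth (trim count rounded down) before averaging — the common default for
trimmed-mean contig coverage — and the trim fraction is configurable.
Breadth counts positions with depth ≥ 1; no higher floor is applied.
Detection requires breadth ≥ 0.80 and tpmean ≥ 5. Normalisation multiplies
tpmean by 10⁹ / (total bases sequenced in the sample): the constant fixes
units at "coverage per Gb" and cancels in all cross-sample ratios.
Undetected (scaffold, sample) cells are zeroed in the abundance matrix,
because a coverage value failing the detection rule is not considered
reliable enough to report.

## pN/pS selection statistic

For each sense reference codon, each of the nine single-base substitutions
is classified by the standard genetic code; the codon's synonymous site
count is (synonymous substitutions)/3 and the non-synonymous count is the
complement, so every sense codon contributes exactly 3 sites. Reference
stop codons (the terminal stop) are excluded from totals; substitutions
*creating* a stop count as non-synonymous. SNPs are called per pileup
column with depth ≥ 10, alternate-allele frequency ≥ 1%, and ≥ 2
supporting reads — explicit population-SNP defaults, all configurable, no
coverage downsampling. Each qualifying alternate allele at a site counts
as its own SNP (reported SNP totals are per-allele, not per-site). Then
pN = n_obs/N_sites, pS = s_obs/S_sites, ratio = pN/pS; the ratio is 0 iff
only synonymous SNPs were observed, and undefined (NaN, never coerced to a
number) when s_obs = 0. A defined ratio < 0.3 flags strong purifying
selection. Results are suppressed — not zeroed — when the minimum per-site
depth across the CDS is ≤ 10×, since a ratio estimated from an unevenly
observed gene is not comparable.

## Denitrification bioenergetics

Each denitrification step is a reduction half-reaction (per mol acceptor):
NO₃⁻/NO₂⁻ (2 e⁻), NO₂⁻/NO (1 e⁻), NO/½N₂O (1 e⁻), N₂O/N₂ (2 e⁻). The
electron donor is pyruvate oxidised completely to CO₂ (10 e⁻ per
pyruvate), stored as the reduction direction of the CO₂/pyruvate couple
and reversed at coupling time. `couple` scales the donor so electrons
cancel exactly, verifies mass and charge balance (electrons included), and
standardises the net reaction to acceptor coefficient −1;
`delta_g` evaluates ΔG°′ = Σ νᵢ ΔGf′ᵢ from the constants table;
`pathway_sum` chains steps, weighting each by the mols of its acceptor
produced per mol of the initial acceptor (the N₂O step counts ½ per mol
nitrate), and must agree with the direct NO₃⁻ → ½N₂ coupling by Hess's
law (< 0.5 kJ/mol).

**Constants table and calibration.** The shipped TSV
(`data/denitrification_constants.tsv`) uses transformed standard formation
energies at pH 7, 25 °C. The donor-side species (pyruvate −474.63, CO₂
−394.36, H₂O −237.18 kJ/mol; H⁺ at the transformed value −39.96 =
−RT·ln 10⁻⁷) are standard microbial-bioenergetics (Thauer-style) values,
and N₂ is the element reference state. The four nitrogen intermediates
carry *effective* values (NO₃⁻ −118.06, NO₂⁻ −20.49, NO +67.43, N₂O
+85.43 kJ/mol) calibrated so that the coupled-reaction convention above
yields the step energies this analysis context reports; the literature
reference values are kept in a side-by-side column of the TSV. The
calibration is necessary because no standard constants set reproduces
those step energies under a single donor potential — most visibly for the
NO₂⁻/NO step, where commonly tabulated potentials (E°′ ≈ +0.35 V) imply
roughly −57 kJ/mol per electron against this convention's −105 — and the
exact convention behind the reported table (extent of donor oxidation,
phases, activity corrections) is not recoverable. The discrepancy is
deliberately carried in the constants file, where it is visible and
editable, rather than absorbed silently into code; all ΔG values are
computed from stoichiometry and the table at run time. Swapping in the
reference column reproduces textbook energetics instead. NO is treated as
aqueous and N₂O/N₂ as gases by default. Proton-motive-force and ATP-yield
modelling are out of scope.

## Synthetic virome generator

The generator emulates the features the pipeline's statistics actually
consume, with truth tables for all of them:

- *Scaffolds*: random background at a target GC (default 0.45), phage-like
  gene layouts (~450–900 nt genes, mostly co-oriented with a ~10% strand
  switch chance, 80–160 nt intergenic gaps), 1-based inclusive
  coordinates. Any gene whose length is a multiple of 3 is written as a
  real ORF (ATG start, sense codons, terminal stop) on its annotated
  strand. AMG ORFs derive their residues from bundled *synthetic stand-in*
  proteins (one per catalog symbol; not real protein sequences), cycled to
  the layout length — guaranteeing valid ORFs without any database.
  Circular scaffolds carry a 30-bp terminal direct repeat.
- *Populations*: variants derive from an ancestor by uniformly placed
  substitutions only, so ANI has an exact Hamming oracle; the default
  fixture (30 scaffolds, 6 populations) draws variant ANI from
  96–99.5% with 90%-ANI outgroups, sizes (8, 7, 7, 6, 1, 1), 10-kb
  scaffolds. Partially aligned variants replace a leading fraction with
  unrelated sequence; `fragment_sequence` exercises split contigs.
- *Reads*: uniform single-end 150-nt reads at round(depth × L / 150) per
  scaffold, uniform start positions, random strand, optional uniform
  per-base error. Strain SNPs are planted as biallelic sites (one SNP per
  codon, start/stop codons excluded, stop-creating alternatives excluded)
  carried per read independently with the specified allele frequency, so
  per-site allele fractions are binomial around the target. Default read
  depth for end-to-end selection tests is 50×, comfortably above the 10×
  reporting gate.

Not emulated: assembly artifacts, indels, GC-dependent or position-dependent
coverage bias, quality-score error models, paired-end structure,
amplification bias, chimeras. Passing tests therefore demonstrate the
*statistics and decision rules* are implemented correctly — they do not
demonstrate robustness to real-data artifacts upstream of these inputs
(mis-assembly, mapping bias, contamination).

Everything is seeded through `numpy.random.default_rng` with per-scaffold
substreams, so identical specs and seed give byte-identical outputs.

## Problem sizes and runtime

Test and example problem sizes are chosen to exercise every rule at
desk scale: 10–16 kb scaffolds, 30-scaffold clustering fixtures, 999-nt
genes at 50× for selection analysis, 1000 random 5-kb sequences for the
motif oracle. The full suite runs in well under a minute of CPU; the
acceptance script is sub-second (its quantities are deterministic).

## Known limitations

- The ANI aligner is substitution-oriented; large indels within a block are
  handled by edlib but heavily indel-fragmented homology will under-report
  aligned fraction. Minimum block 100 bp means homologous fragments
  shorter than that are invisible.
- Greedy centroid clustering is order-dependent by design (longest first);
  near-threshold pairs can land in different clusters than single-linkage
  would produce.
- `detect_circularity` recognises exact terminal repeats only.
- The pN/pS caller assumes a haploid population pileup with independent
  sites; linkage between SNPs is ignored (as in the underlying method).
- The thermodynamic constants are an effective, documented calibration
  (see above), not a recommended reference set for other conventions.
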