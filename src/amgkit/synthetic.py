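"""Synthetic virome generator with ground truth.

Everything downstream of assembly in an AMG survey — population clustering,
viral triage, annotation ranking, motif scanning, abundance profiling, and
pN/pS selection analysis — can be exercised on data produced here, with a
truth table recording what was put in: population membership, AMG placements,
regulatory-motif positions, per-gene synonymous / non-synonymous SNPs, and
per-scaffold read depths.

Design notes
------------
* Population variants are produced by substitutions only, so average
  nucleotide identity (ANI) has an exact Hamming oracle; indel-tolerant
  alignment is exercised separately via :func:`fragment_sequence`.
* Strain-level SNPs are injected as biallelic sites carried by reads with a
  controlled allele frequency — they are genuine haplotype variants, not
  sequencing errors, so pN/pS recovery is well-posed.
* AMG coding sequences are back-translated from bundled synthetic stand-in
  proteins (one per catalog symbol, ``data/amg_proteins_synthetic.fasta``),
  guaranteeing real ORFs (ATG start, in-frame, no internal stop) without any
  external database.
* All table coordinates are 1-based inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO

from amgkit.genetics import (
    AA_TO_CODONS,
    BASES,
    CODON_TABLE,
    STOP_CODONS,
    revcomp,
)

__all__ = [
    "Gene",
    "GenomeSpec",
    "PopulationSpec",
    "SnpSpec",
    "ReadSimSpec",
    "TruthTable",
    "LayoutError",
    "load_amg_proteins",
    "generate_scaffolds",
    "mutate_to_ani",
    "fragment_sequence",
    "generate_population",
    "population_fixture",
    "simulate_reads",
    "simulate_virome",
    "NTCA_CONSENSUS",
]

NTCA_CONSENSUS = "GTA" + "N" * 8 + "TAC"

#: nitrogen-cycle AMG symbols with a bundled protein fixture
N_CYCLE_SYMBOLS = ("focA", "nirA", "nirK", "norB", "amoC", "glnK", "amtB", "ompL")

GENE_CATEGORIES = ("viral_hallmark", "viral_like", "host_like", "amg", "unknown")


class LayoutError(ValueError):
    """Raised for invalid gene layouts (overlaps, out-of-range, bad AMGs)."""


@dataclass(frozen=True)
class Gene:
    """One gene in a scaffold layout; coordinates 1-based inclusive."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    category: str = "unknown"
    amg_symbol: str | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise LayoutError(f"gene {self.gene_id}: strand must be + or -")
        if self.start < 1 or self.end < self.start:
            raise LayoutError(f"gene {self.gene_id}: bad coordinates {self.start}-{self.end}")
        if self.category not in GENE_CATEGORIES:
            raise LayoutError(f"gene {self.gene_id}: unknown category {self.category!r}")
        if self.category == "amg" and not self.amg_symbol:
            raise LayoutError(f"gene {self.gene_id}: AMG gene requires amg_symbol")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeSpec:
    """Blueprint for one synthetic phage-like scaffold."""

    scaffold_id: str
    length: int
    genes: list[Gene] = field(default_factory=list)
    circular: bool = False
    gc_fraction: float = 0.45

    def validate(self) -> None:
        if self.length < 1000:
            raise LayoutError(f"{self.scaffold_id}: length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise LayoutError(f"{self.scaffold_id}: gc_fraction outside [0,1]")
        ordered = sorted(self.genes, key=lambda g: g.start)
        prev_end = 0
        for gene in ordered:
            if gene.end > self.length:
                raise LayoutError(f"{self.scaffold_id}/{gene.gene_id}: gene beyond scaffold end")
            if gene.start <= prev_end:
                raise LayoutError(
                    f"{self.scaffold_id}/{gene.gene_id}: overlaps previous gene"
                )
            prev_end = gene.end
            if gene.category == "amg":
                if gene.amg_symbol not in load_amg_proteins():
                    raise LayoutError(
                        f"{self.scaffold_id}/{gene.gene_id}: amg_symbol "
                        f"{gene.amg_symbol!r} not in the N-cycle catalog"
                    )
                if gene.length % 3 or gene.length < 9:
                    raise LayoutError(
                        f"{self.scaffold_id}/{gene.gene_id}: AMG length must be a "
                        "multiple of 3 and >= 9 so a real ORF can be written"
                    )


@dataclass
class PopulationSpec:
    """A viral population: one ancestor plus substitution-only variants."""

    ancestor_id: str
    n_variants: int
    target_ani: float  # proportion in [0.80, 1.0]
    aligned_fraction: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.80 <= self.target_ani <= 1.0:
            raise ValueError("target_ani must be in [0.80, 1.0]")
        if not 0.0 < self.aligned_fraction <= 1.0:
            raise ValueError("aligned_fraction must be in (0, 1]")


@dataclass(frozen=True)
class SnpSpec:
    """Strain SNPs to inject into one gene's CDS."""

    gene_id: str
    n_syn: int = 0
    n_nonsyn: int = 0
    allele_freq: float = 0.5

    def __post_init__(self):
        if not 0.0 < self.allele_freq <= 1.0:
            raise ValueError("allele_freq must be in (0, 1]")
        if self.n_syn < 0 or self.n_nonsyn < 0:
            raise ValueError("SNP counts must be non-negative")


@dataclass
class ReadSimSpec:
    """Shotgun read simulation parameters."""

    depth_target: float
    read_length: int = 150
    error_rate: float = 0.0
    snp_spec: list[SnpSpec] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.depth_target <= 0:
            raise ValueError("depth_target must be > 0")
        if self.read_length < 20:
            raise ValueError("read_length must be >= 20")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class TruthTable:
    """Ground truth for everything the generator emitted."""

    scaffolds: pd.DataFrame = field(default_factory=pd.DataFrame)
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    motifs: pd.DataFrame = field(default_factory=pd.DataFrame)
    placements: pd.DataFrame = field(default_factory=pd.DataFrame)


_AMG_PROTEINS: dict[str, str] | None = None


def load_amg_proteins() -> dict[str, str]:
    """Synthetic stand-in protein per N-cycle AMG symbol (cached)."""
    global _AMG_PROTEINS
    if _AMG_PROTEINS is None:
        source = resources.files("amgkit.data") / "amg_proteins_synthetic.fasta"
        with resources.as_file(source) as path:
            _AMG_PROTEINS = {
                rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
            }
    return _AMG_PROTEINS


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=probs)


def _build_cds(rng: np.random.Generator, n_codons: int, residues: str | None) -> str:
    """ATG + (n_codons - 2) sense codons + stop; residues cycled if given."""
    if n_codons < 3:
        raise LayoutError("CDS needs at least 3 codons")
    codons = ["ATG"]
    for i in range(n_codons - 2):
        if residues:
            aa = residues[i % len(residues)]
        else:
            aa = rng.choice(list(AA_TO_CODONS))
        options = AA_TO_CODONS[aa]
        codons.append(options[rng.integers(len(options))])
    codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
    return "".join(codons)


def generate_scaffolds(
    specs: list[GenomeSpec], seed: int
) -> tuple[dict[str, str], pd.DataFrame, TruthTable]:
    """Emit scaffold sequences, a gene table, and the truth table.

    Every gene whose length is a multiple of 3 (and >= 9) is written as a real
    ORF on its annotated strand; AMG genes always are (their residues come
    from the bundled stand-in proteins). Circular scaffolds get a 30-bp
    terminal direct repeat.
    """
    proteins = load_amg_proteins()
    scaffolds: dict[str, str] = {}
    gene_rows, scaffold_rows = [], []
    for idx, spec in enumerate(specs):
        spec.validate()
        if spec.scaffold_id in scaffolds:
            raise LayoutError(f"duplicate scaffold id {spec.scaffold_id!r}")
        rng = np.random.default_rng([seed, idx])
        seq = _random_sequence(rng, spec.length, spec.gc_fraction)
        for gene in sorted(spec.genes, key=lambda g: g.start):
            if gene.length % 3 == 0 and gene.length >= 9:
                residues = None
                if gene.category == "amg":
                    residues = proteins[gene.amg_symbol][1:]  # initial Met is the ATG
                cds = _build_cds(rng, gene.length // 3, residues)
                segment = cds if gene.strand == "+" else revcomp(cds)
                seq[gene.start - 1 : gene.end] = np.frombuffer(
                    segment.encode(), dtype="S1"
                )
            gene_rows.append(
                {
                    "scaffold_id": spec.scaffold_id,
                    "gene_id": gene.gene_id,
                    "start": gene.start,
                    "end": gene.end,
                    "strand": gene.strand,
                    "category": gene.category,
                    "amg_symbol": gene.amg_symbol or "",
                }
            )
        if spec.circular and spec.length >= 60:
            seq[-30:] = seq[:30]  # terminal direct repeat marks circularity
        scaffolds[spec.scaffold_id] = seq.tobytes().decode()
        scaffold_rows.append(
            {
                "scaffold_id": spec.scaffold_id,
                "length": spec.length,
                "circular": spec.circular,
                "n_genes": len(spec.genes),
                "amg_symbols": ",".join(
                    g.amg_symbol for g in spec.genes if g.category == "amg"
                ),
            }
        )
    gene_table = pd.DataFrame(
        gene_rows,
        columns=["scaffold_id", "gene_id", "start", "end", "strand", "category", "amg_symbol"],
    )
    truth = TruthTable(scaffolds=pd.DataFrame(scaffold_rows), genes=gene_table.copy())
    return scaffolds, gene_table, truth


def mutate_to_ani(sequence: str, target_ani: float, seed: int) -> str:
    """Substitute uniformly placed bases so Hamming identity equals target_ani.

    Substitutions only — no indels — so the realized identity is exactly
    ``round(len * (1 - target_ani)) / len`` by construction.
    """
    if not 0.80 <= target_ani <= 1.0:
        raise ValueError("target_ani must be in [0.80, 1.0]")
    n_sub = round(len(sequence) * (1.0 - target_ani))
    if n_sub == 0:
        return sequence
    rng = np.random.default_rng(seed)
    positions = rng.choice(len(sequence), size=n_sub, replace=False)
    seq = np.frombuffer(sequence.encode(), dtype="S1").copy()
    for pos in positions:
        current = seq[pos].decode()
        options = [b for b in BASES if b != current]
        seq[pos] = options[rng.integers(3)].encode()
    return seq.tobytes().decode()


def fragment_sequence(sequence: str, n_fragments: int, seed: int) -> list[str]:
    """Split a sequence into contiguous fragments (for alignment exercises)."""
    if n_fragments < 1 or n_fragments > len(sequence) // 100:
        raise ValueError("n_fragments out of range")
    rng = np.random.default_rng(seed)
    cuts = np.sort(rng.choice(np.arange(100, len(sequence) - 99), size=n_fragments - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds[:-1], bounds[1:])]


def generate_population(ancestor: str, spec: PopulationSpec) -> dict[str, str]:
    """Derive variant sequences from an ancestor at the target ANI.

    With ``aligned_fraction`` < 1 the leading portion of each variant is
    replaced with unrelated random sequence, so only that fraction of the
    variant aligns to the ancestor.
    """
    spec.validate()
    variants: dict[str, str] = {}
    for k in range(spec.n_variants):
        var = mutate_to_ani(ancestor, spec.target_ani, seed=int(np.random.default_rng([spec.seed, k]).integers(2**31)))
        if spec.aligned_fraction < 1.0:
            keep = int(round(len(var) * spec.aligned_fraction))
            rng = np.random.default_rng([spec.seed, k, 1])
            noise = _random_sequence(rng, len(var) - keep, 0.45).tobytes().decode()
            var = noise + var[len(var) - keep :]
        variants[f"{spec.ancestor_id}_v{k + 1}"] = var
    return variants


def population_fixture(
    seed: int,
    sizes: tuple[int, ...] = (8, 7, 7, 6, 1, 1),
    length: int = 10000,
    variant_ani: tuple[float, float] = (0.96, 0.995),
    outgroup_ani: float = 0.90,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Scaffold set with known population structure.

    Populations of size 1 are outgroups derived at ``outgroup_ani`` from the
    first multi-member ancestor — close enough to share ancestry but below
    the 95%-ANI population threshold, so each must cluster alone.
    Returns (scaffolds, truth) with truth columns scaffold_id/population_id.
    """
    rng = np.random.default_rng(seed)
    scaffolds: dict[str, str] = {}
    rows = []
    first_ancestor: str | None = None
    for p, size in enumerate(sizes):
        pop_id = f"pop{p + 1}"
        if size == 1 and first_ancestor is not None:
            sid = f"{pop_id}_outgroup"
            scaffolds[sid] = mutate_to_ani(
                first_ancestor, outgroup_ani, seed=int(rng.integers(2**31))
            )
            rows.append({"scaffold_id": sid, "population_id": pop_id})
            continue
        ancestor = _random_sequence(
            np.random.default_rng([seed, 100 + p]), length, 0.45
        ).tobytes().decode()
        if first_ancestor is None:
            first_ancestor = ancestor
        aid = f"{pop_id}_anc"
        scaffolds[aid] = ancestor
        rows.append({"scaffold_id": aid, "population_id": pop_id})
        for k in range(size - 1):
            ani = float(rng.uniform(*variant_ani))
            sid = f"{pop_id}_v{k + 1}"
            scaffolds[sid] = mutate_to_ani(ancestor, ani, seed=int(rng.integers(2**31)))
            rows.append({"scaffold_id": sid, "population_id": pop_id})
    return scaffolds, pd.DataFrame(rows)


# -- read simulation ---------------------------------------------------------


def _snp_candidates(cds: str) -> tuple[list[tuple[int, str, str]], list[tuple[int, str, str]]]:
    """(cds_pos0, ref, alt) lists for synonymous / non-synonymous options.

    The start codon and the terminal stop are excluded; non-synonymous
    options that would create a stop are excluded so injected haplotypes stay
    valid ORFs. At most one candidate position per codon is used downstream.
    """
    syn, nonsyn = [], []
    n_codons = len(cds) // 3
    for ci in range(1, n_codons - 1):
        codon = cds[3 * ci : 3 * ci + 3]
        aa = CODON_TABLE[codon]
        for j in range(3):
            for alt in BASES:
                if alt == codon[j]:
                    continue
                mutated = codon[:j] + alt + codon[j + 1 :]
                new_aa = CODON_TABLE[mutated]
                if new_aa == aa:
                    syn.append((3 * ci + j, codon[j], alt))
                elif new_aa != "*":
                    nonsyn.append((3 * ci + j, codon[j], alt))
    return syn, nonsyn


def _pick_one_per_codon(
    rng: np.random.Generator,
    candidates: list[tuple[int, str, str]],
    n: int,
    used_codons: set[int],
) -> list[tuple[int, str, str]]:
    by_codon: dict[int, list[tuple[int, str, str]]] = {}
    for cand in candidates:
        ci = cand[0] // 3
        if ci not in used_codons:
            by_codon.setdefault(ci, []).append(cand)
    codons = sorted(by_codon)
    if len(codons) < n:
        raise ValueError(f"only {len(codons)} codons available for {n} requested SNPs")
    chosen_codons = rng.choice(codons, size=n, replace=False)
    picked = []
    for ci in sorted(int(c) for c in chosen_codons):
        options = by_codon[ci]
        picked.append(options[rng.integers(len(options))])
        used_codons.add(ci)
    return picked


def plan_snps(
    scaffolds: dict[str, str], gene_table: pd.DataFrame, spec: ReadSimSpec
) -> pd.DataFrame:
    """Choose concrete SNP sites satisfying the per-gene (n_syn, n_nonsyn) spec."""
    rows = []
    genes = gene_table.set_index("gene_id")
    for si, snp in enumerate(spec.snp_spec):
        if snp.gene_id not in genes.index:
            raise KeyError(f"snp_spec names unknown gene {snp.gene_id!r}")
        gene = genes.loc[snp.gene_id]
        scaffold = scaffolds[gene["scaffold_id"]]
        segment = scaffold[gene["start"] - 1 : gene["end"]]
        cds = segment if gene["strand"] == "+" else revcomp(segment)
        if len(cds) % 3:
            raise ValueError(f"gene {snp.gene_id!r} CDS length not divisible by 3")
        syn_c, nonsyn_c = _snp_candidates(cds)
        rng = np.random.default_rng([spec.seed, 7, si])
        used: set[int] = set()
        chosen = [
            (pos, ref, alt, "synonymous")
            for pos, ref, alt in _pick_one_per_codon(rng, syn_c, snp.n_syn, used)
        ] + [
            (pos, ref, alt, "nonsynonymous")
            for pos, ref, alt in _pick_one_per_codon(rng, nonsyn_c, snp.n_nonsyn, used)
        ]
        for cds_pos0, ref, alt, cls in chosen:
            if gene["strand"] == "+":
                scaffold_pos = int(gene["start"]) + cds_pos0
                s_ref, s_alt = ref, alt
            else:
                scaffold_pos = int(gene["end"]) - cds_pos0
                s_ref, s_alt = revcomp(ref), revcomp(alt)
            rows.append(
                {
                    "scaffold_id": gene["scaffold_id"],
                    "gene_id": snp.gene_id,
                    "cds_position": cds_pos0 + 1,
                    "scaffold_position": scaffold_pos,
                    "ref_base": s_ref,
                    "alt_base": s_alt,
                    "cds_ref_base": ref,
                    "cds_alt_base": alt,
                    "classification": cls,
                    "allele_freq": snp.allele_freq,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "scaffold_id", "gene_id", "cds_position", "scaffold_position",
            "ref_base", "alt_base", "cds_ref_base", "cds_alt_base",
            "classification", "allele_freq",
        ],
    )


def simulate_reads(
    scaffolds: dict[str, str],
    spec: ReadSimSpec,
    gene_table: pd.DataFrame | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame, TruthTable]:
    """Simulate uniform shotgun reads carrying injected strain SNPs.

    Returns (reads, placements, truth): reads as (read_id, sequence, quality)
    tuples; placements with the true origin (scaffold, 1-based inclusive
    span, strand) of every read; truth holding the realized SNP plan.
    Reads are drawn uniformly along each scaffold at
    ``round(depth_target * length / read_length)`` reads per scaffold; each
    read carries the alternate allele at each spanned SNP site independently
    with probability ``allele_freq``.
    """
    spec.validate()
    snp_plan = (
        plan_snps(scaffolds, gene_table, spec)
        if spec.snp_spec and gene_table is not None
        else pd.DataFrame()
    )
    reads: list[tuple[str, str, str]] = []
    placement_rows = []
    base_bytes = np.frombuffer(b"ACGT", dtype="S1")
    for sidx, (sid, sequence) in enumerate(scaffolds.items()):
        length = len(sequence)
        if length < spec.read_length:
            warnings.warn(f"scaffold {sid!r} shorter than read_length; skipped")
            continue
        n_reads = round(spec.depth_target * length / spec.read_length)
        if n_reads == 0:
            warnings.warn(f"depth_target too low for scaffold {sid!r}; no reads emitted")
            continue
        rng = np.random.default_rng([spec.seed, 11, sidx])
        seq_arr = np.frombuffer(sequence.encode(), dtype="S1")
        starts = rng.integers(0, length - spec.read_length + 1, size=n_reads)
        strands = rng.integers(0, 2, size=n_reads)
        local_snps = (
            snp_plan[snp_plan["scaffold_id"] == sid] if len(snp_plan) else snp_plan
        )
        for i in range(n_reads):
            start0 = int(starts[i])
            window = seq_arr[start0 : start0 + spec.read_length].copy()
            if len(local_snps):
                for snp in local_snps.itertuples(index=False):
                    off = snp.scaffold_position - 1 - start0
                    if 0 <= off < spec.read_length and rng.random() < snp.allele_freq:
                        window[off] = snp.alt_base.encode()
            if spec.error_rate > 0:
                n_err = rng.binomial(spec.read_length, spec.error_rate)
                for pos in rng.choice(spec.read_length, size=n_err, replace=False):
                    current = window[pos]
                    options = base_bytes[base_bytes != current]
                    window[pos] = options[rng.integers(len(options))]
            strand = "+" if strands[i] == 0 else "-"
            out = window.tobytes().decode()
            if strand == "-":
                out = revcomp(out)
            read_id = f"{sid}|r{i:07d}"
            reads.append((read_id, out, "I" * spec.read_length))
            placement_rows.append(
                {
                    "read_id": read_id,
                    "scaffold_id": sid,
                    "start": start0 + 1,
                    "end": start0 + spec.read_length,
                    "strand": strand,
                }
            )
    placements = pd.DataFrame(
        placement_rows, columns=["read_id", "scaffold_id", "start", "end", "strand"]
    )
    truth = TruthTable(snps=snp_plan, placements=placements.copy())
    return reads, placements, truth


# -- a complete study-conditions virome --------------------------------------


@dataclass
class SyntheticVirome:
    """Bundle returned by :func:`simulate_virome`."""

    scaffolds: dict[str, str]
    gene_table: pd.DataFrame
    truth: TruthTable


def _default_layout(
    rng: np.random.Generator,
    scaffold_id: str,
    length: int,
    amg_symbol: str | None,
) -> tuple[list[Gene], int | None]:
    """Phage-like layout: ~600-nt genes, mostly co-oriented, one optional AMG.

    Returns (genes, motif_position) where motif_position is the 1-based
    intergenic position reserved for an NtcA site upstream of the AMG.
    """
    genes: list[Gene] = []
    pos = 201
    idx = 0
    strand = "+"
    amg_slot = rng.integers(3, 8) if amg_symbol else -1
    motif_pos: int | None = None
    while pos + 900 < length:
        gene_len = int(rng.integers(150, 300)) * 3
        if pos + gene_len + 200 > length:
            break
        if rng.random() < 0.1:  # occasional strand switch, rate stays low
            strand = "-" if strand == "+" else "+"
        idx += 1
        if idx == amg_slot:
            motif_pos = pos - 60  # intergenic, upstream of the AMG start
            category, symbol, g_strand = "amg", amg_symbol, "+"
        else:
            category = str(
                rng.choice(
                    ["viral_hallmark", "viral_like", "host_like", "unknown"],
                    p=[0.1, 0.45, 0.1, 0.35],
                )
            )
            symbol, g_strand = None, strand
        genes.append(
            Gene(
                gene_id=f"{scaffold_id}_g{idx:03d}",
                start=pos,
                end=pos + gene_len - 1,
                strand=g_strand,
                category=category,
                amg_symbol=symbol,
            )
        )
        pos += gene_len + int(rng.integers(80, 160))
    return genes, motif_pos


def simulate_virome(
    seed: int,
    n_populations: int = 6,
    variants_per_population: int = 3,
    scaffold_length: tuple[int, int] = (11000, 16000),
    amg_fraction: float = 0.5,
    variant_ani: tuple[float, float] = (0.96, 0.995),
) -> SyntheticVirome:
    """Generate a small virome with populations, AMG cassettes, and motifs.

    Half of the population ancestors (by default) carry one N-cycle AMG with
    an NtcA site (GTA-N8-TAC) written into the intergenic region upstream;
    truth records population membership, AMG placements, and motif positions.
    """
    rng = np.random.default_rng(seed)
    specs: list[GenomeSpec] = []
    motif_rows = []
    membership: list[tuple[str, str, bool]] = []  # scaffold, population, is_ancestor
    symbols = list(N_CYCLE_SYMBOLS[: max(1, int(round(n_populations * amg_fraction)))])
    for p in range(n_populations):
        sid = f"St{p + 1:02d}_pop{p + 1}"
        length = int(rng.integers(*scaffold_length))
        symbol = symbols[p] if p < len(symbols) else None
        genes, motif_pos = _default_layout(rng, sid, length, symbol)
        specs.append(GenomeSpec(scaffold_id=sid, length=length, genes=genes))
        if motif_pos is not None:
            motif_rows.append({"scaffold_id": sid, "start": motif_pos, "end": motif_pos + 13})
        membership.append((sid, f"pop{p + 1}", True))
    scaffolds, gene_table, truth = generate_scaffolds(specs, seed=seed)
    # write NtcA sites into the reserved intergenic positions
    for row in motif_rows:
        sid, start0 = row["scaffold_id"], row["start"] - 1
        spacer = "".join(
            BASES[i] for i in np.random.default_rng([seed, 13, start0]).integers(0, 4, 8)
        )
        site = "GTA" + spacer + "TAC"
        seq = scaffolds[sid]
        scaffolds[sid] = seq[:start0] + site + seq[start0 + 14 :]
        row["matched_sequence"] = site
    # population variants
    for p, (sid, pop, _) in enumerate(list(membership)):
        ancestor = scaffolds[sid]
        for k in range(variants_per_population - 1):
            ani = float(rng.uniform(*variant_ani))
            vid = f"{sid}_v{k + 1}"
            scaffolds[vid] = mutate_to_ani(ancestor, ani, seed=int(rng.integers(2**31)))
            membership.append((vid, pop, False))
    truth.scaffolds = pd.DataFrame(
        [
            {"scaffold_id": s, "population_id": pop, "is_ancestor": anc,
             "length": len(scaffolds[s])}
            for s, pop, anc in membership
        ]
    )
    truth.motifs = pd.DataFrame(
        motif_rows, columns=["scaffold_id", "start", "end", "matched_sequence"]
    )
    return SyntheticVirome(scaffolds=scaffolds, gene_table=gene_table, truth=truth)
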