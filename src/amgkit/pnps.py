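"""Per-gene pN/pS from read pileups over coding sequences.

The statistic contrasts observed non-synonymous and synonymous SNPs against
their mutational opportunities. For every reference codon, each of the nine
possible single-base substitutions either preserves the encoded amino acid
(synonymous) or changes it; the synonymous *site* count of a codon is
(number of synonymous single-base substitutions) / 3 and the non-synonymous
site count is the complement, so each sense codon contributes exactly three
sites in total. Then

    pN = n_obs / N_sites,   pS = s_obs / S_sites,   pN/pS = pN / pS

with SNPs called from a pileup (population-level, no downsampling: a site
qualifies at depth >= 10 when an alternate allele has frequency >= 1% with
>= 2 supporting reads). A ratio below 0.3 is read as strong purifying
selection. The ratio is 0 when only synonymous SNPs are observed and is
undefined (reported as NaN, not zero) when no synonymous SNPs are available
to normalise against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from amgkit.genetics import BASES, CODON_TABLE, revcomp

__all__ = [
    "CodonSiteTable",
    "VariantCall",
    "PnpsResult",
    "expected_sites",
    "pileup_from_placements",
    "call_variants",
    "pnps",
    "pnps_table",
]


@dataclass
class CodonSiteTable:
    gene_id: str
    per_codon: pd.DataFrame  # codon index (1-based), codon, N_sites, S_sites
    n_sites: float
    s_sites: float


@dataclass(frozen=True)
class VariantCall:
    gene_id: str
    cds_position: int  # 1-based within the CDS
    ref_base: str
    alt_base: str
    depth: int
    alt_fraction: float
    classification: str  # synonymous | nonsynonymous


@dataclass
class PnpsResult:
    gene_id: str
    n_obs: int
    s_obs: int
    n_sites: float
    s_sites: float
    pn: float
    ps: float
    ratio: float  # NaN when undefined (s_obs == 0)
    n_snps: int
    min_gene_coverage: float
    purifying: bool
    suppressed: bool = False  # coverage gate not met; ratio not reportable
    variants: list[VariantCall] = field(default_factory=list)


def expected_sites(cds: str, gene_id: str = "") -> CodonSiteTable:
    """Expected synonymous / non-synonymous site counts for a CDS.

    For each codon the synonymous fraction per position is the number of the
    three alternative bases preserving the amino acid, divided by 3; stop
    reference codons are excluded from the totals and substitutions creating
    a stop count as non-synonymous (standard genetic code).
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    rows = []
    for ci in range(len(cds) // 3):
        codon = cds[3 * ci : 3 * ci + 3]
        if any(b not in BASES for b in codon):
            raise ValueError(f"non-ACGT base in codon {ci + 1}")
        aa = CODON_TABLE[codon]
        if aa == "*":
            if ci < len(cds) // 3 - 1:
                raise ValueError(f"internal stop codon at codon {ci + 1}")
            continue  # terminal stop: excluded from site totals
        syn = 0
        for j in range(3):
            for alt in BASES:
                if alt == codon[j]:
                    continue
                if CODON_TABLE[codon[:j] + alt + codon[j + 1 :]] == aa:
                    syn += 1
        s_sites = syn / 3.0
        rows.append(
            {
                "codon_index": ci + 1,
                "codon": codon,
                "N_sites": 3.0 - s_sites,
                "S_sites": s_sites,
            }
        )
    table = pd.DataFrame(rows, columns=["codon_index", "codon", "N_sites", "S_sites"])
    return CodonSiteTable(
        gene_id=gene_id,
        per_codon=table,
        n_sites=float(table["N_sites"].sum()) if len(table) else 0.0,
        s_sites=float(table["S_sites"].sum()) if len(table) else 0.0,
    )


def pileup_from_placements(
    reads: list[tuple[str, str, str]],
    placements: pd.DataFrame,
    scaffold_id: str,
    gene_start: int,
    gene_end: int,
    gene_strand: str = "+",
) -> pd.DataFrame:
    """Base-count pileup over a gene's CDS from simulated/placed reads.

    Returns a frame with 1-based cds_position, ref-strand base counts A/C/G/T
    (complemented and reversed for minus-strand genes so the counts are in
    CDS orientation), one row per CDS position.
    """
    read_seq = {rid: seq for rid, seq, _ in reads}
    gene_len = gene_end - gene_start + 1
    counts = {b: np.zeros(gene_len, dtype=np.int64) for b in BASES}
    sub = placements[placements["scaffold_id"] == scaffold_id]
    for row in sub.itertuples(index=False):
        seq = read_seq.get(row.read_id)
        if seq is None:
            continue
        if row.strand == "-":
            seq = revcomp(seq)  # back to scaffold forward orientation
        lo = max(row.start, gene_start)
        hi = min(row.end, gene_end)
        for pos in range(lo, hi + 1):
            base = seq[pos - row.start]
            if base in counts:
                counts[base][pos - gene_start] += 1
    frame = pd.DataFrame(
        {"cds_position": np.arange(1, gene_len + 1), **{b: counts[b] for b in BASES}}
    )
    if gene_strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        frame = pd.DataFrame(
            {
                "cds_position": np.arange(1, gene_len + 1),
                **{b: counts[comp[b]][::-1] for b in BASES},
            }
        )
    return frame


def call_variants(
    pileup: pd.DataFrame,
    cds: str,
    gene_id: str = "",
    min_site_depth: int = 10,
    min_alt_fraction: float = 0.01,
    min_alt_reads: int = 2,
) -> list[VariantCall]:
    """Call population SNPs from a CDS-oriented base-count pileup.

    ``pileup`` needs columns cds_position (1-based) and A/C/G/T counts. A
    site yields a SNP when total depth >= min_site_depth and an alternate
    allele reaches min_alt_fraction with min_alt_reads supporting reads;
    every qualifying alternate allele is reported as its own SNP.
    Classification translates the reference codon with only that substitution
    applied.
    """
    cds = cds.upper()
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    calls: list[VariantCall] = []
    for row in pileup.itertuples(index=False):
        pos = int(row.cds_position)
        if pos < 1 or pos > len(cds):
            raise ValueError(f"pileup position {pos} beyond CDS of length {len(cds)}")
        counts = {b: int(getattr(row, b)) for b in BASES}
        depth = sum(counts.values())
        if depth < min_site_depth:
            continue
        ref = cds[pos - 1]
        ci = (pos - 1) // 3
        codon = cds[3 * ci : 3 * ci + 3]
        ref_aa = CODON_TABLE[codon]
        for alt in BASES:
            if alt == ref:
                continue
            n_alt = counts[alt]
            frac = n_alt / depth
            if n_alt >= min_alt_reads and frac >= min_alt_fraction:
                j = (pos - 1) % 3
                alt_aa = CODON_TABLE[codon[:j] + alt + codon[j + 1 :]]
                calls.append(
                    VariantCall(
                        gene_id=gene_id,
                        cds_position=pos,
                        ref_base=ref,
                        alt_base=alt,
                        depth=depth,
                        alt_fraction=frac,
                        classification=(
                            "synonymous" if alt_aa == ref_aa else "nonsynonymous"
                        ),
                    )
                )
    return calls


def pnps(
    gene_id: str,
    variants: list[VariantCall],
    site_table: CodonSiteTable,
    min_gene_coverage: float = float("nan"),
    coverage_gate: float = 10.0,
) -> PnpsResult:
    """Combine variant calls and expected sites into the pN/pS statistic.

    The ratio is 0 when n_obs == 0 and s_obs > 0; NaN (undefined) when
    s_obs == 0; purifying means a defined ratio < 0.3. When the minimum
    per-site coverage over the CDS is known and does not exceed
    ``coverage_gate``, the result is flagged suppressed: the gene was not
    observed deeply enough for the ratio to be reportable.
    """
    n_obs = sum(v.classification == "nonsynonymous" for v in variants)
    s_obs = sum(v.classification == "synonymous" for v in variants)
    pn = n_obs / site_table.n_sites if site_table.n_sites else float("nan")
    ps = s_obs / site_table.s_sites if site_table.s_sites else float("nan")
    if s_obs == 0:
        ratio = float("nan")
    else:
        ratio = pn / ps
    suppressed = (
        not math.isnan(min_gene_coverage) and min_gene_coverage <= coverage_gate
    )
    purifying = (not math.isnan(ratio)) and ratio < 0.3 and not suppressed
    return PnpsResult(
        gene_id=gene_id,
        n_obs=n_obs,
        s_obs=s_obs,
        n_sites=site_table.n_sites,
        s_sites=site_table.s_sites,
        pn=pn,
        ps=ps,
        ratio=ratio,
        n_snps=n_obs + s_obs,
        min_gene_coverage=min_gene_coverage,
        purifying=purifying,
        suppressed=suppressed,
        variants=list(variants),
    )


def pnps_table(results: list[PnpsResult]) -> pd.DataFrame:
    """Tidy per-gene pN/pS table (suppressed genes keep NaN ratios)."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "n_obs": r.n_obs,
                "s_obs": r.s_obs,
                "N_sites": r.n_sites,
                "S_sites": r.s_sites,
                "pN": r.pn,
                "pS": r.ps,
                "ratio": float("nan") if r.suppressed else r.ratio,
                "n_snps": r.n_snps,
                "min_cov": r.min_gene_coverage,
                "purifying": r.purifying,
            }
        )
    return pd.DataFrame(rows)
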