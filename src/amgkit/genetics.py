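"""Small shared genetics primitives: alphabet, genetic code, revcomp."""

from __future__ import annotations

from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# codon -> amino acid, stop codons mapped to '*'
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"

STOP_CODONS = tuple(standard_dna_table.stop_codons)
START_CODON = "ATG"

SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

# amino acid -> codons encoding it
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    AA_TO_CODONS.setdefault(CODON_TABLE[_codon], tuple())
    AA_TO_CODONS[CODON_TABLE[_codon]] += (_codon,)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-preserving)."""
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate a CDS (length divisible by 3) with '*' for stops."""
    if len(cds) % 3:
        raise ValueError("CDS length not divisible by 3")
    return "".join(CODON_TABLE[cds[i : i + 3]] for i in range(0, len(cds), 3))
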