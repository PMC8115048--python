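"""NtcA-binding-site scanning and positional filtering of regulatory calls.

NtcA is the cyanobacterial global nitrogen regulator; its marine-cyanobacteria
binding-site consensus is GTA-N8-TAC (14 bp). The consensus is its own
reverse complement, so a forward-strand scan already finds every
double-stranded site. Promoter/terminator calls produced by external tools
are filtered on their scores (sigma-70 promoters: LDF > 2.75; terminators:
confidence > 90%), and all regulatory features must be intergenic or within
10 bp of a gene boundary to be kept.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from amgkit.genetics import revcomp

__all__ = [
    "MotifDefinition",
    "MotifHit",
    "ExternalRegulatoryCall",
    "NTCA_MOTIF",
    "scan_motif",
    "apply_positional_filter",
    "filter_external_calls",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


@dataclass(frozen=True)
class MotifDefinition:
    """A fixed-length IUPAC consensus motif."""

    name: str = "NtcA"
    consensus: str = "GTA" + "N" * 8 + "TAC"

    @property
    def length(self) -> int:
        return len(self.consensus)

    def regex(self) -> re.Pattern:
        try:
            body = "".join(_IUPAC[ch] for ch in self.consensus.upper())
        except KeyError as exc:
            raise ValueError(f"non-IUPAC character in consensus: {exc}") from exc
        # lookahead so overlapping matches are all reported
        return re.compile(f"(?=({body}))")

    def is_palindromic(self) -> bool:
        """Whether the consensus equals its own reverse complement pattern."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
                "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
                "B": "V", "V": "B", "D": "H", "H": "D"}
        return self.consensus.upper() == "".join(
            comp[c] for c in reversed(self.consensus.upper())
        )


NTCA_MOTIF = MotifDefinition()


@dataclass
class MotifHit:
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    matched_sequence: str
    positional_ok: bool | None = None


@dataclass(frozen=True)
class ExternalRegulatoryCall:
    kind: str  # promoter | terminator
    position: int  # 1-based
    score: float  # LDF for promoters, percent confidence for terminators
    source: str = ""
    scaffold_id: str = ""

    def __post_init__(self):
        if self.kind not in ("promoter", "terminator"):
            raise ValueError(f"kind must be promoter or terminator, got {self.kind!r}")


def scan_motif(
    sequence: str,
    motif: MotifDefinition = NTCA_MOTIF,
    scaffold_id: str = "",
    both_strands: bool = False,
) -> list[MotifHit]:
    """Report every window matching the consensus, overlaps included.

    ``both_strands`` additionally scans the reverse complement and reports
    those hits in forward coordinates with strand "-"; for the palindromic
    default consensus this only duplicates the forward hits.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    sequence = sequence.upper()
    pattern = motif.regex()
    hits = [
        MotifHit(
            scaffold_id=scaffold_id,
            start=m.start() + 1,
            end=m.start() + motif.length,
            strand="+",
            matched_sequence=m.group(1),
        )
        for m in pattern.finditer(sequence)
    ]
    if both_strands:
        n = len(sequence)
        for m in pattern.finditer(revcomp(sequence)):
            start_rc = m.start()
            hits.append(
                MotifHit(
                    scaffold_id=scaffold_id,
                    start=n - (start_rc + motif.length) + 1,
                    end=n - start_rc,
                    strand="-",
                    matched_sequence=m.group(1),
                )
            )
    return sorted(hits, key=lambda h: (h.start, h.strand))


def _near_boundary(start: int, end: int, gene_start: int, gene_end: int, slack: int) -> bool:
    """Whether [start, end] lies within ``slack`` bases of either gene boundary."""
    return (
        min(abs(start - gene_start), abs(start - gene_end)) <= slack
        or min(abs(end - gene_start), abs(end - gene_end)) <= slack
    )


def apply_positional_filter(
    hits: list[MotifHit], gene_table: pd.DataFrame, slack: int = 10
) -> list[MotifHit]:
    """Mark hits as positionally plausible regulatory sites.

    A hit passes when it lies wholly outside every gene (intergenic), or when
    it overlaps a gene but sits within ``slack`` bases of that gene's start or
    stop boundary. Row order of the gene table is irrelevant.
    """
    genes = [
        (int(g.start), int(g.end))
        for g in gene_table.sort_values("start").itertuples(index=False)
    ]
    out = []
    for hit in hits:
        ok = True
        for g_start, g_end in genes:
            overlaps = not (hit.end < g_start or hit.start > g_end)
            if overlaps and not _near_boundary(hit.start, hit.end, g_start, g_end, slack):
                ok = False
                break
        out.append(
            MotifHit(
                scaffold_id=hit.scaffold_id,
                start=hit.start,
                end=hit.end,
                strand=hit.strand,
                matched_sequence=hit.matched_sequence,
                positional_ok=ok,
            )
        )
    return out


def filter_external_calls(
    calls: list[ExternalRegulatoryCall],
    gene_table: pd.DataFrame | None = None,
    ldf_min: float = 2.75,
    conf_min: float = 90.0,
    slack: int = 10,
) -> list[ExternalRegulatoryCall]:
    """Keep promoter/terminator calls passing score and positional rules.

    Promoters are kept iff LDF > ldf_min (strict); terminators iff confidence
    > conf_min (strict). With a gene table, calls must additionally be
    intergenic or within ``slack`` bases of a gene boundary. A promoter whose
    score looks percent-scaled (or a terminator whose score looks LDF-scaled)
    triggers a unit-mismatch warning.
    """
    import warnings

    kept = []
    for call in calls:
        if call.kind == "promoter":
            if call.score > 25:
                warnings.warn(
                    f"promoter at {call.position} has score {call.score}: "
                    "looks percent-scaled, expected LDF"
                )
            if not call.score > ldf_min:
                continue
        else:
            if call.score <= 25:
                warnings.warn(
                    f"terminator at {call.position} has score {call.score}: "
                    "looks LDF-scaled, expected percent confidence"
                )
            if not call.score > conf_min:
                continue
        if gene_table is not None and len(gene_table):
            probe = [
                MotifHit(
                    scaffold_id=call.scaffold_id,
                    start=call.position,
                    end=call.position,
                    strand="+",
                    matched_sequence="",
                )
            ]
            if not apply_positional_filter(probe, gene_table, slack)[0].positional_ok:
                continue
        kept.append(call)
    return kept
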