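"""Annotation-confidence ranking (A–E) and nitrogen-cycle gene flagging.

Ranks condense multi-database homology evidence into a single confidence
letter per query:

    A — reciprocal best hit (RBH) to KEGG with bitscore > 350
    B — RBH to UniRef90 with bitscore > 350
    C — one-way hit to UniRef90 (any bitscore >= 60); one-way KEGG hits with
        bitscore in [60, 350] are treated the same way (tagged "gap-rule",
        since one-way database evidence is the closest analog)
    D — hits only to InterPro
    E — best bitscore < 60 to any database
    unranked — no hits at all

Rules are applied strictly in A→E order; the first that fires wins.
Nitrogen-cycle genes are then shortlisted by matching annotation text / KO
identifiers against an editable catalog (KO + case-insensitive keyword
regex per symbol), a reproducible stand-in for manual curation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "HomologyHit",
    "AnnotationRank",
    "assign_rank",
    "rank_table",
    "load_catalog",
    "flag_n_cycle",
]

VALID_DBS = ("KEGG", "Uniref90", "InterPro")


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    db: str  # KEGG | Uniref90 | InterPro
    subject_id: str = ""
    bitscore: float | None = None  # absent for InterPro
    reciprocal: bool = False
    annotation_text: str = ""

    def __post_init__(self):
        if self.db not in VALID_DBS:
            raise ValueError(f"unknown db {self.db!r}; expected one of {VALID_DBS}")
        if self.bitscore is not None and self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass(frozen=True)
class AnnotationRank:
    query_id: str
    rank: str  # A | B | C | D | E | unranked
    basis: str


def assign_rank(hits: list[HomologyHit]) -> AnnotationRank:
    """Assign the confidence rank for one query's hits (order-independent)."""
    if not hits:
        return AnnotationRank(query_id="", rank="unranked", basis="no-hits")
    query_id = hits[0].query_id
    if any(h.query_id != query_id for h in hits):
        raise ValueError("assign_rank expects hits for a single query")

    def best(db: str, reciprocal: bool | None = None) -> float:
        scores = [
            h.bitscore
            for h in hits
            if h.db == db
            and h.bitscore is not None
            and (reciprocal is None or h.reciprocal == reciprocal)
        ]
        return max(scores, default=float("-inf"))

    if best("KEGG", reciprocal=True) > 350:
        return AnnotationRank(query_id, "A", "kegg-rbh>350")
    if best("Uniref90", reciprocal=True) > 350:
        return AnnotationRank(query_id, "B", "uniref90-rbh>350")
    if best("Uniref90") >= 60:
        return AnnotationRank(query_id, "C", "uniref90-oneway")
    if best("KEGG") >= 60:
        return AnnotationRank(query_id, "C", "gap-rule")
    if all(h.db == "InterPro" for h in hits):
        return AnnotationRank(query_id, "D", "interpro-only")
    scored = [h.bitscore for h in hits if h.bitscore is not None]
    if scored and max(scored) < 60:
        return AnnotationRank(query_id, "E", "bitscore<60")
    return AnnotationRank(query_id, "E", "residual-low-confidence")


def rank_table(hits: list[HomologyHit]) -> pd.DataFrame:
    """Rank every query in a hit list; one row per query."""
    by_query: dict[str, list[HomologyHit]] = {}
    for hit in hits:
        by_query.setdefault(hit.query_id, []).append(hit)
    rows = [
        {"query_id": q, "rank": r.rank, "basis": r.basis}
        for q, group in sorted(by_query.items())
        for r in [assign_rank(group)]
    ]
    return pd.DataFrame(rows, columns=["query_id", "rank", "basis"])


def load_catalog(path: str | Path | None = None) -> pd.DataFrame:
    """N-cycle catalog: symbol, KO identifier, keyword regex (TSV)."""
    if path is None:
        source = resources.files("amgkit.data") / "ncycle_catalog.tsv"
        with resources.as_file(source) as p:
            catalog = pd.read_csv(p, sep="\t")
    else:
        catalog = pd.read_csv(path, sep="\t")
    if catalog["symbol"].duplicated().any():
        raise ValueError("catalog symbols must be unique")
    return catalog


def flag_n_cycle(
    annotations: pd.DataFrame, catalog: pd.DataFrame | None = None
) -> list[tuple[str, str]]:
    """Shortlist queries whose annotation matches an N-cycle catalog entry.

    ``annotations`` needs columns query_id and annotation_text (a ko column
    is used too when present). Output is sorted and deduplicated
    (query_id, symbol) pairs.
    """
    catalog = catalog if catalog is not None else load_catalog()
    patterns = [
        (row.symbol, str(row.ko), re.compile(row.keyword_regex, re.IGNORECASE))
        for row in catalog.itertuples(index=False)
    ]
    flagged: set[tuple[str, str]] = set()
    has_ko = "ko" in annotations.columns
    for row in annotations.itertuples(index=False):
        text = str(getattr(row, "annotation_text", "") or "")
        ko = str(getattr(row, "ko", "") or "") if has_ko else ""
        for symbol, symbol_ko, regex in patterns:
            if (ko and ko == symbol_ko) or regex.search(text):
                flagged.add((row.query_id, symbol))
    return sorted(flagged)
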