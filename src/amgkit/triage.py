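"""Viral triage: decide which scaffolds are viral and reportable.

External classifier outputs (VirSorter-style categories, VirFinder-style
score/p-value) are consumed as tables — never recomputed. The decision rule:
a scaffold is *eligible* when longer than 5 kb, or circular and longer than
1.5 kb; eligible scaffolds are called *viral* when the category is 1 or 2,
or the score exceeds 0.9 with p < 0.05; and viral scaffolds are *reportable*
for AMG analysis only at >= 10 kb. The strand-switch rate (fraction of
adjacent gene pairs changing coding strand) is reported as supporting
evidence — phage genomes switch strand rarely — but carries no hard cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "ScaffoldFeatures",
    "TriageDecision",
    "detect_circularity",
    "strand_switch_rate",
    "classify_viral",
    "triage_table",
]


@dataclass
class ScaffoldFeatures:
    scaffold_id: str
    length: int
    circular: bool = False
    virsorter_category: int | None = None  # 1..6
    virfinder_score: float | None = None  # [0, 1]
    virfinder_p: float | None = None  # [0, 1]
    viral_like_gene_fraction: float | None = None
    unaffiliated_gene_fraction: float | None = None
    strand_switch_rate: float | None = None

    def __post_init__(self):
        if self.virsorter_category is not None and self.virsorter_category not in range(1, 7):
            raise ValueError(
                f"{self.scaffold_id}: virsorter_category must be in 1..6"
            )
        for name in ("virfinder_score", "virfinder_p", "viral_like_gene_fraction",
                     "unaffiliated_gene_fraction", "strand_switch_rate"):
            value = getattr(self, name)
            if value is not None and not 0.0 <= value <= 1.0:
                raise ValueError(f"{self.scaffold_id}: {name} outside [0,1]")


@dataclass
class TriageDecision:
    scaffold_id: str
    is_viral: bool
    reportable: bool
    reasons: list[str] = field(default_factory=list)


def detect_circularity(sequence: str, min_repeat: int = 20) -> bool:
    """True iff a terminal direct repeat of >= min_repeat bases joins the ends.

    Assembly-derived circular genomes present as linear sequences whose start
    is repeated at the end; the longest terminal exact repeat is searched.
    """
    if min_repeat < 1:
        raise ValueError("min_repeat must be >= 1")
    if len(sequence) < 2 * min_repeat:
        raise ValueError("sequence shorter than 2 x min_repeat")
    longest = min(len(sequence) // 2, 1000)  # repeats longer than this are not terminal repeats
    return any(
        sequence[:k] == sequence[-k:] for k in range(min_repeat, longest + 1)
    )


def strand_switch_rate(gene_table: pd.DataFrame) -> float:
    """Fraction of adjacent gene pairs (ordered by start) changing strand."""
    if len(gene_table) < 2:
        raise ValueError("strand_switch_rate undefined for < 2 genes")
    strands = gene_table.sort_values("start")["strand"].tolist()
    switches = sum(a != b for a, b in zip(strands[:-1], strands[1:]))
    return switches / (len(strands) - 1)


def classify_viral(
    features: ScaffoldFeatures,
    size_gate: int = 5000,
    circular_gate: int = 1500,
    report_gate: int = 10000,
) -> TriageDecision:
    """Apply the triage decision rule to one scaffold's features."""
    reasons: list[str] = []
    eligible = False
    if features.length > size_gate:
        eligible = True
        reasons.append(f"length>{size_gate}")
    elif features.circular and features.length > circular_gate:
        eligible = True
        reasons.append(f"circular&length>{circular_gate}")
    classifier_hit = False
    if features.virsorter_category in (1, 2):
        classifier_hit = True
        reasons.append(f"virsorter_cat{features.virsorter_category}")
    if (
        features.virfinder_score is not None
        and features.virfinder_p is not None
        and features.virfinder_score > 0.9
        and features.virfinder_p < 0.05
    ):
        classifier_hit = True
        reasons.append("virfinder_score>0.9&p<0.05")
    is_viral = eligible and classifier_hit
    if not eligible:
        reasons.append("size_ineligible")
    reportable = is_viral and features.length >= report_gate
    if is_viral and not reportable:
        reasons.append(f"below_report_gate_{report_gate}")
    return TriageDecision(
        scaffold_id=features.scaffold_id,
        is_viral=is_viral,
        reportable=reportable,
        reasons=reasons,
    )


def triage_table(
    features: list[ScaffoldFeatures],
    size_gate: int = 5000,
    circular_gate: int = 1500,
    report_gate: int = 10000,
) -> pd.DataFrame:
    """Triage a batch of scaffolds into a tidy decision table."""
    rows = []
    for f in features:
        decision = classify_viral(f, size_gate, circular_gate, report_gate)
        rows.append(
            {
                "scaffold_id": f.scaffold_id,
                "length": f.length,
                "circular": f.circular,
                "is_viral": decision.is_viral,
                "reportable": decision.reportable,
                "reasons": ";".join(decision.reasons),
            }
        )
    return pd.DataFrame(rows)
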