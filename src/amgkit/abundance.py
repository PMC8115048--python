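"""Coverage, trimmed-mean abundance, and the detection rule.

Per-scaffold read depth is accumulated from alignments (a SAM/BAM file or a
plain placement table). A scaffold's coverage is summarised by *tpmean* — the
per-base depth averaged after discarding the highest and lowest 10% of
positions, which suppresses spikes from repeats or conserved regions — and
*breadth*, the fraction of positions covered at all. A scaffold counts as
detected in a sample only with breadth >= 80% and tpmean >= 5x; coverages are
normalised per gigabase of sample sequencing so samples of different size are
comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageProfile",
    "AbundanceRecord",
    "depth_from_alignments",
    "tpmean",
    "breadth",
    "detect_and_normalize",
    "abundance_matrix",
]

NORMALIZATION_BASES = 1e9  # report coverage per Gb of sample sequencing


@dataclass
class CoverageProfile:
    scaffold_id: str
    depths: np.ndarray  # per-base integer depth, length == scaffold length

    def __post_init__(self):
        self.depths = np.asarray(self.depths)
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")


@dataclass
class AbundanceRecord:
    scaffold_id: str
    sample_id: str
    tpmean_depth: float
    breadth: float
    normalized_coverage: float
    detected: bool


def _depths_from_placements(
    placements: pd.DataFrame, lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    depths = {sid: np.zeros(n + 1, dtype=np.int64) for sid, n in lengths.items()}
    for row in placements.itertuples(index=False):
        if row.scaffold_id not in depths:
            raise ValueError(f"alignment references unknown scaffold {row.scaffold_id!r}")
        diff = depths[row.scaffold_id]
        if row.start < 1 or row.end > lengths[row.scaffold_id]:
            raise ValueError(
                f"alignment {row.read_id} extends beyond scaffold "
                f"{row.scaffold_id!r} bounds"
            )
        diff[row.start - 1] += 1
        diff[row.end] -= 1
    return {sid: np.cumsum(diff[:-1]) for sid, diff in depths.items()}


def _depths_from_sam(path: str, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    import pysam

    depths = {sid: np.zeros(n + 1, dtype=np.int64) for sid, n in lengths.items()}
    with pysam.AlignmentFile(path, check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            sid = aln.reference_name
            if sid not in depths:
                raise ValueError(f"alignment references unknown scaffold {sid!r}")
            start = aln.reference_start  # 0-based
            end = aln.reference_end  # exclusive
            if end is None or end > lengths[sid]:
                raise ValueError(f"alignment extends beyond scaffold {sid!r} bounds")
            depths[sid][start] += 1
            depths[sid][end] -= 1
    return {sid: np.cumsum(diff[:-1]) for sid, diff in depths.items()}


def depth_from_alignments(
    alignments: pd.DataFrame | str,
    lengths: dict[str, int],
) -> dict[str, CoverageProfile]:
    """Per-base depth per scaffold from a placement table or SAM/BAM path.

    Placement tables need columns read_id, scaffold_id, start, end (1-based
    inclusive). For SAM/BAM input, secondary and supplementary alignments are
    excluded.
    """
    if isinstance(alignments, pd.DataFrame):
        depths = _depths_from_placements(alignments, lengths)
    else:
        depths = _depths_from_sam(alignments, lengths)
    return {
        sid: CoverageProfile(scaffold_id=sid, depths=vec) for sid, vec in depths.items()
    }


def tpmean(depths: np.ndarray, trim_fraction: float = 0.10) -> float:
    """Trimmed-mean depth: drop the top and bottom ``trim_fraction`` of
    positions (by sorted depth, trim count rounded down), then average."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    if not 0.0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(depths.size * trim_fraction)
    ordered = np.sort(depths)
    kept = ordered[k : depths.size - k] if k else ordered
    return float(np.mean(kept))


def breadth(depths: np.ndarray, min_depth: int = 1) -> float:
    """Fraction of positions covered by at least ``min_depth`` reads."""
    depths = np.asarray(depths)
    if depths.size == 0:
        raise ValueError("empty depth vector")
    return float(np.mean(depths >= min_depth))


def detect_and_normalize(
    profile: CoverageProfile,
    sample_total_bases: float,
    sample_id: str = "",
    trim_fraction: float = 0.10,
    breadth_min: float = 0.80,
    depth_min: float = 5.0,
) -> AbundanceRecord:
    """Summarise one (scaffold, sample) coverage profile.

    normalized_coverage = tpmean x (1e9 / sample_total_bases); detection
    requires breadth >= breadth_min and tpmean >= depth_min.
    """
    if sample_total_bases <= 0:
        raise ValueError("sample_total_bases must be > 0")
    tp = tpmean(profile.depths, trim_fraction)
    br = breadth(profile.depths)
    detected = br >= breadth_min and tp >= depth_min
    return AbundanceRecord(
        scaffold_id=profile.scaffold_id,
        sample_id=sample_id,
        tpmean_depth=tp,
        breadth=br,
        normalized_coverage=tp * (NORMALIZATION_BASES / sample_total_bases),
        detected=detected,
    )


def abundance_matrix(
    records: list[AbundanceRecord], zero_undetected: bool = True
) -> pd.DataFrame:
    """Scaffold x sample matrix of normalized coverage.

    Records failing the detection rule contribute 0 (the coverage is not
    considered reliable enough to report) unless ``zero_undetected`` is off.
    """
    rows = [
        {
            "scaffold_id": r.scaffold_id,
            "sample_id": r.sample_id,
            "value": r.normalized_coverage if (r.detected or not zero_undetected) else 0.0,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=["scaffold_id", "sample_id", "value"])
    return frame.pivot_table(
        index="scaffold_id", columns="sample_id", values="value", fill_value=0.0
    )
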