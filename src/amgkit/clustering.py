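"""ANI-based viral population clustering and AMG-scaffold merging.

Viral populations are defined by the field-standard thresholds: two scaffolds
belong to the same population when they share >= 95% average nucleotide
identity (ANI) over >= 80% of the shorter sequence. ANI is computed
nucmer-style from consolidated local alignment blocks: exact k-mer seeds are
chained along diagonals into candidate blocks, each block is globally aligned
(edlib), and matches/columns are pooled over non-redundant blocks, with
reverse-complement alignments allowed.

Clustering is greedy and representative-centric: scaffolds are considered
longest-first and join the first existing cluster whose representative they
match at both thresholds, otherwise they found a new cluster. Scaffolds that
carry the same AMG and overlap by > 1 kb at >= 99% identity can be merged
into an extended scaffold (id suffixed "E"), filling N-gaps from the partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from amgkit.genetics import revcomp

__all__ = [
    "PairwiseAlignmentSummary",
    "PopulationCluster",
    "MergeRecord",
    "pairwise_ani",
    "hamming_ani",
    "cluster_populations",
    "cluster_scaffolds",
    "apply_cscl_retention",
    "merge_amg_scaffolds",
    "clusters_to_frame",
]

_SEED_K = 15
_MAX_SEED_OCCURRENCES = 8
_MIN_BLOCK = 100
_MAX_CHAIN_GAP = 500
_DIAG_BAND = 32
_END_EXTENSION = 30


@dataclass
class PairwiseAlignmentSummary:
    """ANI and aligned-fraction summary for one scaffold pair."""

    id_a: str
    id_b: str
    ani: float  # percent identity over aligned columns, [0, 100]
    aligned_length: int  # bases of the shorter sequence covered by alignments
    shorter_length: int
    aligned_fraction_shorter: float
    strand: str = "+"


@dataclass
class PopulationCluster:
    cluster_id: str
    member_ids: list[str]
    representative_id: str
    from_cscl: dict[str, bool] = field(default_factory=dict)


@dataclass
class MergeRecord:
    merged_id: str
    source_ids: list[str]
    overlap_length: int
    overlap_identity: float
    gap_fills: list[tuple[int, int]] = field(default_factory=list)
    merged: bool = True
    reason: str = ""


def hamming_ani(seq_a: str, seq_b: str) -> float:
    """Exact substitution-only ANI oracle (%); requires equal lengths."""
    if len(seq_a) != len(seq_b):
        raise ValueError("hamming_ani requires equal-length sequences")
    a = np.frombuffer(seq_a.encode(), dtype="S1")
    b = np.frombuffer(seq_b.encode(), dtype="S1")
    return 100.0 * float(np.mean(a == b))


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return {
        kmer: pos for kmer, pos in index.items() if len(pos) <= _MAX_SEED_OCCURRENCES
    }


def _seed_hits(seq_a: str, seq_b: str, k: int) -> list[tuple[int, int]]:
    """(diagonal, pos_a) pairs for exact shared k-mers."""
    index = _kmer_index(seq_a, k)
    hits = []
    for j in range(len(seq_b) - k + 1):
        for i in index.get(seq_b[j : j + k], ()):
            hits.append((j - i, i))
    return hits


def _chain_blocks(hits: list[tuple[int, int]], k: int) -> list[tuple[int, int, int]]:
    """Chain seed hits into blocks (a_start, a_end_excl, diagonal).

    Hits are chained along each exact diagonal with a bounded positional gap;
    blocks on nearby diagonals that adjoin on the query are then merged, so a
    handful of spurious off-diagonal seeds cannot fragment a long block.
    """
    by_diag: dict[int, list[int]] = {}
    for diag, pa in hits:
        by_diag.setdefault(diag, []).append(pa)
    raw: list[tuple[int, int, int]] = []
    for diag, positions in by_diag.items():
        positions.sort()
        start = prev = positions[0]
        for pa in positions[1:]:
            if pa - prev > _MAX_CHAIN_GAP:
                raw.append((start, prev + k, diag))
                start = pa
            prev = pa
        raw.append((start, prev + k, diag))
    raw.sort()
    merged: list[list[int]] = []
    for a_start, a_end, diag in raw:
        if (
            merged
            and abs(diag - merged[-1][2]) <= _DIAG_BAND
            and a_start <= merged[-1][1] + _MAX_CHAIN_GAP
        ):
            keep = merged[-1] if merged[-1][1] - merged[-1][0] >= a_end - a_start else [a_start, a_end, diag]
            merged[-1] = [min(merged[-1][0], a_start), max(merged[-1][1], a_end), keep[2]]
        else:
            merged.append([a_start, a_end, diag])
    return [(s, e, d) for s, e, d in merged if e - s >= _MIN_BLOCK]


def _align_blocks(seq_a: str, seq_b: str) -> tuple[int, int, list[tuple[int, int]]]:
    """(matches, columns, regions_on_a) over consolidated blocks, one strand."""
    blocks = _chain_blocks(_seed_hits(seq_a, seq_b, _SEED_K), _SEED_K)
    blocks.sort(key=lambda blk: blk[1] - blk[0], reverse=True)
    accepted: list[tuple[int, int]] = []
    matches = columns = 0
    for a_start, a_end, diag in blocks:
        # extend along the diagonal toward sequence boundaries (bounded)
        ext_left = min(a_start, a_start + diag, _END_EXTENSION)
        ext_right = min(
            len(seq_a) - a_end, len(seq_b) - (a_end + diag), _END_EXTENSION
        )
        a_start -= max(ext_left, 0)
        a_end += max(ext_right, 0)
        b_start = max(a_start + diag, 0)
        b_end = min(a_end + diag, len(seq_b))
        if any(not (a_end <= s or a_start >= e) for s, e in accepted):
            continue  # overlaps a longer accepted block on the query: count once
        sub_a = seq_a[a_start:a_end]
        sub_b = seq_b[b_start:b_end]
        if not sub_a or not sub_b:
            continue
        aln = edlib.align(sub_a, sub_b, mode="NW", task="path")
        cols = m = 0
        num = ""
        for ch in aln["cigar"]:
            if ch.isdigit():
                num += ch
            else:
                n = int(num)
                num = ""
                cols += n
                if ch == "=":
                    m += n
        matches += m
        columns += cols
        accepted.append((a_start, a_end))
    return matches, columns, accepted


def pairwise_ani(seq_a: str, seq_b: str, id_a: str = "a", id_b: str = "b") -> PairwiseAlignmentSummary:
    """Nucmer-style ANI between two scaffolds.

    Both orientations of ``seq_b`` are tried and the strand with more aligned
    sequence wins. Raises ``ValueError`` for empty or all-N input (ANI is
    undefined there).
    """
    for name, seq in (("seq_a", seq_a), ("seq_b", seq_b)):
        if not seq:
            raise ValueError(f"{name} is empty")
        if set(seq.upper()) <= {"N"}:
            raise ValueError(f"{name} contains only N characters: ANI undefined")
    shorter_length = min(len(seq_a), len(seq_b))
    fwd = _align_blocks(seq_a, seq_b)
    rev = _align_blocks(seq_a, revcomp(seq_b))
    (matches, columns, regions), strand = max(
        [(fwd, "+"), (rev, "-")], key=lambda item: item[0][1]
    )
    if columns == 0:
        return PairwiseAlignmentSummary(
            id_a, id_b, ani=0.0, aligned_length=0, shorter_length=shorter_length,
            aligned_fraction_shorter=0.0, strand=strand,
        )
    aligned_on_shorter = sum(e - s for s, e in regions)
    aligned_on_shorter = min(aligned_on_shorter, shorter_length)
    return PairwiseAlignmentSummary(
        id_a,
        id_b,
        ani=100.0 * matches / columns,
        aligned_length=aligned_on_shorter,
        shorter_length=shorter_length,
        aligned_fraction_shorter=aligned_on_shorter / shorter_length,
        strand=strand,
    )


def cluster_populations(
    summaries: list[PairwiseAlignmentSummary],
    lengths: dict[str, int] | list[tuple[str, int]],
    ani_min: float = 95.0,
    cov_min: float = 0.80,
    cscl_flags: dict[str, bool] | None = None,
) -> list[PopulationCluster]:
    """Greedy longest-first centroid clustering at the population thresholds.

    Scaffolds (``lengths``: id -> length mapping, or (id, length) pairs) are
    sorted by descending length (ties broken lexicographically by id) and
    each joins the first cluster whose representative it matches at
    ani >= ani_min and aligned fraction of the shorter sequence >= cov_min,
    else founds a new cluster.
    """
    if not isinstance(lengths, dict):
        pairs = list(lengths)
        ids = [sid for sid, _ in pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scaffold ids")
        lengths = dict(pairs)
    edges: dict[tuple[str, str], PairwiseAlignmentSummary] = {}
    for s in summaries:
        edges[(s.id_a, s.id_b)] = s
        edges[(s.id_b, s.id_a)] = s
    order = sorted(lengths, key=lambda sid: (-lengths[sid], sid))
    clusters: list[PopulationCluster] = []
    for sid in order:
        placed = False
        for cluster in clusters:
            edge = edges.get((sid, cluster.representative_id))
            if edge is None:
                continue
            if edge.ani >= ani_min and edge.aligned_fraction_shorter >= cov_min:
                cluster.member_ids.append(sid)
                placed = True
                break
        if not placed:
            clusters.append(
                PopulationCluster(
                    cluster_id=f"VC{len(clusters) + 1:04d}",
                    member_ids=[sid],
                    representative_id=sid,
                )
            )
    if cscl_flags:
        for cluster in clusters:
            cluster.from_cscl = {m: bool(cscl_flags.get(m, False)) for m in cluster.member_ids}
    return clusters


def cluster_scaffolds(
    scaffolds: dict[str, str],
    ani_min: float = 95.0,
    cov_min: float = 0.80,
    cscl_flags: dict[str, bool] | None = None,
) -> list[PopulationCluster]:
    """Convenience wrapper: all-vs-all pairwise ANI, then clustering."""
    ids = sorted(scaffolds)
    summaries = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            summaries.append(pairwise_ani(scaffolds[a], scaffolds[b], a, b))
    lengths = {sid: len(seq) for sid, seq in scaffolds.items()}
    return cluster_populations(summaries, lengths, ani_min, cov_min, cscl_flags)


def apply_cscl_retention(clusters: list[PopulationCluster]) -> list[str]:
    """CsCl-derived scaffolds survive only as cluster representatives.

    CsCl density-gradient purification can distort community composition, so
    a CsCl-derived scaffold is retained iff it is its cluster's
    representative; non-CsCl scaffolds are always retained.
    """
    retained = []
    for cluster in clusters:
        for member in cluster.member_ids:
            if cluster.from_cscl.get(member, False) and member != cluster.representative_id:
                continue
            retained.append(member)
    return sorted(retained)


def clusters_to_frame(clusters: list[PopulationCluster], lengths: dict[str, int] | None = None) -> pd.DataFrame:
    rows = []
    for cluster in clusters:
        for member in cluster.member_ids:
            rows.append(
                {
                    "scaffold_id": member,
                    "cluster_id": cluster.cluster_id,
                    "is_representative": member == cluster.representative_id,
                    "length": (lengths or {}).get(member, pd.NA),
                }
            )
    return pd.DataFrame(rows, columns=["scaffold_id", "cluster_id", "is_representative", "length"])


# -- AMG scaffold merging ----------------------------------------------------


def _overlap_identity(tail: str, head: str) -> tuple[float, list[int]]:
    """Percent identity of two equal-length segments; N is a wildcard.

    Returns (identity, fillable positions) where fillable positions (0-based
    within the overlap) have N in exactly one partner.
    """
    a = np.frombuffer(tail.encode(), dtype="S1")
    b = np.frombuffer(head.encode(), dtype="S1")
    is_n = (a == b"N") | (b == b"N")
    informative = ~is_n
    if informative.sum() == 0:
        return 0.0, []
    ident = 100.0 * float(np.mean(a[informative] == b[informative]))
    fillable = np.nonzero((a == b"N") ^ (b == b"N"))[0].tolist()
    return ident, fillable


def _best_dovetail(seq_a: str, seq_b: str) -> int | None:
    """Most-supported offset of seq_b's start within seq_a (suffix/prefix)."""
    hits = _seed_hits(seq_b, seq_a, _SEED_K)  # diag = pos_a - pos_b = offset
    if not hits:
        return None
    votes: dict[int, int] = {}
    for diag, _ in hits:
        votes[diag] = votes.get(diag, 0) + 1
    offset, support = max(votes.items(), key=lambda kv: (kv[1], -kv[0]))
    if support < 3 or offset < 0:
        return None
    return offset


def _try_merge(
    id_a: str, seq_a: str, id_b: str, seq_b: str, min_overlap: int, min_identity: float
) -> tuple[str, MergeRecord] | None:
    """Merge seq_b onto seq_a's tail if a qualifying dovetail overlap exists."""
    offset = _best_dovetail(seq_a, seq_b)
    if offset is None:
        return None
    overlap = min(len(seq_a) - offset, len(seq_b))
    if overlap <= 0:
        return None
    tail = seq_a[offset : offset + overlap]
    head = seq_b[:overlap]
    identity, fillable = _overlap_identity(tail, head)
    if overlap <= min_overlap or identity < min_identity:
        return (
            "",
            MergeRecord(
                merged_id="",
                source_ids=[id_a, id_b],
                overlap_length=overlap,
                overlap_identity=identity,
                merged=False,
                reason=(
                    f"overlap {overlap} <= {min_overlap}"
                    if overlap <= min_overlap
                    else f"identity {identity:.2f} < {min_identity}"
                ),
            ),
        )
    # consensus over the overlap: fill N from the partner, else keep seq_a
    consensus = list(tail)
    gap_fills: list[tuple[int, int]] = []
    for pos in fillable:
        if consensus[pos] == "N":
            consensus[pos] = head[pos]
            gap_fills.append((offset + pos + 1, 1))
    merged_seq = seq_a[:offset] + "".join(consensus) + seq_b[overlap:]
    merged_id = f"{id_a}E" if not id_a.endswith("E") else id_a
    return merged_seq, MergeRecord(
        merged_id=merged_id,
        source_ids=[id_a, id_b],
        overlap_length=overlap,
        overlap_identity=identity,
        gap_fills=gap_fills,
    )


def merge_amg_scaffolds(
    scaffolds: dict[str, str],
    amg_assignments: dict[str, str],
    min_overlap: int = 1000,
    min_identity: float = 99.0,
) -> tuple[dict[str, str], list[MergeRecord]]:
    """Merge scaffolds that share an AMG symbol and overlap sufficiently.

    For each AMG symbol, scaffold pairs are tested for a dovetail overlap
    (> ``min_overlap`` bases at >= ``min_identity`` % identity, either order,
    reverse complement allowed); qualifying pairs are merged into a single
    extended sequence whose id carries a terminal "E". N positions inside the
    overlap are filled from whichever partner has a base there. Returns the
    updated scaffold dict (merged sources removed) and all merge records,
    including explanatory records for pairs that failed the thresholds.
    """
    scaffolds = dict(scaffolds)
    records: list[MergeRecord] = []
    by_symbol: dict[str, list[str]] = {}
    for sid, symbol in amg_assignments.items():
        by_symbol.setdefault(symbol, []).append(sid)
    for symbol in sorted(by_symbol):
        pool = sorted(by_symbol[symbol], key=lambda sid: (-len(scaffolds[sid]), sid))
        merged_any = True
        while merged_any and len(pool) > 1:
            merged_any = False
            for i in range(len(pool)):
                for j in range(len(pool)):
                    if i == j:
                        continue
                    a, b = pool[i], pool[j]
                    result = None
                    for b_seq in (scaffolds[b], revcomp(scaffolds[b])):
                        attempt = _try_merge(
                            a, scaffolds[a], b, b_seq, min_overlap, min_identity
                        )
                        if attempt is not None and (result is None or attempt[1].merged):
                            result = attempt
                        if result and result[1].merged:
                            break
                    if result is None:
                        continue
                    merged_seq, record = result
                    if not record.merged:
                        if i < j:  # keep one explanatory record per pair
                            records.append(record)
                        continue
                    records.append(record)
                    del scaffolds[a]
                    del scaffolds[b]
                    scaffolds[record.merged_id] = merged_seq
                    pool = [s for s in pool if s not in (a, b)] + [record.merged_id]
                    merged_any = True
                    break
                if merged_any:
                    break
    return scaffolds, records
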