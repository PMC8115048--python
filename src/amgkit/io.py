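"""File-format helpers: FASTA/FASTQ via Biopython, SAM via pysam, TSV tables."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from amgkit.genetics import revcomp


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(scaffolds: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="") for sid, seq in scaffolds.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for read_id, seq, qual in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def write_sam(
    reads: list[tuple[str, str, str]],
    placements: pd.DataFrame,
    lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write placed reads as a plain-text SAM file (pysam)."""
    import pysam

    names = sorted(lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": sid, "LN": lengths[sid]} for sid in names],
    }
    ref_index = {sid: i for i, sid in enumerate(names)}
    seq_by_id = {rid: (seq, qual) for rid, seq, qual in reads}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for row in placements.itertuples(index=False):
            seq, qual = seq_by_id[row.read_id]
            aln = pysam.AlignedSegment()
            aln.query_name = row.read_id
            if row.strand == "-":
                aln.flag = 16
                seq = revcomp(seq)  # SAM stores the reference-forward sequence
                qual = qual[::-1]
            else:
                aln.flag = 0
            aln.reference_id = ref_index[row.scaffold_id]
            aln.reference_start = row.start - 1
            aln.mapping_quality = 60
            aln.cigarstring = f"{len(seq)}M"
            aln.query_sequence = seq
            aln.query_qualities = pysam.qualitystring_to_array(qual)
            sam.write(aln)
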