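"""Readers and writers for the pipeline's tabular and sequence artifacts."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import Cassette
from .quant import CountMatrix


def write_cassette_fasta(cassettes: Sequence[Cassette], path) -> None:
    """Cassette FASTA, header = design_id."""
    records = [
        SeqRecord(Seq(c.full_seq), id=c.design.design_id, description="")
        for c in cassettes
    ]
    SeqIO.write(records, str(path), "fasta")


def write_reads_fasta(reads: Iterable[str], path, prefix: str = "read") -> None:
    records = [
        SeqRecord(Seq(r), id=f"{prefix}_{k}", description="")
        for k, r in enumerate(reads)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_counts_csv(cm: CountMatrix, counts_path, summary_path=None) -> None:
    """Counts CSV (rows = design_id) and optional per-sample summary."""
    cm.counts.rename_axis("design_id").to_csv(counts_path)
    if summary_path is not None:
        summary = pd.DataFrame(
            {
                "total_reads": cm.total_reads,
                "matched_reads": cm.matched_reads,
            }
        )
        summary["match_rate"] = summary["matched_reads"] / summary["total_reads"].where(
            summary["total_reads"] > 0, other=pd.NA
        )
        summary.rename_axis("sample_id").to_csv(summary_path)


def read_counts_csv(path) -> CountMatrix:
    df = pd.read_csv(path, index_col="design_id")
    totals = df.sum(axis=0)
    return CountMatrix(counts=df, total_reads=totals.copy(), matched_reads=totals.copy())


def read_annotation_csv(path) -> dict[str, str]:
    """gene -> category annotation."""
    df = pd.read_csv(path)
    return dict(zip(df["gene"], df["category"]))
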