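"""Thin FASTA/FASTQ/TSV helpers shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Return (id, sequence, phred qualities) per record."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(records: Iterable[tuple[str, str, list[int]]], path: str | Path) -> None:
    recs = []
    for rid, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
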