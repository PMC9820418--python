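"""FASTA/FASTQ/TSV input-output (thin wrappers over Biopython and pandas)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import SimRead


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path) -> list[SimRead]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [SimRead(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), fmt)]


def write_fastq(reads: list[SimRead], path: str | Path, quality: int = 20) -> None:
    with open(path, "w") as fh:
        qch = chr(quality + 33)
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{qch * len(read.sequence)}\n")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
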