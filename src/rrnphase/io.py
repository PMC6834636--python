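"""FASTA/FASTQ and tabular input/output helpers."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def read_fastq(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


def read_sequences(path) -> list[tuple[str, str]]:
    """Dispatch on extension: .fq/.fastq as FASTQ, anything else FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fq", ".fastq"):
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    SeqIO.write((SeqRecord(Seq(seq), id=rid, description="")
                 for rid, seq in records), str(path), "fasta")


def write_fastq(records: Iterable[tuple[str, str]], path,
                quality_char: str = "I") -> None:
    """Write reads with a constant placeholder quality (quality-agnostic)."""
    q = ord(quality_char) - 33

    def _records():
        for rid, seq in records:
            rec = SeqRecord(Seq(seq), id=rid, description="")
            rec.letter_annotations["phred_quality"] = [q] * len(seq)
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(str(path), sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(str(path), sep="\t")
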