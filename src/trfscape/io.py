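"""Shared file readers and writers.

Standard formats only: FASTA/FASTQ (via Biopython, gzip-transparent),
TSV matrices (pandas), GMT gene-set collections, and sample-metadata
tables. Every reader raises :class:`TrfIoError` with enough context to
locate a malformed record.
"""

from __future__ import annotations

import gzip
import io as _io
import os
from typing import Iterator

import pandas as pd
from Bio import SeqIO


class TrfIoError(ValueError):
    """Malformed or missing input file."""


def open_text(path: str | os.PathLike, mode: str = "rt"):
    """Open a possibly gzip-compressed text file transparently."""
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode, newline=None)


def read_fasta(path) -> list[tuple[str, str, str]]:
    """Read FASTA records as (id, description, sequence) tuples.

    Handles multi-line sequences and CRLF line endings; sequences are
    uppercased. Raises :class:`TrfIoError` if the file is missing or
    contains no records.
    """
    if not os.path.exists(os.fspath(path)):
        raise TrfIoError(f"FASTA file not found: {path}")
    records = []
    with open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append((rec.id, rec.description, str(rec.seq).upper()))
    if not records:
        raise TrfIoError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path) -> None:
    """Write (name, sequence) pairs as single-line FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def iter_fastq_sequences(path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file (qualities discarded).

    A truncated or malformed record raises :class:`TrfIoError` naming the
    index of the offending record.
    """
    if not os.path.exists(os.fspath(path)):
        raise TrfIoError(f"FASTQ file not found: {path}")
    with open_text(path) as handle:
        lines = iter(handle)
        idx = 0
        while True:
            try:
                header = next(lines)
            except StopIteration:
                return
            if not header.strip():
                continue
            chunk = []
            try:
                for _ in range(3):
                    chunk.append(next(lines))
            except StopIteration:
                raise TrfIoError(
                    f"{path}: truncated FASTQ record at index {idx}"
                ) from None
            if not header.startswith("@") or not chunk[1].startswith("+"):
                raise TrfIoError(f"{path}: malformed FASTQ record at index {idx}")
            seq = chunk[0].strip().upper()
            if len(chunk[2].strip()) != len(seq):
                raise TrfIoError(
                    f"{path}: quality/sequence length mismatch at record {idx}"
                )
            yield seq
            idx += 1


def write_fastq(sequences, path, quality_char: str = "I", prefix: str = "read") -> None:
    """Write sequences as 4-line FASTQ records with constant quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(sequences):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_tsv_matrix(path, index_col: int = 0) -> pd.DataFrame:
    """Read a TSV matrix with row labels in the first column."""
    if not os.path.exists(os.fspath(path)):
        raise TrfIoError(f"TSV file not found: {path}")
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv_matrix(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_metadata(path, required=("sample_id", "cohort", "condition")) -> pd.DataFrame:
    """Read the sample-metadata table (sample_id, cohort, condition, ...).

    Optional columns (os_time, os_event, stage, ssign, platform) are passed
    through untouched. Returns a frame indexed by sample_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrfIoError(f"{path}: metadata missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise TrfIoError(f"{path}: duplicate sample_id {dup!r}")
    return df.set_index("sample_id")


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    if not os.path.exists(os.fspath(path)):
        raise TrfIoError(f"GMT file not found: {path}")
    sets: dict[str, list[str]] = {}
    with open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TrfIoError(f"{path}:{lineno}: GMT line has <3 fields")
            name, _desc, *genes = fields
            sets[name] = [g for g in genes if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
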