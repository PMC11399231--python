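"""FASTA / delimited-table / embedding-matrix I/O.

FASTA goes through Biopython; tables through pandas. The delimited
default is tab-separated with a header; comma is accepted on read by
sniffing the header line. Every reader uppercases sequences and rejects
duplicate ids.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seqcore import CdsRecord, ProteinRecord
from .embedspace import EmbeddingSet

__all__ = [
    "read_fasta",
    "read_protein_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "read_embeddings",
    "write_embeddings",
    "write_manifest",
]


def _parse_fasta(path: str | Path) -> list[tuple[str, str]]:
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA")
    seen: set[str] = set()
    out = []
    for r in records:
        if not r.id:
            raise ValueError(f"{path}: record with empty header")
        if r.id in seen:
            raise ValueError(f"{path}: duplicate id {r.id!r}")
        seen.add(r.id)
        out.append((r.id, str(r.seq).upper()))
    return out


def read_fasta(path: str | Path) -> list[CdsRecord]:
    """Read nucleotide FASTA into CdsRecords (uppercased, U mapped to T)."""
    return [CdsRecord(id=i, sequence=s) for i, s in _parse_fasta(path)]


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into ProteinRecords (uppercased)."""
    return [ProteinRecord(id=i, sequence=s) for i, s in _parse_fasta(path)]


def write_fasta(
    records: Sequence[CdsRecord | ProteinRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records as FASTA with configurable line wrapping."""
    seen: set[str] = set()
    out = []
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate id {r.id!r}")
        seen.add(r.id)
        out.append(SeqRecord(Seq(r.sequence), id=r.id, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width or None)
        writer.write_file(out)


def read_table(
    path: str | Path, required: Sequence[str] = ("id",)
) -> pd.DataFrame:
    """Read a delimited metadata table (TSV default, comma sniffed).

    The ``id`` column (and any other ``required`` columns) must be
    present; unknown columns are preserved. Duplicate ids are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    if "id" in df.columns:
        df["id"] = df["id"].astype(str)
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise ValueError(f"{path}: duplicate id {dup.iloc[0]!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a metadata table as TSV, preserving column order."""
    df.to_csv(path, sep="\t", index=False)


def write_embeddings(E: EmbeddingSet, matrix_path: str | Path,
                     metadata_path: Optional[str | Path] = None) -> None:
    """Write an embedding set as a delimited matrix with an id column.

    The matrix file has columns ``id, e0..e{d-1}``; metadata goes to a
    sidecar table when ``metadata_path`` is given.
    """
    df = pd.DataFrame(E.matrix, columns=[f"e{j}" for j in range(E.d)])
    df.insert(0, "id", E.ids)
    write_table(df, matrix_path)
    if metadata_path is not None:
        meta = E.metadata.copy()
        meta.insert(0, "id", E.ids)
        write_table(meta, metadata_path)


def read_embeddings(matrix_path: str | Path,
                    metadata_path: Optional[str | Path] = None) -> EmbeddingSet:
    """Read an embedding set written by :func:`write_embeddings`."""
    df = read_table(matrix_path)
    ids = df["id"].tolist()
    matrix = df.drop(columns="id").to_numpy(dtype=float)
    if metadata_path is not None:
        meta = read_table(metadata_path)
        pos = {i: j for j, i in enumerate(meta["id"])}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise ValueError(f"metadata missing ids (e.g. {missing[:5]})")
        meta = meta.iloc[[pos[i] for i in ids]].drop(columns="id")
        meta = meta.reset_index(drop=True)
    else:
        meta = pd.DataFrame(index=range(len(ids)))
    return EmbeddingSet(ids=ids, matrix=matrix, metadata=meta)


def write_manifest(path: str | Path, **params) -> None:
    """Write a JSON run manifest (tool version + full parameterization)."""
    from . import __version__

    payload = {"tool": "codonlens", "version": __version__, **params}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
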