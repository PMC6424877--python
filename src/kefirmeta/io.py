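"""Tabular I/O: BLAST outfmt-6 hit tables, assignment TSVs, headered TSVs.

Everything the pipeline reads or writes is plain text.  TSV outputs carry a
single ``#schema=`` comment line so downstream consumers can detect format
drift; readers skip any ``#`` comment lines.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

SCHEMA_PREFIX = "#schema=kefirmeta/1"

#: The 12 standard BLAST tabular (outfmt 6) columns, in file order.
OUTFMT6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

#: Canonical internal names for hit-table columns.
HIT_COLUMNS = [
    "read_id",
    "subject_id",
    "percent_identity",
    "align_length",
    "query_length",
    "bitscore",
    "evalue",
    "subject_start",
    "subject_end",
]

_OUTFMT6_RENAME = {
    "qseqid": "read_id",
    "sseqid": "subject_id",
    "pident": "percent_identity",
    "length": "align_length",
    "sstart": "subject_start",
    "send": "subject_end",
}


def read_outfmt6(path, query_lengths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Read a headerless BLAST outfmt-6 TSV into the canonical hit table.

    ``query_length`` is taken from ``query_lengths`` when provided, otherwise
    approximated as ``max(qstart, qend)`` (full-length alignments make the two
    identical, and thresholds only ever divide by it).
    """
    raw = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    df = raw.rename(columns=_OUTFMT6_RENAME)
    if query_lengths is not None:
        df["query_length"] = df["read_id"].map(query_lengths)
        if df["query_length"].isna().any():
            missing = df.loc[df["query_length"].isna(), "read_id"].iloc[0]
            raise ValueError(f"no query length for read {missing!r}")
        df["query_length"] = df["query_length"].astype(int)
    else:
        df["query_length"] = raw[["qstart", "qend"]].max(axis=1).astype(int)
    return df[HIT_COLUMNS]


def write_outfmt6(hits: pd.DataFrame, path) -> None:
    """Write a canonical hit table as headerless 12-column outfmt-6."""
    out = pd.DataFrame(
        {
            "qseqid": hits["read_id"],
            "sseqid": hits["subject_id"],
            "pident": hits["percent_identity"],
            "length": hits["align_length"],
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": hits["query_length"],
            "sstart": hits["subject_start"],
            "send": hits["subject_end"],
            "evalue": hits["evalue"],
            "bitscore": hits["bitscore"],
        }
    )
    out.to_csv(path, sep="\t", index=False, header=False)


def read_assignments(path) -> dict[str, str]:
    """Read a two-column read→taxon TSV (one classifier's output)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, names=["read_id", "taxon_id"], header=0
    )
    return dict(zip(df["read_id"], df["taxon_id"]))


def write_assignments(assignments: Mapping[str, str], path) -> None:
    df = pd.DataFrame(
        {"read_id": list(assignments), "taxon_id": list(assignments.values())}
    )
    write_tsv(df, path)


def write_tsv(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    """Write a headered TSV with the schema comment line first."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(SCHEMA_PREFIX + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=float_format)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_lengths_tsv(path) -> dict[str, int]:
    """Two-column id→length TSV (the sequence-free dialect for reads/contigs)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    id_col, len_col = df.columns[:2]
    return dict(zip(df[id_col].astype(str), df[len_col].astype(int)))
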