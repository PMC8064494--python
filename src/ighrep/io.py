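"""Input readers: reads FASTA + metadata TSV, AIRR rearrangement TSV,
and the 10x ``filtered_contig_annotations`` CSV dialect."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .annotate import QueryRead

__all__ = ["read_fasta_with_metadata", "ingest_airr", "write_airr"]

_AIRR_REQUIRED = ("sequence_id", "sequence")
_10X_REQUIRED = ("barcode", "chain", "v_gene", "j_gene")


def read_fasta_with_metadata(fasta_path: str | Path,
                             metadata_path: str | Path) -> list[QueryRead]:
    """Reads FASTA plus a TSV with read_id, cell_id, individual_id, group,
    isotype columns; every FASTA record needs a metadata row."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    meta_by_id = {row["read_id"]: row for _, row in meta.iterrows()}
    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id not in meta_by_id:
            raise ValueError(f"read {rec.id!r} has no metadata row")
        row = meta_by_id[rec.id]
        reads.append(QueryRead(
            read_id=rec.id,
            sequence=str(rec.seq).upper(),
            cell_id=row.get("cell_id", ""),
            individual_id=row.get("individual_id", ""),
            group=row.get("group", "other") or "other",
            isotype=row.get("isotype", "unknown") or "unknown",
        ))
    if not reads:
        raise ValueError(f"no sequences in {fasta_path}")
    return reads


def _isotype_from_c_call(c_call: str) -> str:
    mapping = {"IGHA": "IgA", "IGHG": "IgG", "IGHM": "IgM",
               "IGHD": "IgD", "IGHE": "IgE"}
    for prefix, iso in mapping.items():
        if c_call.upper().startswith(prefix):
            return iso
    return "unknown"


def ingest_airr(path: str | Path, productive_only: bool = False,
                cell_barcode_whitelist: set[str] | None = None
                ) -> tuple[list[QueryRead], pd.DataFrame | None, dict]:
    """Load an AIRR rearrangement TSV or a 10x filtered_contig CSV.

    Returns (reads, passthrough table or None, QC counters). When the
    table already carries v/d/j calls the passthrough table (an
    AIRR-style DataFrame) can feed the repertoire statistics directly
    without re-alignment. ``productive_only`` drops rows whose
    ``productive`` column is false/False/F (dropped count reported in
    QC); the barcode whitelist emulates an upstream cell screen.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    qc = {"rows_in": len(df), "dropped_unproductive": 0,
          "dropped_not_whitelisted": 0, "dropped_non_igh": 0,
          "dropped_short": 0}

    if set(_10X_REQUIRED).issubset(df.columns):     # 10x contig dialect
        df = df.rename(columns={
            "barcode": "cell_id", "contig_id": "sequence_id",
            "v_gene": "v_call", "d_gene": "d_call", "j_gene": "j_call",
            "c_gene": "c_call", "cdr3_nt": "junction",
        })
        n0 = len(df)
        df = df[df["chain"].str.upper() == "IGH"]
        qc["dropped_non_igh"] = n0 - len(df)
    else:
        missing = [c for c in _AIRR_REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing mandatory AIRR columns: {missing}")
        if "cell_id" not in df.columns:
            df["cell_id"] = ""

    if cell_barcode_whitelist is not None:
        n0 = len(df)
        df = df[df["cell_id"].isin(cell_barcode_whitelist)]
        qc["dropped_not_whitelisted"] = n0 - len(df)
    if productive_only and "productive" in df.columns:
        n0 = len(df)
        truthy = df["productive"].str.upper().isin(("T", "TRUE", "1"))
        df = df[truthy]
        qc["dropped_unproductive"] = n0 - len(df)

    has_calls = "v_call" in df.columns and "j_call" in df.columns
    passthrough = df.reset_index(drop=True) if has_calls else None

    reads = []
    for _, row in df.iterrows():
        seq = str(row.get("sequence", "")).upper()
        if len(seq) < 60:
            qc["dropped_short"] += 1
            continue
        reads.append(QueryRead(
            read_id=str(row["sequence_id"]),
            sequence=seq,
            cell_id=str(row.get("cell_id", "")),
            individual_id=str(row.get("individual_id", "")),
            group=str(row.get("group", "other")) or "other",
            isotype=(str(row.get("isotype", "")) or
                     _isotype_from_c_call(str(row.get("c_call", "")))),
        ))
    qc["rows_out"] = len(df)
    return reads, passthrough, qc


def write_airr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)
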