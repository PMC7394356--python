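"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated UTF-8; ``#`` comment lines are ignored in count
tables.  Protein lengths come from either a FASTA file of protein sequences
(length = number of residues) or a two-column TSV.  Results tables are written
one row per protein, sorted by ascending p-value with ties broken by protein
id; rows without a p-value (newly detected / excluded) follow, ordered by id.
"""

from __future__ import annotations

import math
import os
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import (
    ParseError,
    RunDescriptor,
    SpectralCountMatrix,
    ValidationError,
    validate_runs,
)

PAIRWISE_COLUMNS = [
    "protein",
    "mean_nsaf_A",
    "mean_nsaf_B",
    "fold_change",
    "log2_fc",
    "p_value",
    "q_value",
    "status",
]

TREND_COLUMNS = ["protein", "slope", "intercept", "p_value", "trend", "n_points"]


def read_count_table(path: str | os.PathLike) -> SpectralCountMatrix:
    """Read a protein-by-run spectral-count TSV.

    First column is the protein id; remaining columns are run ids; cells are
    non-negative integer PSM counts.  Missing/empty cells are read as 0
    (non-identification carries zero spectral evidence).  Run metadata is not
    known at this point: each run gets a placeholder descriptor whose
    condition equals its run id; attach the real design with
    :meth:`SpectralCountMatrix.with_runs`.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 1:
        raise ParseError(f"{path}: no columns found")
    protein_col = df.columns[0]
    proteins = df[protein_col].astype(str)
    if proteins.duplicated().any():
        dupes = sorted(proteins[proteins.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate protein id(s): {dupes}")
    data = df.drop(columns=[protein_col])
    parsed = {}
    for col in data.columns:
        cells = data[col].fillna("").str.strip().replace("", "0")
        numeric = pd.to_numeric(cells, errors="coerce")
        if numeric.isna().any():
            row = proteins[numeric.isna()].iloc[0]
            raise ParseError(
                f"{path}: malformed count for protein {row!r} in run {col!r}"
            )
        if (numeric < 0).any() or not np.all(np.mod(numeric, 1) == 0):
            row = proteins[(numeric < 0) | (np.mod(numeric, 1) != 0)].iloc[0]
            raise ValidationError(
                f"{path}: count for protein {row!r} in run {col!r} is not a "
                "non-negative integer"
            )
        parsed[col] = numeric.astype(np.int64)
    counts = pd.DataFrame(parsed, dtype=np.int64)
    counts.index = pd.Index(proteins, name="protein")
    runs = [
        RunDescriptor(run_id=c, condition=c, bio_rep=1, tech_rep=1)
        for c in counts.columns
    ]
    return SpectralCountMatrix(counts, runs)


def write_count_table(m: SpectralCountMatrix, path: str | os.PathLike) -> None:
    out = m.counts.copy()
    out.index.name = "protein"
    out.to_csv(path, sep="\t")


def read_protein_lengths(path: str | os.PathLike, format: str = "auto") -> pd.Series:
    """Read protein lengths (amino acids) from FASTA or a two-column TSV.

    With ``format="auto"`` the format is inferred from the extension
    (``.fa/.fasta/.faa`` -> FASTA, otherwise TSV).
    """
    if format == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        format = "fasta" if ext in {".fa", ".fasta", ".faa"} else "tsv"
    if format == "fasta":
        lengths: dict[str, int] = {}
        for record in SeqIO.parse(str(path), "fasta"):
            if record.id in lengths:
                raise ValidationError(f"{path}: duplicate FASTA record {record.id!r}")
            lengths[record.id] = len(record.seq)
        return pd.Series(lengths, dtype=np.int64, name="length")
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] != 2:
            raise ParseError(f"{path}: expected exactly two columns")
        # tolerate an optional header row
        if len(df) and str(df.iloc[0, 1]).strip().lower() in {"length", "len"}:
            df = df.iloc[1:]
        if df.empty:
            return pd.Series(dtype=np.int64, name="length")
        numeric = pd.to_numeric(df.iloc[:, 1], errors="coerce")
        if numeric.isna().any():
            bad = df.iloc[:, 0][numeric.isna()].iloc[0]
            raise ParseError(f"{path}: malformed length for protein {bad!r}")
        series = pd.Series(
            numeric.astype(np.int64).to_numpy(),
            index=df.iloc[:, 0].astype(str).to_numpy(),
            name="length",
        )
        if series.index.has_duplicates:
            dupes = sorted(series.index[series.index.duplicated()])
            raise ValidationError(f"{path}: duplicate protein id(s): {dupes}")
        return series
    raise ValueError(f"unknown length format: {format!r}")


def write_lengths_table(lengths: pd.Series, path: str | os.PathLike) -> None:
    lengths.rename("length").rename_axis("protein").to_csv(path, sep="\t", header=False)


def read_design_table(path: str | os.PathLike) -> list[RunDescriptor]:
    """Read the experimental design TSV.

    Columns: ``run_id``, ``condition``, ``bio_rep``, ``tech_rep`` and an
    optional ``time_h``.  The descriptors are validated: unique run ids,
    unique (condition, bio_rep, tech_rep) triples, and consistent time_h
    within each condition.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"run_id", "condition", "bio_rep", "tech_rep"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing design column(s): {sorted(missing)}")
    runs: list[RunDescriptor] = []
    for _, row in df.iterrows():
        time_h: float | None = None
        if "time_h" in df.columns:
            raw = row["time_h"]
            if isinstance(raw, str) and raw.strip():
                time_h = float(raw)
        try:
            runs.append(
                RunDescriptor(
                    run_id=str(row["run_id"]),
                    condition=str(row["condition"]),
                    bio_rep=int(row["bio_rep"]),
                    tech_rep=int(row["tech_rep"]),
                    time_h=time_h,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: malformed design row {row.to_dict()}") from exc
    validate_runs(runs)
    return runs


def write_design_table(runs: Sequence[RunDescriptor], path: str | os.PathLike) -> None:
    rows = [
        {
            "run_id": r.run_id,
            "condition": r.condition,
            "time_h": "" if r.time_h is None else r.time_h,
            "bio_rep": r.bio_rep,
            "tech_rep": r.tech_rep,
        }
        for r in runs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_experiment(
    counts_path: str | os.PathLike,
    lengths_path: str | os.PathLike,
    design_path: str | os.PathLike,
    lengths_format: str = "auto",
) -> SpectralCountMatrix:
    """Read counts, lengths and design and return the fully annotated matrix."""
    m = read_count_table(counts_path)
    runs = read_design_table(design_path)
    lengths = read_protein_lengths(lengths_path, format=lengths_format)
    return m.with_runs(runs).with_lengths(lengths)


def _record_sort_key(rec) -> tuple[int, float, str]:
    p = getattr(rec, "p_value", None)
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return (1, 0.0, rec.protein)
    return (0, float(p), rec.protein)


def records_to_frame(records: Sequence) -> pd.DataFrame:
    """Convert differential or trend records to a sorted DataFrame."""
    records = sorted(records, key=_record_sort_key)
    if records and hasattr(records[0], "slope"):
        columns = TREND_COLUMNS
    else:
        columns = PAIRWISE_COLUMNS
    rows = [{c: getattr(r, c) for c in columns} for r in records]
    return pd.DataFrame(rows, columns=columns)


def write_records_table(records: Sequence, path: str | os.PathLike) -> None:
    """Write pairwise or trend records as a results TSV.

    Row order is ascending p-value with ties broken by protein id; records
    without a p-value (newly detected / excluded) come last, ordered by id.
    An empty record set produces a header-only file (pairwise schema).
    """
    frame = records_to_frame(records)
    if frame.empty and not len(frame.columns):
        frame = pd.DataFrame(columns=PAIRWISE_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
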