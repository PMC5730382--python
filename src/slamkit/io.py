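"""Shared file I/O and validation.

Conventions: UTF-8 TSV/CSV with a required header row; "NA" is the only
missing-value marker; coordinates are 0-based half-open internally (BED
intervals are read as such). No function mutates its inputs on disk.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codon import CdsSequence, ProtectedIntervals
from .fc import MEASUREMENT_COLUMNS
from .kinetics import FluorescenceTrace
from .qpcr import CQ_COLUMNS, validate_cq_table
from .rip import CountMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_bed_intervals",
    "read_counts",
    "write_counts",
    "read_trace",
    "read_cq_table",
    "read_measurements",
    "write_json",
]

_NA_VALUES = ["NA"]


def read_fasta(path) -> list[CdsSequence]:
    """Read CDS records; sequences are uppercased, duplicate ids rejected."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    seen: set[str] = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        out.append(CdsSequence(id=rec.id, seq=str(rec.seq).upper()))
    return out


def write_fasta(sequences, path) -> None:
    """Write uppercase FASTA with 60-column wrapping."""
    records = [
        SeqRecord(Seq(s.seq), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def read_bed_intervals(path) -> ProtectedIntervals:
    """BED intervals in CDS coordinates, 0-based half-open (cols 2 and 3)."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: BED line needs >= 3 columns: {line!r}")
            intervals.append((int(parts[1]), int(parts[2])))
    return ProtectedIntervals(intervals)


def read_counts(path, sep: str = "\t") -> CountMatrix:
    """Count table: first column transcript_id, then `<role>_<replicate>` columns.

    Cells must be nonnegative integers written as plain digits; scientific
    notation, floats and negatives are rejected with row/column context.
    """
    # counts admit no missing values: every cell must be a literal integer
    df = pd.read_csv(path, sep=sep, dtype=str, na_values=[], keep_default_na=False)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need transcript_id plus >= 2 sample columns")
    df = df.set_index(df.columns[0])
    parsed = pd.DataFrame(index=df.index)
    for col in df.columns:
        cells = df[col]
        bad = ~cells.str.fullmatch(r"\d+")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"{path}: non-integer count {cells[bad].iloc[0]!r} "
                f"at row {row!r}, column {col!r}"
            )
        parsed[col] = cells.astype(np.int64)
    parsed.index.name = "transcript_id"
    return CountMatrix.from_frame(parsed)


def write_counts(m: CountMatrix, path, sep: str = "\t") -> None:
    m.counts.to_csv(path, sep=sep, index_label="transcript_id")


def read_trace(path) -> FluorescenceTrace:
    """Trace CSV with columns time_min, intensity and optional reference."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    for col in ("time_min", "intensity"):
        if col not in df.columns:
            raise ValueError(f"{path}: trace CSV needs column {col!r}")
    return FluorescenceTrace(
        times=df["time_min"].astype(float).to_numpy(),
        intensities=df["intensity"].astype(float).to_numpy(),
        reference=(
            df["reference"].astype(float).to_numpy() if "reference" in df.columns else None
        ),
    )


def read_cq_table(path) -> pd.DataFrame:
    """Cq CSV with columns target, sample, cq, is_no_rt ('NA' = undetermined Cq)."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    missing = set(CQ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: Cq CSV missing columns {sorted(missing)}")
    df["cq"] = pd.to_numeric(df["cq"], errors="raise")
    df["is_no_rt"] = df["is_no_rt"].map(
        {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
    )
    if df["is_no_rt"].isna().any():
        raise ValueError(f"{path}: is_no_rt must be True/False")
    return validate_cq_table(df)


def read_measurements(path) -> pd.DataFrame:
    """Furrow measurement CSV: embryo, stage_min, furrow, channel, intensity."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    missing = set(MEASUREMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: measurement CSV missing columns {sorted(missing)}")
    df["stage_min"] = pd.to_numeric(df["stage_min"], errors="raise")
    df["intensity"] = pd.to_numeric(df["intensity"], errors="raise")
    return df


def _json_default(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o).__name__}")


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
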