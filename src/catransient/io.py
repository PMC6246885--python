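"""Readers and writers for every tabular format the pipeline touches.

Trace tables are wide CSV (first column frame index or time in seconds, one
column per cell), the dialect produced by ImageJ-style ROI time-series
exports. Cell metadata and tidy results are CSV; hemisegment heatmap
matrices are TSV in the matrix2png convention (rows = preparations, columns
= hemisegments T3L..A5R). Missing values are schema errors, never imputed.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (CELL_TABLE_COLUMNS, HEMISEGMENT_ORDER, SchemaError,
                         TraceMatrix, check_uniform_spacing, validate_cell_table)


def read_trace_table(path, stim_time_s: float, dialect: str = "auto",
                     frame_interval_s: float | None = None) -> TraceMatrix:
    """Read a wide ROI trace table.

    dialect 'seconds': first column is time in seconds.
    dialect 'frames': first column is a frame index; ``frame_interval_s``
    converts it to seconds (frame 0 = 0 s).
    dialect 'auto': 'frames' when a frame interval is declared, else 'seconds'.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trace table not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a time column plus at least one cell column")
    cell_ids = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:]
    bad = values.isna() | ~values.map(np.isreal)
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"{path}: missing or non-numeric value at cell {cell_ids[c]}, frame {r}")
    F = values.to_numpy(dtype=float).T

    first = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    if first.isna().any():
        raise SchemaError(f"{path}: non-numeric time/frame value at row "
                          f"{int(first.isna().idxmax())}")
    if dialect == "auto":
        dialect = "frames" if frame_interval_s is not None else "seconds"
    if dialect == "frames":
        if frame_interval_s is None:
            raise SchemaError("frame-index dialect requires frame_interval_s")
        idx = first.to_numpy(dtype=float)
        times = (idx - idx[0]) * frame_interval_s
    elif dialect == "seconds":
        times = first.to_numpy(dtype=float)
    else:
        raise SchemaError(f"unknown dialect {dialect!r}")
    check_uniform_spacing(times)
    return TraceMatrix(cell_ids=cell_ids, times_s=times, F=F,
                       stim_time_s=stim_time_s)


def write_trace_table(traces: TraceMatrix, path) -> None:
    """Write a TraceMatrix as a wide CSV with a time_s first column."""
    traces.to_frame().to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell table not found: {path}")
    return validate_cell_table(pd.read_csv(path, dtype={"cell_id": str}))


def write_cell_table(cells: pd.DataFrame, path) -> None:
    validate_cell_table(cells)
    cells.loc[:, list(CELL_TABLE_COLUMNS)].to_csv(path, index=False)


def write_tidy_table(table: pd.DataFrame, path) -> None:
    """Long-format results table; one metric per row, deterministic columns."""
    table.to_csv(path, index=False)


def read_tidy_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_heatmap_matrix(per_prep: pd.DataFrame, path) -> None:
    """Write percent-responders as a prep x hemisegment TSV matrix.

    ``per_prep`` needs columns prep_id, hemisegment (T3L..A5R labels) and
    percent_responders; hemisegments with no cells may carry NaN (written as
    NA), but every one of the 12 columns must be present for every prep.
    Rows are ordered by prep_id, columns in the canonical T3L..A5R order.
    """
    required = {"prep_id", "hemisegment", "percent_responders"}
    if not required <= set(per_prep.columns):
        raise SchemaError(f"heatmap input missing columns: "
                          f"{sorted(required - set(per_prep.columns))}")
    unknown = set(per_prep["hemisegment"]) - set(HEMISEGMENT_ORDER)
    if unknown:
        raise SchemaError(f"unknown hemisegment labels: {sorted(unknown)}")
    wide = per_prep.pivot_table(index="prep_id", columns="hemisegment",
                                values="percent_responders", dropna=False)
    gaps = [h for h in HEMISEGMENT_ORDER if h not in wide.columns]
    if gaps:
        raise SchemaError(f"heatmap matrix incomplete; missing hemisegments: {gaps}")
    wide = wide.loc[sorted(wide.index), list(HEMISEGMENT_ORDER)]
    wide.to_csv(path, sep="\t", na_rep="NA", index_label="prep_id")


def read_heatmap_matrix(path) -> pd.DataFrame:
    wide = pd.read_csv(path, sep="\t", index_col="prep_id", na_values=["NA"])
    missing = [h for h in HEMISEGMENT_ORDER if h not in wide.columns]
    if missing:
        raise SchemaError(f"heatmap matrix missing hemisegments: {missing}")
    return wide[list(HEMISEGMENT_ORDER)]
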