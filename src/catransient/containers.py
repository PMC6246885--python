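"""Core in-memory containers shared across the pipeline.

A recording is a matrix of raw fluorescence values (cells x frames) plus the
frame clock and the stimulus (withdrawal) time; normalization produces a
matching matrix of ΔF/F (or release fraction) values. Cell metadata lives in
an ordinary pandas DataFrame validated against a closed vocabulary of
ventral-ganglion hemisegments (T3-A5, left/right).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENTS = ("T3", "A1", "A2", "A3", "A4", "A5")
SIDES = ("L", "R")
#: Canonical column order for hemisegment matrices: T3L, T3R, A1L, ... A5R.
HEMISEGMENT_ORDER = tuple(f"{seg}{side}" for seg in SEGMENTS for side in SIDES)

CELL_TABLE_COLUMNS = ("cell_id", "prep_id", "segment", "hemisegment",
                      "condition", "genotype")

SPACING_TOL = 1e-6


class SchemaError(ValueError):
    """Raised when a table or matrix violates its declared schema."""


def check_uniform_spacing(times_s: np.ndarray, tol: float = SPACING_TOL) -> float:
    """Validate strictly increasing, uniformly spaced frame times; return dt."""
    times_s = np.asarray(times_s, dtype=float)
    if times_s.ndim != 1 or times_s.size < 2:
        raise SchemaError("need at least two frame times")
    dt = np.diff(times_s)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise SchemaError(f"frame times not strictly increasing at frame {i + 1}")
    dev = np.abs(dt - dt[0])
    if dev.max() > tol:
        i = int(np.argmax(dev))
        raise SchemaError(
            f"non-uniform frame spacing at frame {i + 1}: "
            f"interval {dt[i]:g} s vs {dt[0]:g} s"
        )
    return float(dt[0])


@dataclass
class TraceMatrix:
    """Raw fluorescence traces, one row per cell, one column per frame."""

    cell_ids: list[str]
    times_s: np.ndarray
    F: np.ndarray
    stim_time_s: float

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise SchemaError("F must be a 2-D cells x frames array")
        if self.F.shape != (len(self.cell_ids), self.times_s.size):
            raise SchemaError(
                f"shape mismatch: {len(self.cell_ids)} cells, "
                f"{self.times_s.size} frames, F is {self.F.shape}"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise SchemaError("duplicate cell ids")
        check_uniform_spacing(self.times_s)
        if not np.all(np.isfinite(self.F)):
            i, j = np.argwhere(~np.isfinite(self.F))[0]
            raise SchemaError(
                f"non-finite fluorescence at cell {self.cell_ids[i]}, frame {j}"
            )
        if np.any(self.F < 0):
            i, j = np.argwhere(self.F < 0)[0]
            raise SchemaError(
                f"negative fluorescence at cell {self.cell_ids[i]}, frame {j}"
            )
        if not (self.times_s[0] <= self.stim_time_s <= self.times_s[-1]):
            raise SchemaError(
                f"stim_time_s={self.stim_time_s} outside recording span "
                f"[{self.times_s[0]}, {self.times_s[-1]}]"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return int(self.times_s.size)

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])

    def to_frame(self) -> pd.DataFrame:
        """Wide table: time_s column plus one column per cell."""
        out = pd.DataFrame({"time_s": self.times_s})
        for i, cid in enumerate(self.cell_ids):
            out[cid] = self.F[i]
        return out


@dataclass
class DffMatrix:
    """Normalized traces: ΔF/F in response mode, (F0-Ft)/F0 in release mode."""

    cell_ids: list[str]
    times_s: np.ndarray
    dff: np.ndarray
    baseline_F0: np.ndarray
    stim_time_s: float
    mode: str = "response"

    def __post_init__(self) -> None:
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.dff = np.asarray(self.dff, dtype=float)
        self.baseline_F0 = np.asarray(self.baseline_F0, dtype=float)
        if self.mode not in ("response", "release"):
            raise SchemaError(f"mode must be 'response' or 'release', got {self.mode!r}")
        if self.dff.shape != (len(self.cell_ids), self.times_s.size):
            raise SchemaError("dff shape does not match cell_ids x times_s")
        if self.baseline_F0.shape != (len(self.cell_ids),):
            raise SchemaError("baseline_F0 must hold one value per cell")
        if np.any(self.baseline_F0 <= 0):
            i = int(np.argmax(self.baseline_F0 <= 0))
            raise SchemaError(f"non-positive baseline for cell {self.cell_ids[i]}")
        check_uniform_spacing(self.times_s)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


def validate_cell_table(cells: pd.DataFrame) -> pd.DataFrame:
    """Validate cell metadata against the closed hemisegment vocabulary."""
    missing = [c for c in CELL_TABLE_COLUMNS if c not in cells.columns]
    if missing:
        raise SchemaError(f"cell table missing columns: {missing}")
    if cells["cell_id"].duplicated().any():
        dup = cells.loc[cells["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise SchemaError(f"duplicate cell_id {dup!r}")
    bad_seg = set(cells["segment"]) - set(SEGMENTS)
    if bad_seg:
        raise SchemaError(f"unknown segment labels: {sorted(bad_seg)}")
    bad_side = set(cells["hemisegment"]) - set(SIDES)
    if bad_side:
        raise SchemaError(f"unknown hemisegment labels: {sorted(bad_side)}")
    return cells


def hemisegment_label(segment: str, side: str) -> str:
    return f"{segment}{side}"
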