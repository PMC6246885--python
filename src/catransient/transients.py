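"""Trace-level quantification: ΔF/F, release, responder calls, AUC, topography.

The normalized signal is ΔF/F = (F_t - F_0)/F_0 with F_0 the mean
fluorescence of the first 10 recorded frames of each cell (release mode uses
(F_0 - F_t)/F_0 so that fluorescence loss reads positive). A cell is a
responder when its post-stimulus ΔF/F reaches 1.5 at any frame; percent
responders is 100 x responders/total. Response magnitude is the trapezoidal
integral of ΔF/F over a time window (full 60-600 s, initiation 60-300 s,
maintenance 300-600 s by default), negative excursions included.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (HEMISEGMENT_ORDER, SchemaError, DffMatrix,
                         TraceMatrix, hemisegment_label, validate_cell_table)

DEFAULT_THRESHOLD = 1.5
DEFAULT_BASELINE_FRAMES = 10

#: Default phase windows, seconds from recording start (stimulus at 60 s).
DEFAULT_WINDOWS = {"full": (60.0, 600.0),
                   "initial": (60.0, 300.0),
                   "late": (300.0, 600.0)}


@dataclass(frozen=True)
class ClassifierConfig:
    """Responder rule: post-stimulus ΔF/F at or above the threshold."""

    threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise SchemaError(f"threshold={self.threshold} must be > 0")


def _baseline(traces: TraceMatrix, n_baseline_frames: int) -> np.ndarray:
    if n_baseline_frames < 1:
        raise SchemaError("n_baseline_frames must be >= 1")
    if traces.n_frames <= n_baseline_frames:
        raise SchemaError(
            f"trace has {traces.n_frames} frames, need more than the "
            f"{n_baseline_frames}-frame baseline window")
    F0 = traces.F[:, :n_baseline_frames].mean(axis=1)
    if np.any(F0 <= 0):
        i = int(np.argmax(F0 <= 0))
        raise SchemaError(f"non-positive baseline F0 for cell {traces.cell_ids[i]}")
    return F0


def compute_dff(traces: TraceMatrix,
                n_baseline_frames: int = DEFAULT_BASELINE_FRAMES) -> DffMatrix:
    """ΔF/F = (F_t - F_0)/F_0 per cell, F_0 = mean of the first frames."""
    F0 = _baseline(traces, n_baseline_frames)
    dff = (traces.F - F0[:, None]) / F0[:, None]
    return DffMatrix(cell_ids=list(traces.cell_ids), times_s=traces.times_s,
                     dff=dff, baseline_F0=F0, stim_time_s=traces.stim_time_s,
                     mode="response")


def compute_release(traces: TraceMatrix,
                    n_baseline_frames: int = DEFAULT_BASELINE_FRAMES) -> DffMatrix:
    """Release = (F_0 - F_t)/F_0; fluorescence loss reads positive."""
    F0 = _baseline(traces, n_baseline_frames)
    rel = (F0[:, None] - traces.F) / F0[:, None]
    return DffMatrix(cell_ids=list(traces.cell_ids), times_s=traces.times_s,
                     dff=rel, baseline_F0=F0, stim_time_s=traces.stim_time_s,
                     mode="release")


def _post_stim_mask(dff: DffMatrix, stim_time_s: float | None) -> tuple[float, np.ndarray]:
    stim = dff.stim_time_s if stim_time_s is None else float(stim_time_s)
    if not (dff.times_s[0] <= stim <= dff.times_s[-1]):
        raise SchemaError(f"stim_time_s={stim} outside recording span")
    return stim, dff.times_s >= stim


def peak_amplitude(dff: DffMatrix, stim_time_s: float | None = None) -> pd.DataFrame:
    """Per-cell maximum post-stimulus signal and the time it occurs."""
    stim, mask = _post_stim_mask(dff, stim_time_s)
    sub = dff.dff[:, mask]
    t_sub = dff.times_s[mask]
    idx = np.argmax(sub, axis=1)
    return pd.DataFrame({
        "cell_id": dff.cell_ids,
        "peak_dff": sub[np.arange(dff.n_cells), idx],
        "peak_time_s": t_sub[idx],
    })


def classify_responders(dff: DffMatrix,
                        cfg: ClassifierConfig | None = None,
                        stim_time_s: float | None = None) -> pd.DataFrame:
    """Call responders: post-stimulus peak at or above the threshold.

    Pre-stimulus frames are never counted, so an excursion confined to the
    baseline period does not make a cell a responder.
    """
    cfg = cfg or ClassifierConfig()
    peaks = peak_amplitude(dff, stim_time_s)
    peaks["is_responder"] = peaks["peak_dff"] >= cfg.threshold
    return peaks[["cell_id", "is_responder", "peak_dff", "peak_time_s"]]


def percent_responders(calls: pd.DataFrame, cells: pd.DataFrame | None = None,
                       by: str | list[str] | None = None):
    """Percent responders = 100 x n_responders / n_cells, overall or per group."""
    if len(calls) == 0:
        raise SchemaError("no cells to classify: empty call table")
    if by is None:
        return 100.0 * float(calls["is_responder"].sum()) / len(calls)
    merged = calls
    if cells is not None:
        merged = calls.merge(cells, on="cell_id", how="left", validate="1:1")
    cols = [by] if isinstance(by, str) else list(by)
    missing = [c for c in cols if c not in merged.columns]
    if missing:
        raise SchemaError(f"grouping columns not found: {missing} "
                          "(pass the cell metadata table)")
    grp = merged.groupby(cols, sort=True)["is_responder"]
    return 100.0 * grp.sum() / grp.count()


@dataclass
class SegmentSummary:
    """Per-prep hemisegment percentages plus the across-prep mean ± SEM."""

    per_prep: pd.DataFrame     # prep_id, hemisegment, n_cells, n_responders, percent
    across_preps: pd.DataFrame  # hemisegment, n_preps, mean_percent, sem_percent


def segment_topography(calls: pd.DataFrame, cells: pd.DataFrame) -> SegmentSummary:
    """Responder topography over hemisegments T3L..A5R, per preparation.

    Hemisegments with no sampled cells in a prep carry NaN percent (written
    as NA in the heatmap matrix). The across-prep SEM uses the n-1 standard
    deviation over preps that sampled the hemisegment.
    """
    validate_cell_table(cells)
    merged = calls.merge(cells, on="cell_id", how="left", validate="1:1")
    if merged["segment"].isna().any():
        unknown = merged.loc[merged["segment"].isna(), "cell_id"].iloc[0]
        raise SchemaError(f"cell {unknown!r} missing from the cell table")
    merged["hemiseg"] = [hemisegment_label(s, h) for s, h
                         in zip(merged["segment"], merged["hemisegment"])]

    counts = (merged.groupby(["prep_id", "hemiseg"], sort=True)["is_responder"]
              .agg(n_cells="count", n_responders="sum").reset_index())
    counts["percent_responders"] = 100.0 * counts["n_responders"] / counts["n_cells"]

    preps = sorted(merged["prep_id"].unique())
    full = pd.MultiIndex.from_product([preps, HEMISEGMENT_ORDER],
                                      names=["prep_id", "hemiseg"])
    per_prep = (counts.set_index(["prep_id", "hemiseg"])
                .reindex(full).reset_index()
                .rename(columns={"hemiseg": "hemisegment"}))
    per_prep["n_cells"] = per_prep["n_cells"].fillna(0).astype(int)
    per_prep["n_responders"] = per_prep["n_responders"].fillna(0).astype(int)

    def _summ(g: pd.Series) -> pd.Series:
        vals = g.dropna()
        n = len(vals)
        sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"n_preps": n,
                          "mean_percent": vals.mean() if n else np.nan,
                          "sem_percent": sem})

    across = (per_prep.groupby("hemisegment", sort=False)["percent_responders"]
              .apply(_summ).unstack().reindex(list(HEMISEGMENT_ORDER))
              .reset_index())
    across["n_preps"] = across["n_preps"].fillna(0).astype(int)
    return SegmentSummary(per_prep=per_prep, across_preps=across)


def auc(dff: DffMatrix, window: tuple[float, float],
        cells: list[str] | None = None, method: str = "trapezoid",
        label: str | None = None) -> pd.DataFrame:
    """Integrate the normalized signal over [start_s, end_s], per cell.

    Trapezoidal rule on the frame grid, with linear interpolation of the
    signal at window boundaries that fall between frames; windows that share
    a grid-point boundary therefore add exactly. ``method='rectangular'``
    gives the left-rectangle sum (value x frame interval over frames in
    [start, end)) as a cross-check. Negative excursions are never clipped.
    """
    start, end = float(window[0]), float(window[1])
    if not start < end:
        raise SchemaError(f"empty window [{start}, {end})")
    t = dff.times_s
    if start < t[0] or end > t[-1]:
        raise SchemaError(f"window [{start}, {end}] outside recording span "
                          f"[{t[0]}, {t[-1]}]")
    if cells is None:
        idx = np.arange(dff.n_cells)
    else:
        pos = {c: i for i, c in enumerate(dff.cell_ids)}
        missing = [c for c in cells if c not in pos]
        if missing:
            raise SchemaError(f"cells not in matrix: {missing}")
        idx = np.array([pos[c] for c in cells], dtype=int)

    y = dff.dff[idx]
    if method == "trapezoid":
        inner = (t > start) & (t < end)
        grid = np.concatenate([[start], t[inner], [end]])
        y0 = np.array([np.interp(start, t, row) for row in y])
        y1 = np.array([np.interp(end, t, row) for row in y])
        vals = np.column_stack([y0, y[:, inner], y1])
        areas = np.trapezoid(vals, grid, axis=1)
    elif method == "rectangular":
        mask = (t >= start) & (t < end)
        areas = y[:, mask].sum(axis=1) * dff.frame_interval_s
    else:
        raise SchemaError(f"unknown AUC method {method!r}")

    return pd.DataFrame({
        "cell_id": [dff.cell_ids[i] for i in idx],
        "window": label if label is not None else f"{start:g}-{end:g}s",
        "start_s": start,
        "end_s": end,
        "auc": areas,
    })


def phase_auc_table(dff: DffMatrix,
                    windows: dict[str, tuple[float, float]] | None = None,
                    calls: pd.DataFrame | None = None,
                    subset: str = "responders",
                    method: str = "trapezoid") -> pd.DataFrame:
    """AUC over named phase windows, by default for responder cells only.

    When a call table is supplied and ``subset='responders'`` the integral is
    computed over responders only (how the study quantified evoked traces);
    ``subset='all'`` pools every cell, the mode used when no cell responds.
    """
    windows = windows or DEFAULT_WINDOWS
    cell_sel: list[str] | None = None
    if calls is not None and subset == "responders":
        cell_sel = calls.loc[calls["is_responder"], "cell_id"].tolist()
    elif subset not in ("responders", "all"):
        raise SchemaError(f"unknown subset {subset!r}")
    parts = [auc(dff, win, cells=cell_sel, method=method, label=name)
             for name, win in windows.items()]
    return pd.concat(parts, ignore_index=True)
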