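"""Group-level statistics: Student t, one-way ANOVA, Tukey HSD, letter
grouping, pupariation batch summaries, and the preference index.

Tests are authored from the classical sums-of-squares formulas (the Tukey
step uses the studentized-range distribution with the Tukey-Kramer
adjustment for unequal group sizes) so that every number the pipeline
reports is reproducible from first principles; independent library routines
serve as cross-checks in the test suite, not as the implementation.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SchemaError

ALPHA_DEFAULT = 0.05


def _as_groups(groups) -> list[tuple[str, np.ndarray]]:
    if isinstance(groups, Mapping):
        items = list(groups.items())
    else:
        items = [(name, vals) for name, vals in groups]
    out = []
    for name, vals in items:
        arr = np.asarray(vals, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise SchemaError(f"group {name!r} must be a non-empty 1-D sample")
        out.append((str(name), arr))
    return out


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float
    degenerate: bool = False


def t_test_two_tailed(a, b, equal_var: bool = True) -> TTestResult:
    """Two-sample two-tailed Student t test (pooled variance by default).

    Welch's correction is available via ``equal_var=False``. Zero combined
    variance is handled explicitly: equal means give p = 1, unequal means a
    degenerate p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise SchemaError("each sample needs n >= 2 for a t test")
    m1, m2 = a.mean(), b.mean()
    v1, v2 = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = n1 + n2 - 2
    if se2 == 0.0:
        if m1 == m2:
            return TTestResult(0.0, float(df), 1.0, degenerate=True)
        return TTestResult(math.copysign(math.inf, m1 - m2), float(df), 0.0,
                           degenerate=True)
    t = (m1 - m2) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    ms_within: float
    degenerate: bool = False


def one_way_anova(groups) -> AnovaResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    gs = _as_groups(groups)
    if len(gs) < 2:
        raise SchemaError("ANOVA needs at least two groups")
    small = [name for name, v in gs if v.size < 2]
    if small:
        raise SchemaError(f"groups with n < 2 cannot enter the ANOVA: {small}")
    all_vals = np.concatenate([v for _, v in gs])
    grand = all_vals.mean()
    k = len(gs)
    N = all_vals.size
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for _, v in gs)
    ss_within = sum(((v - v.mean()) ** 2).sum() for _, v in gs)
    dfb, dfw = k - 1, N - k
    msb = ss_between / dfb
    msw = ss_within / dfw
    if msw == 0.0:
        if msb == 0.0:
            return AnovaResult(0.0, dfb, dfw, 1.0, 0.0, degenerate=True)
        return AnovaResult(math.inf, dfb, dfw, 0.0, 0.0, degenerate=True)
    F = msb / msw
    p = stats.f.sf(F, dfb, dfw)
    return AnovaResult(float(F), dfb, dfw, float(p), float(msw))


def tukey_hsd(groups) -> pd.DataFrame:
    """Tukey's multiple-comparison test over all group pairs.

    The studentized-range statistic q = |m_i - m_j| / sqrt(MSW/2 (1/n_i + 1/n_j))
    is referred to the studentized-range distribution with k groups and the
    within-groups degrees of freedom (Tukey-Kramer for unequal n).
    """
    gs = _as_groups(groups)
    an = one_way_anova(gs)
    k = len(gs)
    rows = []
    for (na, va), (nb, vb) in itertools.combinations(gs, 2):
        diff = va.mean() - vb.mean()
        if an.ms_within == 0.0:
            p_adj = 1.0 if diff == 0.0 else 0.0
            q = 0.0 if diff == 0.0 else math.inf
        else:
            se = math.sqrt(an.ms_within / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            q = abs(diff) / se
            p_adj = float(stats.studentized_range.sf(q, k, an.df_within))
        rows.append((na, nb, float(diff), float(q), min(max(p_adj, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "q", "p_adj"])


def compact_letter_display(pairwise: pd.DataFrame,
                           groups: Sequence[str] | None = None,
                           alpha: float = ALPHA_DEFAULT) -> dict[str, str]:
    """Assign letters so two groups share one iff their pair is non-significant.

    Insert-and-absorb: start from one letter covering all groups; for each
    significant pair split every letter set containing both members into two
    sets each dropping one member, then absorb sets contained in others. The
    result is deterministic given input order; minimal letter count is not
    guaranteed.
    """
    need = {"group1", "group2", "p_adj"}
    if not need <= set(pairwise.columns):
        raise SchemaError(f"pairwise table missing columns: {sorted(need - set(pairwise.columns))}")
    if groups is None:
        seen: list[str] = []
        for g in itertools.chain(pairwise["group1"], pairwise["group2"]):
            if g not in seen:
                seen.append(g)
        groups = seen
    groups = list(groups)
    pmap = {frozenset((r.group1, r.group2)): r.p_adj for r in pairwise.itertuples()}
    expected = [frozenset(p) for p in itertools.combinations(groups, 2)]
    missing = [tuple(sorted(p)) for p in expected if p not in pmap]
    if missing:
        raise SchemaError(f"pairwise table incomplete; missing pairs: {missing}")

    sets: list[set[str]] = [set(groups)]
    for ga, gb in itertools.combinations(groups, 2):
        if pmap[frozenset((ga, gb))] >= alpha:
            continue
        nxt: list[set[str]] = []
        for s in sets:
            if ga in s and gb in s:
                nxt.append(s - {ga})
                nxt.append(s - {gb})
            else:
                nxt.append(s)
        # absorb: drop any set contained in another
        sets = [s for i, s in enumerate(nxt)
                if s and not any(i != j and s < t or (s == t and i > j)
                                 for j, t in enumerate(nxt))]

    order = {g: i for i, g in enumerate(groups)}
    sets.sort(key=lambda s: tuple(sorted(order[g] for g in s)))
    letters = {g: "" for g in groups}
    for i, s in enumerate(sets):
        lab = _letter(i)
        for g in groups:
            if g in s:
                letters[g] += lab
    return letters


def _letter(i: int) -> str:
    out = ""
    i += 1
    while i:
        i, r = divmod(i - 1, 26)
        out = chr(ord("a") + r) + out
    return out


@dataclass
class AnovaTukeyResult:
    anova: AnovaResult
    pairwise: pd.DataFrame
    letters: dict[str, str]
    alpha: float


def anova_tukey(groups, alpha: float = ALPHA_DEFAULT) -> AnovaTukeyResult:
    """One-way ANOVA + Tukey MCT + compact letter display, in one call."""
    gs = _as_groups(groups)
    an = one_way_anova(gs)
    pw = tukey_hsd(gs)
    letters = compact_letter_display(pw, groups=[n for n, _ in gs], alpha=alpha)
    return AnovaTukeyResult(anova=an, pairwise=pw, letters=letters, alpha=alpha)


@dataclass
class BatchSummary:
    """Pupariation outcomes: per batch, per group, and the 12 h rate curve."""

    per_batch: pd.DataFrame   # group, batch_id, n_larvae, n_pupariated, percent, oversized
    summary: pd.DataFrame     # group, n_batches, mean_percent, sem_percent
    rate_curve: pd.DataFrame | None  # group, time_h, mean_cumulative_percent


def summarize_batches(records: pd.DataFrame, batch_size: int = 25,
                      horizon_d: float = 10.0, bin_h: float = 12.0) -> BatchSummary:
    """Summarize per-larva pupariation records batch-wise.

    ``records`` holds one row per larva with columns group, batch_id and
    either a boolean ``pupariated`` or a ``pupariation_time_h`` (NaN = never,
    within the horizon of ``horizon_d`` days). With times, a cumulative rate
    curve at ``bin_h``-hour bins is produced; it is non-decreasing by
    construction. Batches exceeding ``batch_size`` are flagged, not dropped.
    """
    horizon_h = horizon_d * 24.0
    df = records.copy()
    has_times = "pupariation_time_h" in df.columns
    if has_times:
        df["pupariated"] = df["pupariation_time_h"].notna() & (
            df["pupariation_time_h"] <= horizon_h)
    elif "pupariated" not in df.columns:
        raise SchemaError("records need a 'pupariated' or 'pupariation_time_h' column")

    per_batch = (df.groupby(["group", "batch_id"], sort=True)["pupariated"]
                 .agg(n_larvae="count", n_pupariated="sum").reset_index())
    per_batch["percent"] = 100.0 * per_batch["n_pupariated"] / per_batch["n_larvae"]
    per_batch["oversized"] = per_batch["n_larvae"] > batch_size

    def _summ(g: pd.Series) -> pd.Series:
        n = len(g)
        sem = float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"n_batches": n, "mean_percent": g.mean(),
                          "sem_percent": sem})

    summary = (per_batch.groupby("group")["percent"].apply(_summ)
               .unstack().reset_index())
    summary["n_batches"] = summary["n_batches"].astype(int)

    rate = None
    if has_times:
        edges = np.arange(bin_h, horizon_h + bin_h / 2, bin_h)
        rows = []
        for (grp, batch), sub in df.groupby(["group", "batch_id"], sort=True):
            t = sub["pupariation_time_h"].to_numpy(dtype=float)
            n = len(sub)
            for edge in edges:
                done = np.sum(~np.isnan(t) & (t <= edge))
                rows.append((grp, batch, edge, 100.0 * done / n))
        per = pd.DataFrame(rows, columns=["group", "batch_id", "time_h",
                                          "cumulative_percent"])
        rate = (per.groupby(["group", "time_h"], sort=True)["cumulative_percent"]
                .mean().reset_index()
                .rename(columns={"cumulative_percent": "mean_cumulative_percent"}))
    return BatchSummary(per_batch=per_batch, summary=summary, rate_curve=rate)


def preference_index(n_test: int, n_control: int) -> float:
    """PI = (n_test - n_control)/(n_test + n_control), in [-1, 1].

    Larvae that left the arena are excluded before counting, so they never
    enter the denominator.
    """
    if n_test < 0 or n_control < 0:
        raise SchemaError("counts must be non-negative")
    total = n_test + n_control
    if total == 0:
        raise SchemaError("preference index undefined: no larvae scored")
    return (n_test - n_control) / total
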