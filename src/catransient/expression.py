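"""Expression-side computations: the consensus differential-expression gate
and 2^-ΔΔCt qPCR fold changes.

The consensus gate does not re-estimate differential expression; it filters
the tabular outputs of three upstream engines (CuffDiff2-, DESeq- and
edgeR-style tables). A gene passes one method when it has nonzero expression
in both conditions, per-method significance below the cutoff, and at least a
25% fold change; the consensus up/down sets are the direction-consistent
triple intersections, and the Venn partition over the three per-method sets
is reported alongside.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import SchemaError

DE_COLUMNS = ("gene", "expr_a", "expr_b", "fold_change", "significance")
MIN_CHANGE_DEFAULT = 0.25
SIG_CUTOFF_DEFAULT = 0.05


@dataclass
class ConsensusResult:
    up: set[str]
    down: set[str]
    per_method: dict[str, dict[str, set[str]]]  # method -> {"up": ..., "down": ...}
    conflicting: set[str]
    venn: dict[tuple[str, ...], int]
    venn_up: dict[tuple[str, ...], int]
    venn_down: dict[tuple[str, ...], int]


def _method_sets(table: pd.DataFrame, min_change: float, sig_cutoff: float,
                 symmetric_down: bool) -> dict[str, set[str]]:
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"DE table missing columns: {missing}")
    up_cut = 1.0 + min_change
    down_cut = (1.0 - min_change) if symmetric_down else 1.0 / (1.0 + min_change)
    ok = ((table["expr_a"] > 0) & (table["expr_b"] > 0)
          & (table["significance"] < sig_cutoff))
    up = set(table.loc[ok & (table["fold_change"] >= up_cut), "gene"])
    down = set(table.loc[ok & (table["fold_change"] <= down_cut), "gene"])
    return {"up": up, "down": down}


def consensus_de(tables: Mapping[str, pd.DataFrame] | Sequence[pd.DataFrame],
                 min_change: float = MIN_CHANGE_DEFAULT,
                 sig_cutoff: float = SIG_CUTOFF_DEFAULT,
                 symmetric_down: bool = True) -> ConsensusResult:
    """Three-method consensus gate over per-method DE tables.

    Per method a gene must have nonzero expression in both conditions,
    significance < ``sig_cutoff`` and a fold change of at least ``min_change``
    (up: FC >= 1.25; down: FC <= 0.75 on the symmetric linear reading, or
    FC <= 1/1.25 with ``symmetric_down=False``). Consensus sets are the
    direction-consistent intersections across all three methods; genes
    significant in all three but with conflicting directions are excluded
    and listed. The result is invariant to the order of the input tables.
    """
    if isinstance(tables, Mapping):
        items = list(tables.items())
    else:
        items = [(str(t["method"].iloc[0]) if "method" in t.columns else f"method{i+1}", t)
                 for i, t in enumerate(tables)]
    if len(items) != 3:
        raise SchemaError(f"consensus gate needs exactly three DE tables, got {len(items)}")
    per_method = {name: _method_sets(t, min_change, sig_cutoff, symmetric_down)
                  for name, t in items}

    ups = [s["up"] for s in per_method.values()]
    downs = [s["down"] for s in per_method.values()]
    up = set.intersection(*ups)
    down = set.intersection(*downs)
    any_sig = [s["up"] | s["down"] for s in per_method.values()]
    conflicting = set.intersection(*any_sig) - up - down

    names = [n for n, _ in items]
    venn = venn_counts(dict(zip(names, any_sig)))
    venn_up = venn_counts(dict(zip(names, ups)))
    venn_down = venn_counts(dict(zip(names, downs)))
    return ConsensusResult(up=up, down=down, per_method=per_method,
                           conflicting=conflicting, venn=venn,
                           venn_up=venn_up, venn_down=venn_down)


def venn_counts(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts of a three-set Venn partition.

    Keys are tuples of the set names (input order) a region belongs to; the
    seven non-empty regions of three sets are always present. The counts of
    all regions containing a given set sum to that set's size.
    """
    names = list(sets)
    if len(names) != 3:
        raise SchemaError(f"venn_counts expects three sets, got {len(names)}")
    universe = set().union(*sets.values())
    out: dict[tuple[str, ...], int] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set().union(*(sets[n] for n in names if n not in combo)) \
                if len(combo) < 3 else set()
            out[combo] = len(inside - outside)
    assert sum(out.values()) == len(universe)
    return out


def ddct_fold_change(ct: pd.DataFrame, target: str | Sequence[str],
                     housekeeping: str, expt: str | Sequence[str],
                     control: str | Sequence[str]) -> pd.DataFrame:
    """Relative expression by 2^-ΔΔCt with housekeeping normalization.

    ΔΔCt = (Ct_target - Ct_housekeeping)_expt - (Ct_target - Ct_housekeeping)_control,
    with technical duplicates averaged first. ``expt``/``control`` may be
    single sample labels or equal-length lists of biological replicates
    (paired by position); one row per (gene, replicate pair) is returned.
    """
    need = {"sample", "gene", "replicate", "Ct"}
    if not need <= set(ct.columns):
        raise SchemaError(f"Ct table missing columns: {sorted(need - set(ct.columns))}")
    targets = [target] if isinstance(target, str) else list(target)
    expts = [expt] if isinstance(expt, str) else list(expt)
    controls = [control] if isinstance(control, str) else list(control)
    if len(controls) == 1 and len(expts) > 1:
        controls = controls * len(expts)
    if len(expts) != len(controls):
        raise SchemaError("expt and control replicate lists must pair up")

    means = ct.groupby(["sample", "gene"])["Ct"].mean()

    def _ct(sample: str, gene: str) -> float:
        try:
            return float(means.loc[(sample, gene)])
        except KeyError:
            raise SchemaError(f"no Ct values for gene {gene!r} in sample {sample!r}")

    rows = []
    for gene in targets:
        for i, (e, c) in enumerate(zip(expts, controls), start=1):
            ddct = ((_ct(e, gene) - _ct(e, housekeeping))
                    - (_ct(c, gene) - _ct(c, housekeeping)))
            rows.append((gene, housekeeping, i, ddct, 2.0 ** (-ddct)))
    return pd.DataFrame(rows, columns=["gene", "housekeeping", "replicate",
                                       "ddct", "fold_change"])


def ddct_summary(folds: pd.DataFrame) -> pd.DataFrame:
    """Mean and SEM of per-replicate fold changes, per gene x housekeeping."""
    def _summ(g: pd.Series) -> pd.Series:
        n = len(g)
        sem = float(g.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        return pd.Series({"n": n, "mean_fold": g.mean(), "sem_fold": sem})
    out = (folds.groupby(["gene", "housekeeping"])["fold_change"]
           .apply(_summ).unstack().reset_index())
    out["n"] = out["n"].astype(int)
    return out
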