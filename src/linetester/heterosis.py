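"""Mid-parent and better-parent heterosis with significance tests.

MPH% = 100*(F1 - MP)/MP with MP = (P1 + P2)/2; BPH% = 100*(F1 - BP)/BP
where BP is the parent mean further in the breeder's desirable direction
for the trait (lower for earliness traits, higher for yield traits). The
sign of the percentages is never flipped by the direction: direction only
selects BP and drives ranking.

Significance uses the balanced-trial t statistics
(F1 - MP)/sqrt(3 MSe/(2r)) and (F1 - BP)/sqrt(2 MSe/r) referred to the
error df, starred at 5/1/0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .anova import star_code
from .study_io import EntryMeans, TrialDesign

__all__ = ["heterosis", "heterosis_significance", "rank_heterotic", "HET_SIG_LEVELS"]

# three-level star codes used for heterosis tests
HET_SIG_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def _better_parent(p1: float, p2: float, direction: str) -> float:
    if direction == "+":
        return max(p1, p2)
    if direction == "-":
        return min(p1, p2)
    raise ValueError(f"desirable direction must be '+' or '-', got {direction!r}")


def heterosis(
    cross_means: EntryMeans,
    parent_means: EntryMeans,
    design: TrialDesign,
    direction: str = "+",
) -> pd.DataFrame:
    """Per-cross heterosis table for one trait.

    Returns a DataFrame indexed by cross label with columns line, tester,
    F1, MP, BP, MPH_pct, BPH_pct. Crosses with a zero mid- or
    better-parent mean are flagged (NaN percentages) rather than divided.
    """
    rows = []
    for li, tj in design.cross_ids():
        label = design.cross_label(li, tj)
        f1 = cross_means.values[label]
        p1 = parent_means.values[li]
        p2 = parent_means.values[tj]
        mp = (p1 + p2) / 2
        bp = _better_parent(p1, p2, direction)
        mph = 100 * (f1 - mp) / mp if mp != 0 else math.nan
        bph = 100 * (f1 - bp) / bp if bp != 0 else math.nan
        rows.append((label, li, tj, f1, mp, bp, mph, bph))
    return pd.DataFrame(
        rows, columns=["cross", "line", "tester", "F1", "MP", "BP", "MPH_pct", "BPH_pct"]
    ).set_index("cross")


def heterosis_significance(
    table: pd.DataFrame, mse: float, r: int, df_error: int
) -> pd.DataFrame:
    """Attach t statistics, p values and star codes for MPH and BPH."""
    if mse <= 0:
        raise ValueError("mean squared error must be positive")
    if r < 2:
        raise ValueError("need at least 2 replicates")
    out = table.copy()
    se_mp = math.sqrt(3 * mse / (2 * r))
    se_bp = math.sqrt(2 * mse / r)
    t_mp = (out["F1"] - out["MP"]) / se_mp
    t_bp = (out["F1"] - out["BP"]) / se_bp
    p_mp = 2 * stats.t.sf(np.abs(t_mp), df_error)
    p_bp = 2 * stats.t.sf(np.abs(t_bp), df_error)
    out["t_MPH"] = t_mp
    out["p_MPH"] = p_mp
    out["sig_MPH"] = [star_code(p, HET_SIG_LEVELS) for p in p_mp]
    out["t_BPH"] = t_bp
    out["p_BPH"] = p_bp
    out["sig_BPH"] = [star_code(p, HET_SIG_LEVELS) for p in p_bp]
    return out


def rank_heterotic(table: pd.DataFrame, k: int, direction: str = "+") -> pd.DataFrame:
    """Top-k crosses by significant mid-parent heterosis in the desirable
    direction; ties broken by BPH then by cross label (deterministic)."""
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available crosses")
    if "sig_MPH" not in table.columns:
        raise ValueError("run heterosis_significance first")
    sig = table[table["sig_MPH"] != ""].copy()
    if direction == "+":
        sig = sig[sig["MPH_pct"] > 0]
        ascending = [False, False, True]
    elif direction == "-":
        sig = sig[sig["MPH_pct"] < 0]
        ascending = [True, True, True]
    else:
        raise ValueError(f"desirable direction must be '+' or '-', got {direction!r}")
    sig = sig.reset_index().sort_values(
        ["MPH_pct", "BPH_pct", "cross"], ascending=ascending, kind="mergesort"
    ).set_index("cross")
    return sig.head(k)
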