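"""Balanced line x tester analysis of variance.

The trial is analysed as a randomized complete block design (RCBD) on the
l + t parents and l*t crosses (checks excluded), with the treatment sum of
squares partitioned hierarchically:

    treatments = parents + (parents vs crosses) + crosses
    parents    = lines + testers + (lines vs testers)
    crosses    = line effect + tester effect + line x tester

Error SS is obtained by subtraction from the total, with df
(l + t + lt - 1)(r - 1); every mean square is tested against it with an
upper-tail F test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .study_io import PlotRecord, TrialDesign, check_balance

__all__ = ["AnovaRow", "AnovaTable", "lt_anova", "f_significance", "star_code"]

# Upper-tail significance thresholds and their star codes (5/1/0.1/0.01%).
SIG_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def star_code(p: float, levels=SIG_LEVELS) -> str:
    for thr, code in levels:
        if p < thr:
            return code
    return ""


def f_significance(F: float, df1: int, df2: int) -> tuple[float, str]:
    """Upper-tail p of the F(df1, df2) distribution with its star code."""
    if not np.isfinite(F):
        raise ValueError("non-finite F statistic")
    if F < 0:
        raise ValueError("F statistic must be nonnegative")
    if df1 < 1 or df2 < 1:
        raise ValueError("F test needs df1, df2 >= 1")
    p = float(stats.f.sf(F, df1, df2))
    return p, star_code(p)


@dataclass
class AnovaRow:
    source: str
    df: int
    ss: float
    ms: float | None
    F: float | None = None
    p: float | None = None
    sig: str = ""


@dataclass
class AnovaTable:
    """Ordered source decomposition with F tests against the pooled error."""

    trait: str
    rows: list[AnovaRow]

    def __getitem__(self, source: str) -> AnovaRow:
        for row in self.rows:
            if row.source == source:
                return row
        raise KeyError(source)

    @property
    def error_ms(self) -> float:
        return self["Error"].ms

    @property
    def error_df(self) -> int:
        return self["Error"].df

    def mean_squares(self) -> dict[str, float]:
        return {r.source: r.ms for r in self.rows if r.ms is not None}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(r.source, r.df, r.ss, r.ms, r.F, r.p, r.sig) for r in self.rows],
            columns=["source", "df", "SS", "MS", "F", "p", "sig"],
        ).set_index("source")


# Row order of the published decomposition.
ROW_ORDER = [
    "Replicates", "Treatments", "Parents", "Parents (Line)", "Parents (Testers)",
    "Parents (L vs T)", "Parents vs Crosses", "Crosses", "Line Effect",
    "Tester Effect", "Line x Tester Eff.", "Error", "Total",
]


def _totals_table(records: Sequence[PlotRecord], design: TrialDesign, trait: str) -> np.ndarray:
    """(entries x reps) value matrix over parents + crosses, design order."""
    entries = (
        list(design.line_ids)
        + list(design.tester_ids)
        + [design.cross_label(li, tj) for li, tj in design.cross_ids()]
    )
    idx = {e: i for i, e in enumerate(entries)}
    y = np.full((len(entries), design.r), np.nan)
    for rec in records:
        if rec.role == "check":
            continue
        if rec.entry not in idx:
            raise ValueError(f"entry {rec.entry!r} not in design")
        if trait in rec.traits:
            y[idx[rec.entry], rec.rep - 1] = rec.traits[trait]
    if np.isnan(y).any():
        n_missing = int(np.isnan(y).sum())
        raise ValueError(
            f"unbalanced data for trait {trait!r}: {n_missing} missing plot values; "
            "the balanced-data decomposition requires a complete table"
        )
    return y


def lt_anova(records: Sequence[PlotRecord], design: TrialDesign, trait: str) -> AnovaTable:
    """RCBD line x tester decomposition of one trait.

    Requires the complete balanced table (all parents and crosses in every
    replicate); checks present in the records are ignored.
    """
    l, t, r = design.l, design.t, design.r
    y = _totals_table(records, design, trait)
    n_entries = l + t + l * t
    N = n_entries * r
    grand = y.sum()
    cf = grand**2 / N

    ss_total = float((y**2).sum() - cf)
    rep_totals = y.sum(axis=0)
    ss_rep = float((rep_totals**2).sum() / n_entries - cf)
    entry_totals = y.sum(axis=1)
    ss_treat = float((entry_totals**2).sum() / r - cf)
    ss_error = ss_total - ss_rep - ss_treat

    # parents vs crosses partition of the treatment SS
    lt_tot = entry_totals[:l]          # line parents
    tt_tot = entry_totals[l:l + t]     # tester parents
    ct_tot = entry_totals[l + t:]      # crosses, line-major order
    p_tot = lt_tot.sum() + tt_tot.sum()
    c_tot = ct_tot.sum()
    n_par = l + t

    ss_parents = float((lt_tot**2).sum() / r + (tt_tot**2).sum() / r - p_tot**2 / (n_par * r))
    ss_pvc = float(p_tot**2 / (n_par * r) + c_tot**2 / (l * t * r) - cf)
    ss_crosses = ss_treat - ss_parents - ss_pvc

    # within parents: lines, testers, 1-df lines-vs-testers contrast
    ss_par_lines = float((lt_tot**2).sum() / r - lt_tot.sum() ** 2 / (l * r))
    ss_par_testers = float((tt_tot**2).sum() / r - tt_tot.sum() ** 2 / (t * r))
    ss_lvt = ss_parents - ss_par_lines - ss_par_testers

    # within crosses: line effect, tester effect, interaction
    cmat = ct_tot.reshape(l, t)
    ss_line = float((cmat.sum(axis=1) ** 2).sum() / (t * r) - c_tot**2 / (l * t * r))
    ss_tester = float((cmat.sum(axis=0) ** 2).sum() / (l * r) - c_tot**2 / (l * t * r))
    ss_lxt = ss_crosses - ss_line - ss_tester

    dfs = {
        "Replicates": r - 1,
        "Treatments": n_entries - 1,
        "Parents": n_par - 1,
        "Parents (Line)": l - 1,
        "Parents (Testers)": t - 1,
        "Parents (L vs T)": 1,
        "Parents vs Crosses": 1,
        "Crosses": l * t - 1,
        "Line Effect": l - 1,
        "Tester Effect": t - 1,
        "Line x Tester Eff.": (l - 1) * (t - 1),
        "Error": (n_entries - 1) * (r - 1),
        "Total": N - 1,
    }
    sss = {
        "Replicates": ss_rep,
        "Treatments": ss_treat,
        "Parents": ss_parents,
        "Parents (Line)": ss_par_lines,
        "Parents (Testers)": ss_par_testers,
        "Parents (L vs T)": ss_lvt,
        "Parents vs Crosses": ss_pvc,
        "Crosses": ss_crosses,
        "Line Effect": ss_line,
        "Tester Effect": ss_tester,
        "Line x Tester Eff.": ss_lxt,
        "Error": ss_error,
        "Total": ss_total,
    }

    ms_error = ss_error / dfs["Error"]
    rows = []
    for source in ROW_ORDER:
        df = dfs[source]
        ss = sss[source]
        ms = ss / df if df > 0 else None
        F = p = None
        sig = ""
        if source not in ("Error", "Total") and ms is not None and ms_error > 0:
            F = ms / ms_error
            p, sig = f_significance(F, df, dfs["Error"])
        rows.append(AnovaRow(source, df, ss, ms, F, p, sig))
    return AnovaTable(trait=trait, rows=rows)
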