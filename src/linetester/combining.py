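"""General and specific combining ability from cross means.

With mu the grand mean of the l x t cross means, the GCA of line i is the
deviation of its row mean, g_i = x_i. - mu; the GCA of tester j is
g_j = x_.j - mu; and the SCA of cross (i, j) is the interaction residual
s_ij = x_ij - x_i. - x_.j + mu. Standard errors follow the balanced
line x tester forms SE(g_line) = sqrt(MSe/(r t)), SE(g_tester) =
sqrt(MSe/(r l)), SE(s) = sqrt(MSe/r), and the 95% critical difference is
the two-sided Student t quantile times the SE of a single effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats

from .anova import star_code
from .study_io import EntryMeans, TrialDesign

__all__ = [
    "CombiningAbility",
    "estimate_gca_sca",
    "critical_differences",
    "gca_sca_significance",
    "cross_means_matrix",
]


@dataclass
class CombiningAbility:
    trait: str
    line_ids: list[str]
    tester_ids: list[str]
    grand_mean: float
    gca_lines: np.ndarray          # (l,)
    gca_testers: np.ndarray        # (t,)
    sca: np.ndarray                # (l, t)
    se_gca_line: float | None = None
    se_gca_tester: float | None = None
    se_sca: float | None = None
    cd95_gca_line: float | None = None
    cd95_gca_tester: float | None = None
    cd95_sca: float | None = None
    sig_gca_lines: list[str] = field(default_factory=list)
    sig_gca_testers: list[str] = field(default_factory=list)
    sig_sca: np.ndarray | None = None

    def sca_value(self, line_id: str, tester_id: str) -> float:
        return float(self.sca[self.line_ids.index(line_id), self.tester_ids.index(tester_id)])


def cross_means_matrix(means: EntryMeans, design: TrialDesign) -> np.ndarray:
    """Assemble the complete l x t grid of cross means in design order."""
    grid = np.full((design.l, design.t), np.nan)
    for i, li in enumerate(design.line_ids):
        for j, tj in enumerate(design.tester_ids):
            label = design.cross_label(li, tj)
            if label not in means.values:
                raise ValueError(f"missing cross mean for {label!r}")
            grid[i, j] = means.values[label]
    return grid


def estimate_gca_sca(means: EntryMeans, design: TrialDesign) -> CombiningAbility:
    """GCA and SCA effects from the complete grid of cross means.

    The effects satisfy exact zero-sum constraints and reconstruct every
    cell as mu + g_i + g_j + s_ij.
    """
    grid = cross_means_matrix(means, design)
    mu = float(grid.mean())
    g_lines = grid.mean(axis=1) - mu
    g_testers = grid.mean(axis=0) - mu
    sca = grid - grid.mean(axis=1, keepdims=True) - grid.mean(axis=0, keepdims=True) + mu
    return CombiningAbility(
        trait=means.trait,
        line_ids=list(design.line_ids),
        tester_ids=list(design.tester_ids),
        grand_mean=mu,
        gca_lines=g_lines,
        gca_testers=g_testers,
        sca=sca,
    )


def critical_differences(
    mse: float,
    design: TrialDesign,
    alpha: float = 0.05,
    df_error: int | None = None,
    difference_based: bool = False,
) -> dict[str, float]:
    """Standard errors and critical differences for GCA/SCA estimates.

    ``difference_based=True`` multiplies the SE by sqrt(2), giving the CD
    for comparing two effects rather than testing one against zero.
    """
    if mse <= 0:
        raise ValueError("mean squared error must be positive")
    l, t, r = design.l, design.t, design.r
    if df_error is None:
        df_error = (l + t + l * t - 1) * (r - 1)
    se_line = math.sqrt(mse / (r * t))
    se_tester = math.sqrt(mse / (r * l))
    se_sca = math.sqrt(mse / r)
    tcrit = float(stats.t.ppf(1 - alpha / 2, df_error))
    k = math.sqrt(2) if difference_based else 1.0
    return {
        "se_gca_line": se_line,
        "se_gca_tester": se_tester,
        "se_sca": se_sca,
        "cd_gca_line": k * tcrit * se_line,
        "cd_gca_tester": k * tcrit * se_tester,
        "cd_sca": k * tcrit * se_sca,
        "df_error": df_error,
    }


def _codes(effects: np.ndarray, se: float, df_error: int):
    if se <= 0:
        raise ValueError("zero standard error")
    tstat = np.abs(np.asarray(effects, dtype=float)) / se
    p = 2 * stats.t.sf(tstat, df_error)
    return np.vectorize(star_code, otypes=[object])(p)


def gca_sca_significance(
    ca: CombiningAbility, mse: float, design: TrialDesign, df_error: int | None = None
) -> CombiningAbility:
    """Attach SEs, 95% CDs and two-sided t star codes to the effects."""
    cds = critical_differences(mse, design, df_error=df_error)
    ca.se_gca_line = cds["se_gca_line"]
    ca.se_gca_tester = cds["se_gca_tester"]
    ca.se_sca = cds["se_sca"]
    ca.cd95_gca_line = cds["cd_gca_line"]
    ca.cd95_gca_tester = cds["cd_gca_tester"]
    ca.cd95_sca = cds["cd_sca"]
    dfe = cds["df_error"]
    ca.sig_gca_lines = list(_codes(ca.gca_lines, ca.se_gca_line, dfe))
    ca.sig_gca_testers = list(_codes(ca.gca_testers, ca.se_gca_tester, dfe))
    ca.sig_sca = _codes(ca.sca, ca.se_sca, dfe)
    return ca
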