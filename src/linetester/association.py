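"""Phenotypic distance, trait PCA variance shares, and the correlation
analysis linking parental distances and combining ability with heterosis.

Phenotypic distance (PD) is the Euclidean distance between parents over
z-score standardized trait means (standardization is the default: it
makes the distance invariant to trait units and is what produces
magnitudes comparable across trait sets). Genetic distance (GD) comes
from the marker module. The association analysis correlates, over the
l*t crosses of a trial, the per-cross parental distances (GD, PD) and the
cross's SCA effect with its mid- and better-parent heterosis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .anova import star_code
from .combining import CombiningAbility
from .markers import DistanceMatrix
from .study_io import EntryMeans, TrialDesign

__all__ = [
    "CorrelationResult",
    "phenotypic_distance",
    "cross_distance_lookup",
    "pearson_correlation",
    "association_matrix",
    "pca_variance_shares",
]

# star codes used in the correlation grid (5% and 1% only)
CORR_SIG_LEVELS = ((0.01, "**"), (0.05, "*"))


@dataclass
class CorrelationResult:
    label: str
    n: int
    r: float
    t: float
    p: float
    sig: str


def phenotypic_distance(
    means_by_trait: dict[str, EntryMeans],
    entries: list[str],
    traits: list[str] | None = None,
    standardize: bool = True,
) -> DistanceMatrix:
    """Euclidean distance between entries over (standardized) trait means.

    Zero-variance traits cannot be standardized and are dropped with a
    warning.
    """
    traits = list(traits) if traits is not None else list(means_by_trait)
    cols = []
    kept = []
    for trait in traits:
        em = means_by_trait[trait]
        v = np.array([em.values[e] for e in entries], dtype=float)
        if standardize:
            sd = v.std(ddof=0)
            if sd == 0:
                warnings.warn(f"trait {trait!r} has zero variance across entries; dropped")
                continue
            v = (v - v.mean()) / sd
        cols.append(v)
        kept.append(trait)
    if not cols:
        raise ValueError("no usable traits for phenotypic distance")
    X = np.column_stack(cols)
    d = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(list(entries), d, kind="euclidean")


def cross_distance_lookup(d: DistanceMatrix, crosses: list[tuple[str, str]]) -> pd.Series:
    """Parental distance per cross, ordered and labelled as the cross list."""
    vals, labels = [], []
    for li, tj in crosses:
        if li not in d.ids:
            raise KeyError(f"parent {li!r} absent from distance matrix")
        if tj not in d.ids:
            raise KeyError(f"parent {tj!r} absent from distance matrix")
        vals.append(d.between(li, tj))
        labels.append(TrialDesign.cross_label(li, tj))
    return pd.Series(vals, index=labels, name=d.kind)


def pearson_correlation(x, y, label: str = "") -> CorrelationResult:
    """Product-moment correlation with the exact t test (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if x.max() == x.min() or y.max() == y.min():
        raise ValueError("zero variance in x or y")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc**2).sum() * (yc**2).sum())
    r = float((xc * yc).sum() / denom)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = math.inf if r > 0 else -math.inf
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r**2))
        p = 2 * float(stats.t.sf(abs(t), n - 2))
    return CorrelationResult(label=label, n=n, r=r, t=t, p=p,
                             sig=star_code(p, CORR_SIG_LEVELS))


def association_matrix(
    heterosis_table: pd.DataFrame,
    sca: CombiningAbility,
    design: TrialDesign,
    gd_per_cross: pd.Series | None = None,
    pd_per_cross: pd.Series | None = None,
) -> pd.DataFrame:
    """Correlations of GD, PD and SCA with MPH and BPH over the l*t crosses.

    All inputs are aligned by cross label (not position); crosses lacking a
    heterosis value are dropped pairwise. Returns one row per available
    pair (GD-MPH, GD-BPH, GD-SCA, PD-MPH, PD-BPH, PD-SCA, SCA-MPH,
    SCA-BPH) with r, t, p, n and the star code.
    """
    labels = [design.cross_label(li, tj) for li, tj in design.cross_ids()]
    sca_vec = pd.Series(
        [sca.sca_value(li, tj) for li, tj in design.cross_ids()], index=labels
    )
    vectors = {"SCA": sca_vec}
    if gd_per_cross is not None:
        vectors["GD"] = gd_per_cross.reindex(labels)
    if pd_per_cross is not None:
        vectors["PD"] = pd_per_cross.reindex(labels)
    het = heterosis_table.reindex(labels)
    targets = {"MPH": het["MPH_pct"], "BPH": het["BPH_pct"]}

    pairs = []
    for dist_name in ("GD", "PD"):
        if dist_name in vectors:
            pairs += [(dist_name, "MPH"), (dist_name, "BPH"), (dist_name, "SCA")]
    pairs += [("SCA", "MPH"), ("SCA", "BPH")]

    rows = []
    for a, b in pairs:
        xa = vectors[a]
        xb = targets[b] if b in targets else vectors[b]
        keep = xa.notna() & xb.notna()
        res = pearson_correlation(xa[keep], xb[keep], label=f"{a} vs {b}")
        rows.append((a, b, res.n, res.r, res.t, res.p, res.sig))
    return pd.DataFrame(rows, columns=["x", "y", "n", "r", "t", "p", "sig"])


def pca_variance_shares(
    means_by_trait: dict[str, EntryMeans],
    entries: list[str],
    traits: list[str] | None = None,
    n_components: int | None = None,
) -> np.ndarray:
    """Eigenvalue shares of the trait correlation matrix, descending.

    With standardized traits these are the fractions of total variation
    captured by each principal component; they sum to 1 over all
    components.
    """
    if len(entries) < 2:
        raise ValueError("need at least 2 entries")
    traits = list(traits) if traits is not None else list(means_by_trait)
    X = np.column_stack(
        [[means_by_trait[t].values[e] for e in entries] for t in traits]
    ).astype(float)
    corr = np.corrcoef(X, rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)[::-1]
    eigvals = np.clip(eigvals, 0, None)
    shares = eigvals / eigvals.sum()
    if n_components is not None:
        shares = shares[:n_components]
    return shares
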