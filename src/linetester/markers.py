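"""SSR allelic diversity, marker-based genetic distance, cluster trees,
and the Evanno delta-K summary.

Per-locus statistics follow the microsatellite conventions: observed
heterozygosity Ho is the heterozygote fraction among typed individuals;
expected heterozygosity He = 1 - sum(p_i^2) (gene diversity, with an
optional 2n/(2n-1) small-sample correction); and PIC defaults to
Botstein's form 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2, with the simpler
1 - sum(p_i^2) selectable.

Genetic distance between two individuals is the simple matching
dissimilarity: one minus the mean per-locus fraction of shared alleles
(counting multiplicity) over co-typed loci. Trees are UPGMA (rooted,
ultrametric; merge order delegated to scipy's average linkage) or
neighbour-joining (scikit-bio), with optional locus-bootstrap support.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
import skbio
from skbio.tree import TreeNode

from .study_io import GenotypeMatrix

__all__ = [
    "LocusStats",
    "DistanceMatrix",
    "DeltaKResult",
    "allele_frequencies",
    "locus_stats",
    "summarize_panel",
    "pic_class",
    "simple_matching_distance",
    "upgma_tree",
    "nj_tree",
    "bootstrap_support",
    "to_newick",
    "evanno_delta_k",
]


def to_newick(tree: "TreeNode") -> str:
    """Serialize a tree to a newick string (internal names carry support)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


@dataclass
class LocusStats:
    locus: str
    n_typed: int
    N: int        # distinct allele count
    Ho: float
    He: float
    PIC: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with labelled ids."""

    ids: list[str]
    data: np.ndarray
    kind: str  # {"simple_matching", "euclidean"}

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be nonnegative")

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])

    def to_skbio(self) -> skbio.DistanceMatrix:
        return skbio.DistanceMatrix(self.data, ids=self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


# ---------------------------------------------------------------------------
# Allelic diversity
# ---------------------------------------------------------------------------

def allele_frequencies(gm: GenotypeMatrix, locus: str) -> dict[str, float]:
    """Allele frequencies over the 2*n_typed allele copies at one locus."""
    counts: Counter[str] = Counter()
    for call in gm.locus_calls(locus):
        if call is not None:
            counts[call[0]] += 1
            counts[call[1]] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"locus {locus!r} has no typed calls")
    return {a: c / total for a, c in sorted(counts.items())}


def _pic_botstein(freqs) -> float:
    p = list(freqs)
    s2 = sum(x * x for x in p)
    cross = sum(2 * p[i] ** 2 * p[j] ** 2
                for i in range(len(p)) for j in range(i + 1, len(p)))
    return 1 - s2 - cross


def locus_stats(
    gm: GenotypeMatrix,
    locus: str,
    pic_form: str = "botstein",
    he_form: str = "plain",
) -> LocusStats:
    """Diversity statistics for one locus."""
    calls = [c for c in gm.locus_calls(locus) if c is not None]
    if not calls:
        raise ValueError(f"locus {locus!r} has no typed calls")
    freqs = allele_frequencies(gm, locus)
    n_typed = len(calls)
    ho = sum(1 for a, b in calls if a != b) / n_typed
    s2 = sum(p * p for p in freqs.values())
    he = 1 - s2
    if he_form == "unbiased":
        he *= 2 * n_typed / (2 * n_typed - 1)
    elif he_form != "plain":
        raise ValueError(f"unknown he_form {he_form!r}")
    if pic_form == "botstein":
        pic = _pic_botstein(freqs.values())
    elif pic_form == "simple":
        pic = 1 - s2
    else:
        raise ValueError(f"unknown pic_form {pic_form!r}")
    return LocusStats(locus=locus, n_typed=n_typed, N=len(freqs), Ho=ho, He=he, PIC=pic)


def pic_class(pic: float) -> str:
    """Marker informativeness: highly (>=0.5), reasonably (0.25-0.5),
    slightly (<0.25) informative."""
    if pic >= 0.5:
        return "highly informative"
    if pic > 0.25:
        return "reasonably informative"
    return "slightly informative"


def summarize_panel(stats) -> dict:
    """Panel-level summary of per-locus diversity.

    Accepts a list of :class:`LocusStats` or a DataFrame with columns
    locus, N, Ho, He, PIC. Reports allele totals, means, extremes with
    their locus ids, and informativeness class counts.
    """
    if isinstance(stats, pd.DataFrame):
        df = stats
    else:
        if not stats:
            raise ValueError("empty locus list")
        df = pd.DataFrame(
            [(s.locus, s.N, s.Ho, s.He, s.PIC) for s in stats],
            columns=["locus", "N", "Ho", "He", "PIC"],
        )
    if df.empty:
        raise ValueError("empty locus list")
    # sort by locus id so summaries (incl. tie-broken argmins) are
    # invariant to input order
    df = df.sort_values("locus", kind="mergesort").reset_index(drop=True)
    out = {
        "n_loci": len(df),
        "total_alleles": int(df["N"].sum()),
        "mean_N": float(df["N"].mean()),
        "min_N": int(df["N"].min()),
        "max_N": int(df["N"].max()),
    }
    for col in ("Ho", "He", "PIC"):
        out[f"mean_{col}"] = float(df[col].mean())
        out[f"min_{col}"] = float(df[col].min())
        out[f"max_{col}"] = float(df[col].max())
        out[f"argmin_{col}"] = str(df.loc[df[col].idxmin(), "locus"])
        out[f"argmax_{col}"] = str(df.loc[df[col].idxmax(), "locus"])
    classes = df["PIC"].map(pic_class).value_counts().to_dict()
    out["pic_classes"] = classes
    return out


# ---------------------------------------------------------------------------
# Simple matching distance
# ---------------------------------------------------------------------------

def _pair_similarity(a: tuple[str, str], b: tuple[str, str]) -> float:
    """Shared alleles counting multiplicity, halved: in {0, 0.5, 1}."""
    shared = sum((Counter(a) & Counter(b)).values())
    return shared / 2


def simple_matching_distance(gm: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise simple matching dissimilarity over co-typed loci
    (pairwise deletion of missing calls)."""
    n = len(gm.individual_ids)
    calls = [gm.individual_calls(ind) for ind in gm.individual_ids]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            sims = [
                _pair_similarity(a, b)
                for a, b in zip(calls[i], calls[j])
                if a is not None and b is not None
            ]
            if not sims:
                raise ValueError(
                    f"no co-typed loci between {gm.individual_ids[i]!r} "
                    f"and {gm.individual_ids[j]!r}"
                )
            d[i, j] = d[j, i] = 1 - sum(sims) / len(sims)
    return DistanceMatrix(list(gm.individual_ids), d, kind="simple_matching")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def upgma_tree(d: DistanceMatrix) -> TreeNode:
    """Rooted ultrametric UPGMA tree; node height is half the average
    linkage merge distance, so cophenetic distances reproduce an
    ultrametric input exactly."""
    n = len(d.ids)
    if n < 2:
        raise ValueError("need at least 2 leaves")
    Z = linkage(squareform(d.data, checks=False), method="average")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in d.ids]
    heights = [0.0] * n
    for i, j, dist, _count in Z:
        a, b = nodes[int(i)], nodes[int(j)]
        h = dist / 2
        a.length = h - heights[int(i)]
        b.length = h - heights[int(j)]
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
        heights.append(h)
    root = nodes[-1]
    root.length = None
    return root


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Unrooted neighbour-joining tree (scikit-bio)."""
    return skbio.tree.nj(d.to_skbio())


def _clades(tree: TreeNode) -> set[frozenset]:
    """Leaf-name sets of internal, non-root nodes of a rooted tree."""
    out = set()
    for node in tree.non_tips():
        if node.parent is None:
            continue
        out.add(frozenset(t.name for t in node.tips()))
    return out


def bootstrap_support(
    gm: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    tree_builder=upgma_tree,
) -> TreeNode:
    """Tree with locus-bootstrap support on internal nodes.

    Loci (columns) are resampled with replacement ``n_reps`` times; the
    support of an internal node is the fraction of replicate trees that
    contain the same leaf set as a clade. Deterministic given the seed.
    """
    if seed is None:
        raise ValueError("bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    base = tree_builder(simple_matching_distance(gm))
    counts: Counter[frozenset] = Counter()
    loci = gm.locus_ids
    for _ in range(n_reps):
        resampled = [loci[k] for k in rng.integers(0, len(loci), size=len(loci))]
        rep_tree = tree_builder(simple_matching_distance(gm.subset_loci(resampled)))
        counts.update(_clades(rep_tree))
    for node in base.non_tips():
        if node.parent is None:
            continue
        clade = frozenset(t.name for t in node.tips())
        node.support = counts[clade] / n_reps
        node.name = f"{node.support:.2f}"
    return base


# ---------------------------------------------------------------------------
# Evanno delta-K
# ---------------------------------------------------------------------------

@dataclass
class DeltaKResult:
    table: pd.DataFrame  # per K: mean_L, sd_L, Lp, Lpp_abs, delta_k
    best_k: int


def evanno_delta_k(loglik: dict[int, list[float]]) -> DeltaKResult:
    """Second-order rate of change of the model log-likelihood over K.

    delta_K = |L''(K)| / sd(L(K)) with L'(K) = mean L(K) - mean L(K-1) and
    L''(K) = L'(K+1) - L'(K); defined for interior K only.
    """
    ks = sorted(loglik)
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("K values must be consecutive")
    means, sds = {}, {}
    for k in ks:
        runs = np.asarray(loglik[k], dtype=float)
        if len(runs) < 2:
            raise ValueError(f"K={k}: need at least 2 runs for an sd")
        means[k] = runs.mean()
        sds[k] = runs.std(ddof=1)
    rows = []
    for k in ks:
        lp = means[k] - means[k - 1] if k - 1 in means else np.nan
        if k - 1 in means and k + 1 in means:
            lpp = abs((means[k + 1] - means[k]) - lp)
            if sds[k] == 0:
                raise ValueError(f"K={k}: zero standard deviation, delta-K undefined")
            dk = lpp / sds[k]
        else:
            lpp = dk = np.nan
        rows.append((k, means[k], sds[k], lp, lpp, dk))
    table = pd.DataFrame(
        rows, columns=["K", "mean_L", "sd_L", "Lp", "Lpp_abs", "delta_k"]
    ).set_index("K")
    best_k = int(table["delta_k"].idxmax())
    return DeltaKResult(table=table, best_k=best_k)
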