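"""Synthetic data generators emulating the study's statistical structure.

Two generators provide ground-truthed inputs for every analysis stage:

* :func:`simulate_trial` draws a balanced line x tester field trial. Cross
  plots follow y = mu + g_i + g_j + s_ij + rep_k + e with zero-centred GCA
  and double-centred SCA effects at the configured variances; parent plots
  carry the homozygous-parent additive value 2g minus a uniform
  inbreeding-depression offset, which induces positive mid-parent
  heterosis without modelling loci explicitly.
* :func:`simulate_markers` draws a multi-subpopulation codominant SSR
  panel: per-locus base allele frequencies, subpopulation frequencies
  diverged around them (a Dirichlet concentration parameter controls the
  divergence), and fully homozygous doubled-haploid individuals where
  flagged.

A third helper, :func:`simulate_loglik_profile`, produces the per-K model
log-likelihood runs consumed by the Evanno delta-K summary, with a planted
slope change (elbow) at a chosen K.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .study_io import GenotypeMatrix, PlotRecord, TrialDesign

__all__ = [
    "TrialSimConfig",
    "MarkerSimConfig",
    "simulate_trial",
    "simulate_markers",
    "simulate_loglik_profile",
]


@dataclass
class TrialSimConfig:
    """Variance architecture of a simulated balanced l x t x r trial.

    Defaults mirror the study conditions: a 20 x 6 line x tester set in 3
    replicates, with non-additive (SCA) variance roughly twice the average
    GCA variance — the architecture the curd-maturity components display —
    and a plot error of 5 on the trait scale.
    """

    l: int = 20
    t: int = 6
    r: int = 3
    mu: float = 100.0
    var_gca_line: float = 14.0
    var_gca_tester: float = 14.0
    var_sca: float = 27.0
    var_rep: float = 0.5
    var_error: float = 5.0
    parent_inbreeding_effect: float = 10.0
    check_count: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in ("var_gca_line", "var_gca_tester", "var_sca", "var_rep", "var_error"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.l < 2 or self.t < 2 or self.r < 2:
            raise ValueError("need l >= 2, t >= 2, r >= 2")


def _centred_normal(rng, n, var):
    """Zero-sum draw whose df-based variance (sum of squares / (n-1)) is an
    unbiased estimate of ``var`` — exactly what the ANOVA mean squares
    divide by, so component recovery is unbiased."""
    x = rng.normal(0.0, np.sqrt(var), size=n)
    return x - x.mean()


def simulate_trial(cfg: TrialSimConfig) -> tuple[TrialDesign, list[PlotRecord], dict]:
    """Simulate one balanced trial; returns (design, records, truth).

    The truth record stores the drawn effect vectors and the configured
    variances for recovery experiments.
    """
    rng = np.random.default_rng(cfg.seed)
    line_ids = [f"L{i+1}" for i in range(cfg.l)]
    tester_ids = [f"T{j+1}" for j in range(cfg.t)]
    check_ids = [f"C{k+1}" for k in range(cfg.check_count)]
    design = TrialDesign(line_ids, tester_ids, cfg.r, check_ids)

    g_line = _centred_normal(rng, cfg.l, cfg.var_gca_line)
    g_tester = _centred_normal(rng, cfg.t, cfg.var_gca_tester)
    s = rng.normal(0.0, np.sqrt(cfg.var_sca), size=(cfg.l, cfg.t))
    s = s - s.mean(axis=1, keepdims=True) - s.mean(axis=0, keepdims=True) + s.mean()
    rep_eff = rng.normal(0.0, np.sqrt(cfg.var_rep), size=cfg.r)
    sd_e = np.sqrt(cfg.var_error)

    records: list[PlotRecord] = []
    trait = "y"
    for k in range(cfg.r):
        rep = k + 1
        for i, li in enumerate(line_ids):
            y = cfg.mu + 2 * g_line[i] - cfg.parent_inbreeding_effect \
                + rep_eff[k] + rng.normal(0, sd_e)
            records.append(PlotRecord(li, "line_parent", rep, {trait: y}))
        for j, tj in enumerate(tester_ids):
            y = cfg.mu + 2 * g_tester[j] - cfg.parent_inbreeding_effect \
                + rep_eff[k] + rng.normal(0, sd_e)
            records.append(PlotRecord(tj, "tester_parent", rep, {trait: y}))
        for i, li in enumerate(line_ids):
            for j, tj in enumerate(tester_ids):
                y = cfg.mu + g_line[i] + g_tester[j] + s[i, j] \
                    + rep_eff[k] + rng.normal(0, sd_e)
                records.append(
                    PlotRecord(design.cross_label(li, tj), "cross", rep,
                               {trait: y}, cross_parents=(li, tj))
                )
        for c in check_ids:
            y = cfg.mu + rep_eff[k] + rng.normal(0, sd_e)
            records.append(PlotRecord(c, "check", rep, {trait: y}))

    truth = {
        "trait": trait,
        "mu": cfg.mu,
        "gca_lines": g_line,
        "gca_testers": g_tester,
        "sca": s,
        "rep_effects": rep_eff,
        "var_gca_line": cfg.var_gca_line,
        "var_gca_tester": cfg.var_gca_tester,
        "var_gca_avg": (cfg.t * cfg.var_gca_line + cfg.l * cfg.var_gca_tester)
        / (cfg.l + cfg.t),
        "var_sca": cfg.var_sca,
        "var_error": cfg.var_error,
        "inbreeding_effect": cfg.parent_inbreeding_effect,
    }
    return design, records, truth


@dataclass
class MarkerSimConfig:
    """Structured codominant SSR panel.

    Defaults emulate the study panel: 26 individuals x 87 loci, 2-10
    alleles per locus, 4 subpopulations, and fully homozygous individuals
    (the panel mixes male-sterile backcross lines and doubled haploids,
    both essentially homozygous, so ``dh_flags`` defaults to all-true).
    """

    n_individuals: int = 26
    n_loci: int = 87
    min_alleles: int = 2
    max_alleles: int = 10
    n_subpops: int = 4
    differentiation: float = 0.5   # Dirichlet concentration; smaller = more diverged
    dh_flags: list[bool] | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.min_alleles < 2:
            raise ValueError("need at least 2 alleles per locus")
        if self.max_alleles < self.min_alleles:
            raise ValueError("max_alleles < min_alleles")
        if self.differentiation <= 0:
            raise ValueError("differentiation must be positive")
        if self.dh_flags is not None and len(self.dh_flags) != self.n_individuals:
            raise ValueError("dh_flags length must equal n_individuals")


def simulate_markers(cfg: MarkerSimConfig) -> tuple[GenotypeMatrix, dict]:
    """Simulate a structured SSR panel; returns (genotypes, truth)."""
    rng = np.random.default_rng(cfg.seed)
    dh = cfg.dh_flags if cfg.dh_flags is not None else [True] * cfg.n_individuals
    inds = [f"I{i+1}" for i in range(cfg.n_individuals)]
    loci = [f"ssr{j+1:03d}" for j in range(cfg.n_loci)]
    subpop = np.array([i % cfg.n_subpops for i in range(cfg.n_individuals)])

    base_freqs = []
    pop_freqs = []   # per locus: (n_subpops, k) array
    for _ in loci:
        k = int(rng.integers(cfg.min_alleles, cfg.max_alleles + 1))
        base = rng.dirichlet(np.ones(k))
        pops = rng.dirichlet(cfg.differentiation * k * base, size=cfg.n_subpops)
        base_freqs.append(base)
        pop_freqs.append(pops)

    calls = {}
    for i, ind in enumerate(inds):
        for j, loc in enumerate(loci):
            if rng.random() < cfg.missing_rate:
                calls[(ind, loc)] = None
                continue
            p = pop_freqs[j][subpop[i]]
            if dh[i]:
                a = rng.choice(len(p), p=p)
                call = (str(a), str(a))
            else:
                a, b = rng.choice(len(p), size=2, p=p)
                call = (str(min(a, b)), str(max(a, b)))
            calls[(ind, loc)] = call
    gm = GenotypeMatrix(inds, loci, calls)
    truth = {
        "subpop": subpop,
        "base_freqs": base_freqs,
        "pop_freqs": pop_freqs,
        "dh_flags": list(dh),
    }
    return gm, truth


def simulate_loglik_profile(
    k_max: int = 10,
    n_runs: int = 15,
    elbow_k: int = 4,
    seed: int = 0,
    slope_before: float = 50.0,
    slope_after: float = 2.0,
    noise_sd: float = 0.5,
) -> dict[int, list[float]]:
    """Per-K log-likelihood runs with a piecewise-linear mean profile whose
    slope changes at ``elbow_k`` (the planted optimum)."""
    if not 2 <= elbow_k < k_max:
        raise ValueError("need 2 <= elbow_k < k_max")
    rng = np.random.default_rng(seed)
    out: dict[int, list[float]] = {}
    level = -1000.0
    means = {}
    for k in range(1, k_max + 1):
        means[k] = level
        level += slope_before if k < elbow_k else slope_after
    for k in range(1, k_max + 1):
        out[k] = list(means[k] + rng.normal(0, noise_sd, size=n_runs))
    return out
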