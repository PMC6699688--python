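"""Genetic variance components and derived parameters from the line x
tester mean squares.

Estimator forms (``published`` is the default):

=============  ==========================================  =========================
component      published form                              textbook form
=============  ==========================================  =========================
sigma2_gca(l)  (MS_line - MS_error) / (r t)                (MS_line - MS_lxt) / (r t)
sigma2_gca(t)  (MS_tester - MS_error) / (r l)              (MS_tester - MS_lxt) / (r l)
sigma2_sca     (MS_lxt - MS_error) / r                     same
=============  ==========================================  =========================

The average GCA variance is the cross-count-weighted mean
(t*sigma2_line + l*sigma2_tester) / (l + t): each line is observed in t
crosses and each tester in l. Additive and dominance variances follow the
half-sib convention for fully inbred parents, sigma2_A = 2*sigma2_gca(avg)
and sigma2_D = sigma2_sca. Negative estimates are reported as computed
unless ``clamp_negative`` is set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .anova import AnovaTable
from .study_io import TrialDesign

__all__ = [
    "VarianceComponents",
    "estimate_variance_components",
    "variance_components_from_ms",
    "degree_of_dominance",
    "heritability_and_ga",
    "heritability_class",
    "predictability_ratio",
]

SELECTION_K = 2.06  # standardized selection differential at 5% intensity


@dataclass
class VarianceComponents:
    trait: str
    s2_gca_line: float
    s2_gca_tester: float
    s2_gca_avg: float
    s2_sca: float
    s2_A: float
    s2_D: float
    env_var: float  # MS_error / r, the variance of an entry mean
    estimator_form: str = "published"

    @property
    def ratio_AD(self) -> float:
        if self.s2_D == 0:
            raise ZeroDivisionError("sigma2_D is zero")
        return self.s2_A / self.s2_D

    @property
    def phenotypic_var(self) -> float:
        return self.s2_A + self.s2_D + self.env_var


def variance_components_from_ms(
    ms_line: float,
    ms_tester: float,
    ms_lxt: float,
    ms_error: float,
    l: int,
    t: int,
    r: int,
    trait: str = "",
    estimator_form: str = "published",
    clamp_negative: bool = False,
) -> VarianceComponents:
    """Variance components directly from the four mean squares."""
    if estimator_form == "published":
        sub_l = sub_t = ms_error
    elif estimator_form == "textbook":
        sub_l = sub_t = ms_lxt
    else:
        raise ValueError(f"unknown estimator_form {estimator_form!r}")
    s2_line = (ms_line - sub_l) / (r * t)
    s2_tester = (ms_tester - sub_t) / (r * l)
    s2_sca = (ms_lxt - ms_error) / r
    if clamp_negative:
        s2_line = max(s2_line, 0.0)
        s2_tester = max(s2_tester, 0.0)
        s2_sca = max(s2_sca, 0.0)
    s2_avg = (t * s2_line + l * s2_tester) / (l + t)
    return VarianceComponents(
        trait=trait,
        s2_gca_line=s2_line,
        s2_gca_tester=s2_tester,
        s2_gca_avg=s2_avg,
        s2_sca=s2_sca,
        s2_A=2 * s2_avg,
        s2_D=s2_sca,
        env_var=ms_error / r,
        estimator_form=estimator_form,
    )


def estimate_variance_components(
    anova: AnovaTable,
    design: TrialDesign,
    estimator_form: str = "published",
    clamp_negative: bool = False,
) -> VarianceComponents:
    """Variance components from a fitted line x tester ANOVA table."""
    ms = anova.mean_squares()
    for needed in ("Line Effect", "Tester Effect", "Line x Tester Eff.", "Error"):
        if needed not in ms:
            raise ValueError(f"ANOVA table lacks mean square for {needed!r}")
    return variance_components_from_ms(
        ms["Line Effect"], ms["Tester Effect"], ms["Line x Tester Eff."], ms["Error"],
        design.l, design.t, design.r,
        trait=anova.trait, estimator_form=estimator_form, clamp_negative=clamp_negative,
    )


def degree_of_dominance(vc: VarianceComponents) -> float | None:
    """sqrt(sigma2_D / sigma2_A); None (with a warning) when sigma2_A <= 0."""
    if vc.s2_A <= 0:
        warnings.warn(
            f"trait {vc.trait!r}: nonpositive additive variance, degree of dominance undefined"
        )
        return None
    if vc.s2_D < 0:
        warnings.warn(f"trait {vc.trait!r}: negative dominance variance, degree of dominance undefined")
        return None
    return math.sqrt(vc.s2_D / vc.s2_A)


def heritability_class(h2_pct: float) -> str:
    """Breeder's classification: high (>30%), medium (10-30%), low (<10%)."""
    if h2_pct > 30:
        return "high"
    if h2_pct >= 10:
        return "medium"
    return "low"


def heritability_and_ga(
    vc: VarianceComponents,
    selection_k: float = SELECTION_K,
    ga_heritability: str = "narrow",
) -> tuple[float, float]:
    """Narrow-sense heritability (percent) and genetic advance.

    h2ns% = 100 * sigma2_A / VP with VP = sigma2_A + sigma2_D + MS_error/r.
    GA = h2 * sqrt(VP) * K with h2 as a fraction; the narrow-sense form is
    the default, a broad-sense option (using (sigma2_A+sigma2_D)/VP) exists.
    """
    vp = vc.phenotypic_var
    if vp <= 0:
        raise ValueError("nonpositive phenotypic variance")
    h2_narrow = 100 * vc.s2_A / vp
    if ga_heritability == "narrow":
        h2_frac = vc.s2_A / vp
    elif ga_heritability == "broad":
        h2_frac = (vc.s2_A + vc.s2_D) / vp
    else:
        raise ValueError(f"unknown ga_heritability {ga_heritability!r}")
    ga = h2_frac * math.sqrt(vp) * selection_k
    return h2_narrow, ga


def predictability_ratio(vc: VarianceComponents) -> float:
    """2*sigma2_gca / (2*sigma2_gca + sigma2_sca); near 1 means additive,
    GCA-predictable control of the trait."""
    denom = 2 * vc.s2_gca_avg + vc.s2_sca
    if denom == 0:
        raise ZeroDivisionError("2*sigma2_gca + sigma2_sca is zero")
    return 2 * vc.s2_gca_avg / denom
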