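# linetester

Line × tester combining-ability analysis, heterosis estimation and SSR
diversity statistics for balanced hybrid-breeding trials — built around a
cauliflower (*Brassica oleracea* var. *botrytis*) study design in which 20
cytoplasmic male-sterile (CMS) lines were crossed to 6 doubled-haploid (DH)
testers and the 120 F₁ hybrids evaluated with their 26 parents over 3
replicates for 16 agronomic traits, alongside an 87-locus microsatellite
(SSR) panel of the parents.

It is written for plant breeders and quantitative geneticists who need the
full computational chain of such a study as tested, reusable code:

- **ANOVA** (`linetester.anova`): the balanced RCBD line × tester source
  decomposition — replicates, treatments split into parents (lines, testers,
  lines-vs-testers), parents-vs-crosses, and crosses split into line effect,
  tester effect and line × tester interaction — with upper-tail F tests.
- **Combining ability** (`linetester.combining`): with μ the grand mean of
  the l × t cross means, GCA effects gᵢ = x̄ᵢ. − μ and gⱼ = x̄.ⱼ − μ, SCA
  effects sᵢⱼ = x̄ᵢⱼ − x̄ᵢ. − x̄.ⱼ + μ, standard errors SE(gᵢ) = √(MSe/rt),
  SE(gⱼ) = √(MSe/rl), SE(sᵢⱼ) = √(MSe/r), and 95% critical differences.
- **Variance components** (`linetester.varcomp`):
  σ²gca(line) = (MS_line − MS_error)/rt, σ²gca(tester) = (MS_tester −
  MS_error)/rl, σ²sca = (MS_l×t − MS_error)/r, the cross-count-weighted
  average σ²gca, σ²A = 2σ²gca, σ²D = σ²sca, degree of dominance
  √(σ²D/σ²A), narrow-sense heritability h²ns = σ²A/V_P, genetic advance
  GA = h² · √V_P · K (K = 2.06 at 5% selection intensity), and the
  predictability ratio 2σ²gca/(2σ²gca + σ²sca).
- **Heterosis** (`linetester.heterosis`): MPH% = 100(F₁ − MP)/MP and
  BPH% = 100(F₁ − BP)/BP with direction-aware better-parent selection,
  t tests against the trial error, and top-k ranking.
- **Marker diversity** (`linetester.markers`): allele frequencies, Ho,
  He = 1 − Σpᵢ², Botstein PIC = 1 − Σpᵢ² − ΣΣ 2pᵢ²pⱼ², simple matching
  genetic distance, UPGMA/NJ trees with locus bootstrap, Evanno
  ΔK = |L″(K)|/sd(L(K)).
- **Association** (`linetester.association`): standardized Euclidean
  phenotypic distance, trait PCA variance shares, and the Pearson
  correlation grid of GD/PD/SCA against MPH/BPH over crosses.
- **Synthetic data** (`linetester.simulate`): ground-truthed generators for
  balanced trials (additive/non-additive architecture, replicate and plot
  error, parental inbreeding depression) and structured SSR panels with
  fully homozygous DH individuals.

The published summary tables that are reproducible without the raw plot
data — the per-trait mean squares, the derived variance components and the
per-locus diversity table — ship as CSV fixtures under
`src/linetester/data/`.

## Worked example

From the published curd-maturity (CM) mean squares — line 1054.16, tester
33.96, line × tester 85.61, error 4.94, with l = 20, t = 6, r = 3:

```python
from linetester.varcomp import (variance_components_from_ms,
                                heritability_and_ga, predictability_ratio)

vc = variance_components_from_ms(1054.16, 33.96, 85.61, 4.94, l=20, t=6, r=3)
h2, ga = heritability_and_ga(vc)
print(round(vc.s2_gca_line, 2), round(vc.s2_gca_avg, 2), round(vc.s2_sca, 2))
print(round(h2, 2), round(ga, 2), round(predictability_ratio(vc), 2))
```

prints

```
58.29 13.82 26.89
49.21 7.6 0.51
```

i.e. a line GCA variance of 58.29, average GCA variance 13.82 and SCA
variance 26.89 days²; curd maturity is the one trait where additive
variance (σ²A = 27.65) exceeds dominance variance, giving the highest
narrow-sense heritability of the study (49.21%, "high" class), an expected
selection gain of 7.60 days per cycle at 5% intensity, and a
predictability ratio of 0.51.

The `analysis/` directory holds the numbered end-to-end drivers
(`01_simulate_trial.py` … `06_association.py`): simulate a study-sized
trial and SSR panel, run the ANOVA and combining-ability stage, derive all
16 traits' variance components from the shipped mean squares, estimate and
rank heterosis, compute marker diversity, distances, the bootstrapped
UPGMA tree and ΔK, and correlate distances and SCA with heterosis. Each
writes its tables under `results/`.

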