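# Methods

## The model

A balanced line × tester trial crosses l female lines to t male testers
and grows the l·t hybrids together with the l + t parents (and optionally
check cultivars) in r complete replicates. The observation model for a
cross plot is

    y_ijk = μ + g_i + g_j + s_ij + ρ_k + ε_ijk

with line GCA g_i, tester GCA g_j, SCA s_ij, replicate effect ρ_k and plot
error ε. GCA effects are constrained to sum to zero over lines and over
testers; the SCA matrix has zero row and column sums. Parents are modelled
per se as μ + 2g − d, the homozygous additive value minus a uniform
inbreeding-depression offset d (both parent sets — CMS backcross lines and
doubled haploids — are treated as fully inbred, the F = 1 convention
implicit in σ²A = 2·Cov(half-sibs)). The offset induces positive
mid-parent heterosis without an explicit locus-level model.

## ANOVA

The analysis is the plain RCBD decomposition on the l + t + lt entries
(checks excluded). The trial this package mirrors was laid out as an
alpha lattice, but its published combining-ability analysis is the RCBD
one — the error degrees of freedom equal (entries − 1)(r − 1) — so block
labels are carried through I/O as informational only and no lattice
adjustment or REML fit is attempted. Parents-vs-crosses and
lines-vs-testers are 1-df group contrasts on totals. Error SS is obtained
by subtraction, so total SS = replicate SS + treatment SS + error SS holds
by construction; the partition identities are verified against an
independent deviation-form oracle in the tests. Missing plot values are
accepted at I/O but the ANOVA refuses incomplete tables rather than
silently switching estimator class.

## Estimator forms

The GCA variance estimators subtract MS_error, not the textbook MS_l×t:

    σ²gca(line)   = (MS_line  − MS_error)/(r·t)
    σ²gca(tester) = (MS_tester − MS_error)/(r·l)
    σ²sca         = (MS_l×t   − MS_error)/r

and the average GCA variance is cross-count weighted,
(t·σ²line + l·σ²tester)/(l + t), because each line is observed in t
crosses and each tester in l. These are the forms that reproduce the
published component tables from the published mean squares; the textbook
form is available behind `estimator_form="textbook"`. Negative estimates
are reported as computed (`clamp_negative` exists but is off by default).
Genetic advance uses the narrow-sense heritability fraction — the form
that reproduces the published GA values — with a broad-sense option.

Critical differences use the SE of a single effect (t(α/2, df_e)·SE),
which is what reproduces the published CD footers; a `difference_based`
flag gives the √2-inflated CD for comparing two effects. Effect
significance is a two-sided t test: effects can be negative and the
desirable direction is a reporting concern (per-trait `+`/`-` in
`linetester.traits`), not part of the statistic. Heterosis t statistics
use the balanced-trial standard errors √(3MSe/2r) for MPH and √(2MSe/r)
for BPH; the squared t is the equivalent 1-df F. No multiple-testing
correction is applied across traits or crosses, matching standard
practice in these trials.

## Marker statistics

He is the plain gene diversity 1 − Σp², with the 2n/(2n−1) small-sample
correction as an option. PIC defaults to Botstein's form
1 − Σp² − ΣΣ_{i<j} 2pᵢ²pⱼ²: per-locus diversity tables in this literature
consistently show PIC < He, which the simpler 1 − Σp² (selectable as
`pic_form="simple"`) cannot produce. Simple matching distance scores each
co-typed locus by shared alleles counting multiplicity (0, ½ or 1) and
averages over loci with pairwise deletion of missing calls. Allele labels
are compared as exact strings after whitespace trimming — panels scored
from gels are already discretized, so no fragment-size binning is done.

UPGMA delegates the average-linkage merge order to scipy and assigns node
heights as half the merge distance, so an ultrametric input is a fixed
point of the cophenetic distances. Bootstrap support resamples loci
(columns, the marker-tree convention), requires an explicit seed, and
scores each internal node by the fraction of replicate trees containing
its exact leaf set. Neighbour-joining (scikit-bio) is provided alongside
since both appear in this literature; UPGMA is the default for reports.

The Evanno summary takes externally supplied per-K log-likelihood runs
(ΔK = |L″(K)|/sd(L(K))); the Bayesian admixture inference that produces
such runs is out of scope.

## Phenotypic distance and association

Traits are z-score standardized (population SD) before the Euclidean
distance: raw-scale distances are dominated by gram-denominated traits,
and for p standardized, independent traits the expected pairwise distance
is ≈ √(2p) — the magnitude such studies report — so standardization is
the default and makes PD invariant to per-trait affine rescaling.
Correlations in the association grid are computed per trait over the l·t
crosses with pairwise deletion, reporting n per cell.

## Synthetic generators and what they show

`simulate_trial` defaults to the study conditions: (l, t, r) = (20, 6, 3),
SCA variance 27 and average GCA variance 14 (the curd-maturity magnitudes,
the one trait with a near-1 additive/dominance ratio), plot error 5,
replicate variance 0.5, inbreeding depression 10 on a trait scale of
μ = 100. Effects are drawn normal and exactly centred (SCA
double-centred). They are deliberately *not* rescaled after centring:
the ANOVA mean squares divide by the model df (l − 1, t − 1,
(l−1)(t−1)), for which the centred draw is already unbiased — E[MS_line] =
σ²e + r·t·Σg²/(l−1) with E[Σg²] = (l−1)σ² — and this, together with the
exact zero row/column sums removing any SCA leakage into main-effect
totals, is what makes the published-form estimators unbiased in the recovery
experiment (verified at 500 trials; z-scores < 3). The per-trial plug-in
heritability ratio carries a small Jensen bias (≈ −0.02 at this design
size); heritability recovered from the averaged components is unbiased,
and the tests check both.

`simulate_markers` defaults to 26 individuals × 87 loci with 2–10 alleles
per locus in 4 subpopulations, all individuals fully homozygous (the
study panel mixes heavily backcrossed CMS lines and DH testers).
Subpopulation allele frequencies are Dirichlet draws around shared base
frequencies; the concentration default 0.5 produces the cleanly separable
clusters such panels show (average-linkage clustering recovers the 4
planted groups at adjusted Rand ≥ 0.9 across seeds). Loci are independent
— no linkage or map positions are simulated, since no analysis stage uses
them — and the generator does not emulate genotyping error or null
alleles. Passing tests therefore demonstrate correctness of the
estimators under the balanced normal model, not robustness to real-data
pathologies (unbalancedness, scoring error, relatedness within
subpopulations).

Problem sizes used in the statistical tests — 500 recovery trials, 1000
null trials at (4, 3, 3), 20 clustering seeds, 100 elbow seeds, 200
association simulations — were chosen to keep Monte-Carlo error well
inside the asserted tolerances while the whole suite stays quick to run.

## Numerical notes and edge cases

- Zero-variance data: every SS is 0 and F statistics are reported absent.
- Degenerate variance components: σ²A ≤ 0 makes the degree of dominance
  undefined (None with a warning); V_P ≤ 0 is an error.
- Heterosis with MP = 0 or BP = 0 flags the cross (NaN) instead of
  dividing; ranking breaks ties by BPH then cross label, so it is
  deterministic.
- Evanno ΔK raises on zero run-to-run SD at an interior K rather than
  emitting an infinity.
- Published-table fixtures carry the printed 2-dp values; chaining them
  reproduces every derived cell to 2 dp except nine cells that differ by
  exactly one unit in the last printed digit, where the original analysis
  chained unrounded mean squares (e.g. the gross-plant-weight SCA variance
  computes to 277152.37 against a printed 277152.38). The tests assert the
  headline cells exactly and the full grid within one last-digit ulp.
- Counts of "significantly high SCA" crosses per trait depend on unstated
  tie conventions at the threshold and are not asserted.
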