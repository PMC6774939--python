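# Methods

## The transmission model

`freqbias` models a cultural system as a haploid Wright–Fisher-style
population with infinite-alleles innovation and frequency-dependent
copying. A population of N agents each carries one variant. Generations do
not overlap: at every timestep all N agents are redrawn simultaneously
from the previous generation's counts. Each new agent

1. with probability μ innovates, adopting a variant label never used
   before in the run (a monotone global counter guarantees infinite-alleles
   novelty);
2. otherwise copies variant *k* with probability proportional to
   *n_k*^(1−b), where *n_k* is *k*'s count in the previous generation.

b = 0 reduces the kernel to proportional-to-frequency sampling (random
copying); b < 0 raises the weight of common variants (conformity); b > 0
favours rare ones (novelty). The kernel's sign convention is validated
empirically rather than assumed: the directionality test checks that the
mean fitted turn-over exponent decreases strictly across
b ∈ {−0.1, 0, +0.1} and exceeds the neutral value under conformity.

Runs start from maximal diversity (N distinct singletons) and discard a
warm-up period before recording. Because the stationary distribution does
not depend on the start, the choice of initial state is immaterial once
the warm-up has passed; the default warm-up of 200 steps is several times
the diversity relaxation time at the default constants (≈ 1/(2μ + 1/N) ≈
13 generations for N = 729, μ = 0.037).

Implementation: one seeded `numpy` generator per run; the per-step update
draws the innovator count Binomial(N, μ) and the copy counts from one
multinomial over the surviving variants, so a full 232-step run at the
default constants costs ~10 ms. `step()` errors on a previous-generation
count vector that does not sum to N or has non-positive total weight; a
uniform fallback is deliberately not provided.

### Warm-up estimation

`estimate_warmup` averages the Simpson-diversity series of many neutral
runs and slides a 50-step OLS window along the averaged curve; the first
window whose slope is statistically indistinguishable from zero (t-test,
α = 0.01) marks equilibrium. Window length and α are configurable. At
N = 729, μ = 0.037 with 1000 replicates the plateau is detected near
step 50 — diversity genuinely relaxes that fast at these constants — while
the package keeps the conventional, conservative 200-step default for all
analyses. If no window passes within the horizon the function raises
rather than returning a guess.

## Summary statistics

**Turn-over.** At each timepoint variants are ranked by descending count;
ties break by earlier first appearance in the table, then by column order
(lexicographic id for tables built from events — the synthetic generator
zero-pads its ids so lexicographic order equals creation order).
z_y(t) is the number of variants in the top-y list at t that were absent
from the top-y list at t−1; when fewer than y variants are present the
list truncates to all of them. The mean profile follows z̄_y = A·y^x,
fitted by OLS on log z̄_y against log y, excluding sizes with z̄_y = 0
(log undefined; only degenerate short runs are affected).

**The saturation cap.** At the default constants a timepoint holds far
fewer distinct variants (~40–190 depending on b) than the largest list
size carried in the statistics vector (142). Beyond the minimum
per-timepoint variant count every "top list" is the entire population and
z̄_y stops growing with y; including that flat tail in the fit drags the
exponent down under *both* bias signs and destroys its diagnostic value.
The exponent statistic is therefore always fitted over list sizes up to
min(y_max, minimum per-timepoint variant count) — the same convention as
defining y_max from the sparsest year of observed data — while the z̄_y
vector itself still spans 1..y_max. `turnover_profile(...,
cap_at_present=False)` exposes the uncapped fit for inspection.

**Diversity.** Simpson's D = Σ (n_i/n)² — the probability that two tokens
drawn with replacement are the same variant; values near 1 mean low
diversity. The without-replacement (unbiased) form is available behind a
flag. D ∈ (0, 1], equal to 1 iff monomorphic.

**The statistics vector.** Fixed slot order: x, z̄_1..z̄_{y_max},
D_1..D_T, D̄ (176 slots at y_max = 142, T = 32), optionally followed by
two linear-discriminant axes (178). A record whose exponent is unfittable
(fewer than two non-zero z̄ values) carries NaN in the x slot and is
dropped from reference tables, with the count logged.

## Observation-derived constants

From a long-format event table, N is estimated as the mean number of
unique agents per year (rounded to nearest, halves away from zero — the
convention is stated because the estimate feeds an integer population
size), and μ as the mean over years of (variants first appearing that
year) / (events that year). The first year is excluded from the μ
estimate: "first appearance" is undefined there, so including it would
count every initial variant as new. Note the estimator reads *first
appearance in the observation window*, which slightly overstates the true
innovation rate when variants re-enter after an absence; on synthetic data
at the default regime the bias is within ~0.001–0.002 of μ = 0.037.

Year filtering (`filter_years`) drops timepoints with fewer than
`min_variants` non-zero variants; "presence" means a non-zero count in
that row, not cumulative presence. The threshold is a free parameter.

## Rejection ABC

Parameter inference draws b ~ U(−0.2, 0.2), simulates at the observed
constants (32 recorded timepoints), and summarises each run by (x, D̄).
Each statistic is standardised by its median absolute deviation across
the reference table — making the exponent (scale ~0.05) and diversity
(scale ~0.002) commensurable and the acceptance region invariant to
affine rescaling of either statistic; raw distances are available via
`standardize=False`. The ε = 0.01 fraction with the smallest Euclidean
distances to the observed pair forms the posterior sample
(accept count = round(ε·n), exactly).

The 95% HPDI is the shortest window of ⌈0.95·m⌉ consecutive order
statistics of the accepted sample — checked in the tests against an
exhaustive window scan. Goodness of fit uses the median accepted distance
as test statistic, with a null built from pseudo-observations drawn from
the reference table, each evaluated leave-one-out against the remaining
rows (MAD scales are computed once from the full table; removing one row
perturbs them negligibly at the table sizes used). Cross-validation
re-estimates b for held-out reference rows at each tolerance and reports
squared errors normalised by the prior variance of b, so 1 means
uninformative statistics and 0 perfect recovery.

## Random-forest model choice

Three reference blocks are simulated — b ~ U(−0.2, 0) (conformity),
b ~ U(0, 0.2) (novelty), b = 0 (neutrality) — with equal counts per
class. A two-axis linear discriminant projection is fitted once on the
full labelled table (not refit per bootstrap; it precedes forest
training) and appended to the 176 base statistics. A
`RandomForestClassifier` with 1000 trees, bootstrap samples of the full
table size and default CART hyper-parameters is trained on the 178
predictors; out-of-bag predictions give the error estimate. For tiny
tables the LDA can be switched to the shrinkage-regularised eigen solver
(`shrinkage=True`); the default solver tolerates the collinearity of
neighbouring z̄/D columns at realistic table sizes.

The posterior probability of the selected model follows the
OOB-regression recipe: a regression forest is fitted to the per-record
OOB misclassification indicator over the predictors, and the posterior
probability is 1 − its prediction at the observed point, clipped to
[0, 1]. Because the fully grown regression forest partially memorises
training rows, this quantity is meaningful at points *outside* the
reference table — which the observed data always are.

Gini (mean-decrease-impurity) importances are reported ranked. Known
artifact, demonstrated in the tests: duplicating a predictor does not
conserve the pair's summed importance (correlated copies each extract
impurity decrease at different nodes); importances are a ranking
diagnostic, not an additive decomposition.

## Synthetic data

The generator runs the simulator at a chosen (b_true, μ, N) and expands
each recorded agent-variant adoption into one event row. Agent ids are
drawn each year without replacement from a pool of 10·N, so unique
artists per year equal N exactly while artists recur across years; the
generator does not model artist careers, genre structure or the partial
coverage of a crowd-sourced database (rare-variant undercount), so
pipeline tests on synthetic data validate the inference machinery, not
robustness to those observational biases. With `events_per_agent` = 1
(default) the rebuilt frequency table equals the simulated one exactly
(the round-trip test); larger values scale all counts uniformly.

## Problem sizes and tolerances

Monte-Carlo sizes used by the test and acceptance runs, chosen as the
package's own desk-scale defaults: 200 replicates × 100 recorded
timesteps for the neutral-exponent calibration (band 0.86 ± 0.1);
5000 simulations per model for the choice reference (OOB error checked
at ≤ 0.10; it tightens toward ~0.05 as the table grows); 10 000 rejection
reference rows with ε = 0.01 for parameter recovery (median bias < 0.02,
pooled HPDI coverage ≥ 90% over 60 recovery experiments); 60-replicate
ensembles for the directionality check. All randomness flows from
explicit `SeedSequence` roots, so every number is reproducible.

## Known limitations

- Single-parameter inference: N and μ are plugged in as point estimates,
  not jointly inferred with b.
- The turn-over exponent is known to be overestimated with few
  timepoints; at T = 32 comparisons should be made against simulations of
  identical length (as the ABC machinery does) rather than against the
  asymptotic neutral value.
- No overlapping generations, age or network structure, or
  prestige/content biases; equifinality with those mechanisms is not
  addressed.
- The closed-form neutral turn-over expectations from the earlier
  literature are not implemented; neutral expectations are generated by
  simulation with b = 0.
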