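# freqbias

Generative inference of **frequency-based transmission bias** in cultural
frequency data.

Many cultural systems — music samples passed between artists, baby names,
dog breeds — leave longitudinal records of how often each variant was
adopted each year. Whether that record reflects *random copying* (neutral
evolution), *conformity* (disproportionate adoption of common variants) or
*novelty bias* (disproportionate adoption of rare ones) cannot be read off
the frequencies directly; it has to be inferred by comparing the observed
dynamics with those of an explicit transmission model. `freqbias`
implements that comparison end to end for analysts of population-scale
cultural data:

- an **agent-based infinite-alleles transmission model**: N agents are
  resimulated each timestep; an agent innovates with probability μ
  (adopting a never-before-seen variant) and otherwise copies variant *k*
  of the previous generation with probability ∝ *n_k*^(1−b). b = 0 is
  neutral, b < 0 conformity, b > 0 novelty;
- **turn-over and diversity summary statistics**: the turn-over rate *z_y*
  (new entrants per timestep into the top-*y* most-frequent list) follows
  the power law *z̄_y = A·y^x*, with x ≈ 0.86 under neutrality, x > 0.86
  under conformity and x < 0.86 under novelty; plus per-timepoint Simpson
  diversity D = Σ p²;
- **rejection ABC** for the posterior of b from (x, D̄): accept the ε
  fraction of prior draws whose simulated statistics fall closest to the
  observed pair (MAD-standardised Euclidean distance), summarised by the
  posterior median and 95% HPDI, with goodness-of-fit and leave-one-out
  cross-validation diagnostics;
- **random-forest ABC model choice** among conformity / novelty /
  neutrality on 178 statistics (x, z̄_1..142, D_1..32, D̄, two LDA axes),
  with per-tree votes, out-of-bag error, an OOB-calibrated posterior
  probability and Gini variable importances;
- a **synthetic-data generator** that emits WhoSampled-style long-format
  sampling-event tables (`year,variant,agent`) with known ground truth, so
  the full pipeline is testable without scraped data.

## Worked example

```python
from freqbias import FrequencyBiasModel, SynthConfig, generate_dataset

# a synthetic sampling tradition with known weak conformity (b = -0.05)
ds = generate_dataset(SynthConfig(b_true=-0.05, seed=7))
model = FrequencyBiasModel.from_events(ds.events)
print(model)
# <FrequencyBiasModel T=32 V=893 N=729 mu=0.0358 y_max=40>

res = model.fit(n_iter=10_000, epsilon=0.01, seed=1)
print(res.summary())
```

```
Rejection-ABC estimate of frequency-based bias
======================================================
observed turn-over exponent x       0.9516
observed mean diversity D̄           0.7404
prior                            U(-0.2, 0.2)
reference simulations            10000
tolerance epsilon                0.01
accepted draws                   100
------------------------------------------------------
posterior median b                  -0.0514
95% HPDI                         [-0.0592, -0.0449]
interpretation                   conformity (b < 0)
======================================================
```

The fitted exponent (0.95 > 0.86, a convex turn-over profile) already
hints at conformity; the posterior median −0.051 recovers the generating
b = −0.05 and the 95% HPDI excludes zero. Model choice works the same way:

```python
choice = model.fit_model_choice(n_per_model=2000, n_trees=1000, seed=1)
print(choice.summary())
```

```
Random-forest ABC model choice
======================================================
votes: conformity=1000  novelty=0  neutrality=0
selected model                   conformity
posterior probability            1.000
out-of-bag error                 0.053
------------------------------------------------------
top 5 variables (Gini importance):
  Dbar                 0.0937
  D_30                 0.0357
  D_18                 0.0332
  zbar_31              0.0316
  D_31                 0.0304
======================================================
```

Every tree votes conformity, and the forest's out-of-bag error (~5%)
shows the three regimes are well separated by the statistics — mean
diversity doing most of the work.

A command-line interface mirrors the library
(`freqbias synth | simulate | sumstats | abc-reject | abc-rf | full`); the
`full` subcommand runs ingest → constants → observed statistics →
rejection ABC → model choice and writes `posterior.json`,
`model_choice.json`, `summary_observed.csv` and a run `manifest.json`.

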