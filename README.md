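# paleoforage

Did climate change or human hunting pressure restructure European
hunter-gatherer diets between the Last Glacial Maximum and the early
Holocene (22–9 kya)? The zooarchaeological record alone cannot say:
climate drives both prey distributions and human population density, so
a falling share of a prey species in faunal assemblages is equally
consistent with habitat shifts and with anthropogenic resource
depression. `paleoforage` implements the full analytical chain needed to
separate the two, for researchers in quantitative paleoecology,
zooarchaeology and human behavioral ecology.

## The models

**Prey ranking.** Within the prey choice model, a species' profitability
is its post-encounter return rate. With pursuit failure probability *p*,
energy *e*, post-acquisition handling time *h* and post-encounter
pre-acquisition (pursuit) time *c*:

    PERR = e(1 − p) / ((1 − p)h + c)        [kcal/h]

A species of rank *j*+1 enters the diet iff its PERR exceeds the overall
return rate of the higher-ranked diet,

    e*_{j+1}/h*_{j+1} > Σ_{i≤j} λ_i e*_i / (1 + Σ_{i≤j} λ_i h*_i),

with effective values e\* = e(1−p), h\* = (1−p)h + c and encounter rates
λ. Parameters for extinct/extirpated populations are predicted from body
weight by per-parameter allometric regressions fitted on a reference
fauna.

**Habitat suitability.** A maximum-entropy presence/background model on
four climate variables (mean/low/high temperature, precipitation),
features limited to linear + quadratic terms, L1-regularized with the
multiplier chosen by four-fold cross-validated AUC, hindcast over
century-sliced paleoclimate grids and evaluated at archaeological sites
(median calibrated age rounded to the nearest century; containing grid
cell).

**Population proxy.** Radiocarbon dates are calibrated on a 1-year grid,
same-site dates binned by complete-linkage clustering at 200 years, the
summed probability distribution truncated to 22.0–9.1 kya and smoothed
with a 200-year local mean.

**Path models.** Everything is aggregated to Cultural Techno-Units
(Magdalenian, Epigravettian, ABC, TPC, Mesolithic; BBT excluded for
sample size) and fed to piecewise structural equation models — one
quasibinomial logistic regression per causal path (φ from Pearson χ²,
t-based inference, latent-theoretic standardized betas):
`population ~ climate`, `suitability ~ climate`,
`zooarch ~ suitability + population`, plus a red-deer mediation model
`red deer ~ combined(reindeer+boar) ~ population ~ climate`.

Every input can be generated synthetically with known ground truth
(`paleoforage.synth`), so the whole chain is testable end to end with no
downloads.

## Worked example

```sh
python analysis/01_rank_prey.py
```

```
allometric fits (slope, p-value, R^2):
  e: slope=+0.949  p=3.59e-28  R2=0.987  [log-log]
  h: slope=+0.907  p=6.50e-26  R2=0.982  [log-log]
  c: slope=+0.086  p=2.70e-11  R2=0.800  [linear-log]
  p: slope=+0.039  p=1.05e-07  R2=0.642  [linear-log]

ranked target species (PERR in kcal/h):
 rank  species  weight_kg   perr
    1    horse      500.0 4087.7
    2      elk      385.0 4040.0
    3 red_deer      187.0 3909.2
    4     boar      117.0 3824.9
    5 reindeer       86.0 3769.9
```

Energy and handling scale almost isometrically with body weight (slopes
0.95 and 0.91 on the log-log scale), so the five return rates span only
8% across a 6× weight range — ranking prey by body weight alone would
be unreliable. The remaining drivers continue the chain:
`02_habitat_models.py` (envelope fitting and hindcasting, with held-out
AUC and rank correlation against the planted truth),
`03_population_proxy.py` (SPD), `04_combine_ctu.py` (the per-CTU summary
table) and `05_path_models.py` (path coefficients and the calibration
experiment showing that worlds generated *without* human pressure yield
population-path betas centered on zero while a real suitability effect
is detected with high power). Each writes its tables under `results/`.

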