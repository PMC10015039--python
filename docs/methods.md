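# Methods

This note documents the models, the synthetic worlds they are validated
on, and the numerical and design choices a user should know before
trusting or extending the pipeline.

## Prey choice with pursuit failure

The return rate `PERR = e(1−p)/((1−p)h + c)` discounts both the energy
`e` and the post-acquisition handling time `h` by the success
probability `1−p`, while the pursuit time `c` is paid on every attempt.
Setting `p = 0` recovers the classical `e/(h+c)`. The rate is undefined
only at `p = 1, c = 0` (nothing is ever caught and nothing is ever
spent), which is rejected as degenerate.

The diet-breadth solver needs the classical two-parameter form, so
pursuit failure enters through effective values `e* = e(1−p)` and
`h* = (1−p)h + c`; this makes the inclusion threshold for a species
exactly its PERR, keeping ranking and diet membership mutually
consistent. The solver adds species in rank order and stops at the first
whose PERR does not exceed the overall rate of the diet above it; this
prefix also maximizes the overall return rate over all rank prefixes
(verified against exhaustive search in the tests), and whether a species
is included never depends on its own encounter rate.

**Allometric prediction.** One OLS regression per parameter against body
weight. Defaults: log–log for `e` and `h` (the usual power-law
allometry), linear-in-log-weight for `c` and `p` (a probability and a
short duration whose *relative* noise is not multiplicative). All
transforms are configurable per parameter, including plain linear.
Predictions are clamped: `p` into [0, 1], `e`/`h` floored at 1e−9,
`c` at 0, so downstream PERRs stay finite. The p-value reported is the
two-sided t-test on the slope.

## Climate-envelope model

A presence/background maximum-entropy model. Features are the four
climate variables standardized by the mean/sd of the *training
background*, plus their squares (8 features, fixed order). The fit
minimizes

    −(1/n) Σ_presence w·f(x) + log Z_bg + m · Σ_f λ_f |w_f|

with `Z_bg` the mean of `exp(w·f)` over the background,
`λ_f = sd_presence(f)/√n_presence` (the maxent default-regularization
shape, floored at 1e−6) and `m` the regularization multiplier. The
objective is convex; it is solved by L-BFGS-B on the split `w = u − v`,
`u, v ≥ 0`, with the penalty written `m·λ·(u+v)` (equal to the L1 form
at any optimum, smooth everywhere), `ftol = 1e−13`.

Exact duplicate presence coordinates are dropped before fitting —
duplicate records carry no information about the environmental density,
and this makes fits invariant to accidental duplication of a presence
file. The synthetic occurrence generator jitters points inside cells, so
coincident points essentially never arise naturally.

**A note on the regularization path.** With *per-feature* penalty scales
the plain L1 norm of the weights is **not** guaranteed monotone in the
multiplier, and is observed to be non-monotone on some worlds. The
quantity the multiplier provably controls is the penalty-weighted norm
`Σ_f λ_f |w_f|`; that is what `EnvelopeModel.penalty_weighted_norm()`
exposes and the tests check (tolerance 1e−7 for residual optimizer
slack).

**Output scale.** Raw scores `w·f(x)` are mapped to [0, 1] by the
cloglog transform `1 − exp(−exp(η + const))` with `const` calibrated by
root-finding so that the mean output at the training presences is 0.5
(the modern maxent convention). The raw score is always available;
relative statements (AUC, rank correlations, CTU rankings) are identical
on either scale.

**Model selection.** Presences are partitioned into k = 4 seeded random
folds (not spatial blocks); each candidate multiplier is refit on k−1
folds and scored by rank-based AUC of the held-out presences against the
full background. Ties in mean AUC go to the larger multiplier (stronger
shrinkage).

**Site extraction.** Sites are assigned the century of their median
calibrated age with half-up rounding (12,350 → 12,400) and the value of
their containing cell — no interpolation, no reprojection; coordinates
are assumed to be on the grid's own CRS. Sites with no surface for their
century, outside the grid, or on nodata cells are skipped and counted,
never silently zeroed.

## Radiocarbon and the SPD

Calibration scans every calendar year in the curve's span and scores the
measurement against the linearly interpolated curve with variance
`error² + σ_curve(θ)²`, normalizing to unit mass (computed in log space;
negligible tails trimmed at 1e−7 of the mode). Dates whose support
touches the curve edge with non-negligible density are rejected as
outside coverage.

Same-site dates are binned by complete-linkage clustering of
*uncalibrated* ages cut at 200 years — the established SPD binning
convention; bins never span sites. Each bin contributes the *mean* of
its members' calibrated densities, so every bin carries total mass 1 and
intensively dated sites are not over-weighted. The SPD is the plain sum
over bins, truncated to the study window (22,000–9,100 cal BP; dates are
pre-filtered by median calibrated age before binning). The 200-year
local mean smoother spans 201 points on the yearly grid and shrinks at
the window edges rather than padding, so no mass is invented. Yearly and
century-aggregated outputs are both provided (centuries keyed by half-up
rounding, matching the climate slices).

## CTU aggregation

Site records (one per date) are deduplicated within (site id, century),
keeping the first record by lab id for determinism. Raw technocomplex
labels are mapped to the six macro-units through an editable CSV shipped
with the package (Magdalenian incl. Cresswellian/Hamburgian;
Epigravettian incl. Romanellian/Bouverian; ABC = Azilian +
Federmessergroups; TPC = Ahrensburgian/Bromme/Swiderian; Mesolithic
incl. Beuronian/Maglemose/Sauveterrian/Microlaminar; BBT = Belloisian/
Laborian); unmapped labels are dropped with counts reported. "Central
tendency" is the arithmetic mean throughout, with the median available
behind a flag. BBT is carried through cleaning but excluded from the
analysis table (five analysis CTUs). Variables missing for a CTU are
NaN, never zero. The tracked species set is fixed to reindeer, boar,
red deer, elk, horse.

## Path models

Each path is a quasibinomial logistic regression fitted by IRLS with
unit prior weights: binomial variance, logit link, convergence when the
relative deviance change falls below 1e−8 (max 100 iterations).
Dispersion is `φ = Pearson χ²/(n−k)`; standard errors are `√φ` times the
binomial-model SEs; p-values are two-sided t on `n−k` df. This matches
R's `glm(..., family = quasibinomial)` and statsmodels
`GLM(Binomial).fit(scale="X2", use_t=True)`, both used as independent
cross-checks in the tests.

Standardization uses the latent-variable convention for logit models:
`std_beta = b · sd(x) / √(var(η) + π²/3)`, with SEs scaled by the same
factor — invariant to affine rescaling of predictors. Raw and
standardized coefficients are always reported side by side.

Design choices: predictors (climate, SPD, suitability-as-predictor) are
z-scored before fitting; the mean SPD is additionally min-max scaled to
(0, 1) where it serves as a quasibinomial *response* (a density has no
natural proportion scale); boundary proportions are squeezed by
`(y(n−1)+0.5)/n`, applied only when a boundary value is present. No
global d-separation/Fisher's-C statistic is computed — the pSEM is its
set of component fits. A warning is always emitted for fits on fewer
than 10 units: with five CTUs each path carries 2–3 residual df and the
aggregated-table fits should be read as descriptive; the calibration
experiment below is what validates the machinery.

## Synthetic worlds and what they do (not) show

All generators are pure functions of (config, seed) and store their
ground truth beside the data; the truth is never visible to the
inference code.

- **Reference fauna** (default n = 30): weights log-uniform on
  [5, 5000] kg; `e` ≈ 1300 kcal per kg at 100 kg with log-log slope
  0.95; full processing time `h` ≈ 35 h at 100 kg with slope 0.90 (so
  return rates sit in the few-thousand kcal/h range and depend only
  weakly on size); `c` and `p` linear in log weight with Gaussian noise,
  `p` clipped to [0.02, 0.95]. Noise sds (0.25/0.25/0.12/0.08) give the
  fitted p-value ordering e, h ≪ c < p, i.e. energy and handling are
  well predicted by weight, pursuit failure poorly.
- **Climate cube**: default 60×80 cells, 131 century slices
  (22.0→9.0 kya); latitudinal gradient (8 °C) + smooth seeded noise +
  linear warming (0.05 °C per slice, ~6.5 °C total); high ≥ mean ≥ low
  temperature everywhere by construction; precipitation log-normal. The
  spatial pattern is constant over time so the warming trend is the only
  temporal signal.
- **Occurrences**: cells drawn ∝ exp(w_true·f), points jittered within
  cells, background uniform (default 10,000).
- **Sites and dates**: site counts per CTU window ∝ a stated intensity;
  1–4 dates per site pushed through a toy monotone calibration curve
  (μ(θ) = θ + 150·sin(2πθ/5000), σ = 30 y) with 40–80 y errors. Real
  IntCal-format curve files are accepted wherever a curve is consumed.
- **Assemblages**: expected shares are a softmax over species of
  `a·log PERR + b·logit(suitability) − g·population·rank_penalty`;
  NISP is Dirichlet-multinomial around them. `g = 0` encodes the
  no-human-depression null; the rank penalty makes `g > 0` depress
  high-ranked species most. This share model is a synthetic-only
  stand-in for unknown foraging noise and is never used in inference.
- **Pseudo-CTU worlds** (for calibration): n = 200 units with
  climate → population, climate → suitability, and a Beta-noised
  zooarchaeological share around
  `expit(b0 + b_suit·z(logit suit) + g_pop·z(pop))` — binomial-type
  variance inflated by a constant, exactly the quasibinomial regime.

What passing tests show: the estimators are correct and calibrated
*under their own assumptions* (independent units, correctly specified
link, climate-only suitability). What they do not show: robustness to
spatial/temporal autocorrelation between sites, taphonomic loss,
research-intensity bias in the radiocarbon record, GBIF sampling bias,
or niche drift between modern and Pleistocene populations — none of
which the synthetic worlds emulate.

## Problem sizes and experiment designs

Chosen once as desk-scale study conditions: envelope recovery uses a
60×80 world, 2000 presences (75/25 split), 10,000 background points and
planted weights (3, 0, 0, 1, −2, 0, 0, 0) — strong enough that the
*true* surface is discriminable (held-out AUC of the truth ≈ 0.87);
diet-breadth validation uses 1000 random instances of ≤ 8 species; SPD
flatness uses 500 uniformly dated single-date sites, checked per interior
century against a 3σ binomial envelope (the envelope is conservative:
calibration spreads each date's mass across century boundaries);
path-model calibration uses 200 replicates of 200-unit worlds, with the
coverage band [0.90, 0.98] around the nominal 0.95 (±3 binomial sd plus
margin at 200 replicates; the same band used for the allometric CI
coverage check at 500 replicates).

## Known limitations

- The envelope model supports only linear+quadratic features; no hinge/
  product/threshold features, dispersal constraints or biotic
  interactions.
- Grids are plain arrays with explicit geometry and CSV round-trip; no
  GeoTIFF/NetCDF I/O and no CRS handling — inputs must already share the
  grid's coordinate system.
- SPD machinery offers no null-model fitting, permutation tests, marine
  reservoir or taphonomic corrections.
- With five aggregated CTUs the study-layout path models are honest
  about their df but cannot be internally validated at that n; all
  calibration claims are at the pseudo-unit scale.
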