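# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `mycorun`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Data model

The design is a 4 × 4 × 4 factorial over bagasse, wheat bran and beech
sawdust, each at 0 / 25 / 50 / 100 % of a 10 g aliquot (the three
percentages are independent fractions and do not sum to 100), observed at
eight running times (5–40 d in 5 d steps) with four replicates: 512
treatments, 2,048 running-length (RL) observations, and one running rate
(RR) per substrate-replicate (256 rows). The all-zero mixture is a no-growth
control: RL ≡ 0, and its RR is defined as 0 because "length / time" is
0/undefined there.

The packaged summary tables give, per substrate, the day on which the
statistically highest RL was recorded ("days-to-highest", one of 25/30/35/40)
and the mean RL and RR at that day. Dividing mean RL by days-to-highest
reproduces the printed mean RR within ±0.002 cm d⁻¹ for 63 of the 64
substrates; the one exception (B 50 / WB 25 / BS 50: 9.72/30 = 0.324 vs a
printed 0.320) is an internal inconsistency of the printed tables that we
preserve as printed. Significance letters are stored as annotations, never
parsed as numbers.

## Synthetic replicate-level data

Raw replicate-level data were never published, so the generator emulates
them from the summary tables. Per substrate, mean RL follows a linear ramp

    mean_rl(t) = plateau · min(t, plateau_day) / plateau_day,

the simplest curve consistent with a monotone rise to the reported plateau
at the reported day. Replicate noise is a single multiplicative factor
`max(0, 1 + δ/plateau)` with `δ ~ N(0, σ²)` drawn once per
substrate-replicate, so that (a) the value at the plateau day is
`plateau + δ` — an additive replicate SD of exactly σ — and (b) each
replicate's trajectory remains monotone in time. Default σ = 0.30 cm,
chosen to match the ±0.35 cm spread reported for the design's follow-up
validation culture; it is a free parameter of `SimConfig`, surfaced in every
config, never hard-coded downstream. Replicate rates are the replicate's RL
at the plateau day divided by that day (replicate rate SD ≈ σ/plateau_day ≈
0.008–0.012 cm d⁻¹). The random stream is a single `numpy` generator seeded
from `SimConfig.seed`, consumed in substrate-then-replicate order; a seed
fully determines the dataset.

What this generator does **not** emulate: sigmoidal or lagged growth shapes,
heteroscedastic or time-correlated measurement error beyond the shared
replicate factor, contamination/failed runs, and any real curvature of the
response surface between the coarse factor levels. Tests passing on these
data therefore validate the machinery (training, CV bookkeeping, GA search,
VSR accounting) and the qualitative structure of the analysis, not
field-data performance.

## Preprocessing

The response (RL or RR) is Box–Cox transformed, `((y + c)^λ − 1)/λ` with
offset c = 1 because the control contributes exact zeros; λ is estimated
once per dataset by profile maximum likelihood (Brent search) and reused for
every model fit on that dataset so that all methods see the same target.
Inputs are designed factor levels and are only min–max scaled to [−1, 1]
(where the tanh hidden layer is well conditioned), never power-transformed.
The forward/inverse transform uses `expm1`/`log1p` forms that stay accurate
as λ → 0; round trips are exact to 1e−9. Model predictions that leave the
image of the forward map (possible when extrapolating with λ ≠ 0) are
clipped to the boundary before inversion.

A PCA screen on the scaled input+output matrix flags rows whose whitened
score distance on the components covering ≥ 90 % of variance exceeds 3
robust SDs (median/MAD) of the score-distance distribution; on the bounded
designed data it flags nothing, and a planted gross outlier is caught.

## Surrogate network and training

One hidden tanh layer, linear output. The hidden width is the only
architectural hyperparameter and is chosen by the integer-coded GA
(range 1–25) with fitness −(pooled CV test RMSE); each distinct width is
evaluated once and cached, making the search an exhaustive sweep at the cost
of at most 25 CV evaluations. The width search uses a reduced plan (8 folds,
1 repeat); the chosen width is then re-evaluated under the full 8 × 10 plan.

Training: Xavier-uniform init, full-batch gradient descent with an
adaptive-moment (Adam-style) update on the MSE of the transformed response;
learning rate 0.02, up to 1,500 epochs, early stopping on a 15 % validation
split with patience 150 and best-weights restore. Early stopping is the only
regularizer; it is also what keeps the surrogate from developing large
spurious bumps between design grid points (see Limitations). Training is
deterministic given (seed, data, config), and models serialize to JSON with
bit-exact float round trips.

Metrics: R², RMSE, MAE, and MAPE (averaged over nonzero targets only, since
the control rows are exact zeros), always computed in original units; both
MAE and MAPE are reported because different summaries of the same analyses
conventionally print either.

## Cross-validation

8 folds × 10 repeats = 80 splits, assigned at the row (replicate) level to
mirror the source row counts; pooled train/test metrics come from
concatenated in-/out-of-fold predictions. Replicates of one substrate are
near-twins, so row-level folds are optimistically biased for generalization
to *unseen substrates*; `CVPlan(group_by_substrate=True)` keeps all rows of
a substrate in one fold for the pessimistic reading. The default mirrors the
original protocol and is the documented known bias. (A substrate-grouped
width search was also evaluated during development and rejected: with only
64 groups the grouped selection is unstable across seeds.)

## Linear baselines

All five comparators fit the Box–Cox-transformed response on the raw inputs
and are affine predictors; they are cross-validated under exactly the same
plan as the network. MLR and OLSR are the same least-squares estimator
reported under both conventional names. Stepwise is bidirectional partial-F
selection (enter 0.05, remove 0.10, ties to the lowest p then lowest index,
cycle-guarded). PCR standardizes features before extracting components
(raw levels span 0–100 while time spans 5–40; unstandardized 95 %-variance
truncation would discard the time axis) and defaults to the smallest
component count explaining ≥ 95 % of standardized feature variance. PLSR is
NIPALS with the component count chosen by deterministic 5-fold CV inside the
training data.

## Sensitivity (VSE / VSR)

For each input the surrogate is retrained from the same seed and width with
that input removed; the retrained model's whole-dataset RMSE is the VSE, and
VSR = VSE / full-model RMSE, min–max rescaled so the most important input
scores exactly 1 and the least exactly 0. Retraining-without-input is the
primary definition (a model in which the variable "is not available"); a
cheaper mean-ablation variant (input frozen at its mean, no retraining) is
available via `method="mean_ablate"` for comparison.

## Optimization

The real-coded GA maximizes the surrogate's original-units prediction over
the design box — components in [0, 100] %, time in [5, 40] d; extrapolation
outside the box is disallowed. The initial population is seeded with the
best-predicted design-grid compositions (time axis: each substrate's
days-to-highest), which with elitism guarantees the result is at least as
good as every grid point's prediction. Optimal times are reported both as
fractional days and in a days + hours rendering.

## GA engine

Population 50, 500 generations, crossover 0.85, mutation 0.01 — the four
canonical settings — with roulette-wheel parent selection on
min-shifted fitnesses (the shift makes RMSE-type objectives, maximized as
their negatives, nonnegative weights) and one elite individual, which makes
the best-so-far trace nondecreasing. Operator forms, unspecified in the
original protocol, are standard for continuous media optimization:
arithmetic crossover + clipped Gaussian mutation (σ = 10 % of the gene
range) for real genes; single-point crossover + uniform redraw for integer
genes. The fixed generation count is the sole stopping rule.

## Problem sizes in the shipped checks

The test suite and acceptance script run the full default design (2,048 /
256 rows, width range 1–25, 80-split CV) for the headline surrogate-vs-
baseline comparison, and scaled-down configurations (fewer repeats,
narrower width ranges, fewer generations) for structural and property
checks; each file states its sizes inline.

## Known limitations

* **Between-grid uncertainty.** With factor levels only at 0/25/50/100 %,
  the surrogate is unconstrained on wide interior regions; optima found
  there can exceed the largest observed mean. Early stopping bounds but does
  not eliminate this.
* **Near-tied rate optima.** The printed rate table carries statistically
  indistinguishable maxima in two distant corners of the design (high wheat
  bran with zero sawdust, and high bagasse + high bran with high sawdust:
  0.393 vs 0.385/0.384 cm d⁻¹, the same significance letter). With
  calibrated replicate noise (SE of a 4-replicate mean ≈ 0.006 cm d⁻¹) and
  surrogate smoothing, the GA optimum of the rate model alternates between
  these modes across simulation seeds rather than concentrating in one; any
  single run — including a wet-lab campaign — effectively samples one of
  them. The length-model conclusions (running time dominant, wheat bran the
  key component) are stable across seeds.
* **Row-level CV bias.** See Cross-validation; use the grouping switch for
  unseen-substrate generalization estimates.
* **No mechanistic growth model.** The ramp/plateau curve is a calibration
  device, not hyphal biology; do not interpret simulated trajectories
  biologically.
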