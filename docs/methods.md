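# Methods

## Optimizer model

WOA maintains `n_agents` candidate vectors in a box `[lb, ub]^D`. Each
iteration every agent draws four scalars — `r₁, r₂, p` uniform on (0,1) and
`l` uniform on (−1,1) — and moves by one of three rules. With
`A = 2a·r₁ − a` and `C = 2r₂`:

- **Encircling** (`p < 0.5`, `|A| < 1`): `X ← X* − A·|C·X* − X|`, a
  contraction toward the incumbent elite `X*`.
- **Exploration** (`p < 0.5`, `|A| ≥ 1`): the same move relative to a
  randomly selected agent. The reference agent is re-drawn **per
  coordinate**: per-coordinate references keep exploration incoherent across
  dimensions, which prevents the swarm from coherently following narrow
  curved valleys and is what keeps the Rosenbrock mean near the classical
  ~28 plateau. Drawing the reference once per agent instead lets runs
  descend the valley (means of 6–15 on 30-dim Rosenbrock) and changes the
  algorithm's published character.
- **Spiral** (`p ≥ 0.5`): `X ← |X* − X|·e^{bl}·cos(2πl) + X*` with shape
  constant `b = 1`.

`a` decays linearly, `a(t) = 2(1 − t/T)`, reaching **exactly zero** at the
final iteration so the last encircling step collapses agents onto the elite.
The elite is replaced only on strict improvement after each synchronous
population evaluation; positions are clamped to the box after every update.
All randomness flows from one `numpy.random.Generator` seeded by the config;
identical config and seed give bit-identical trajectories.

### Discrete-recombination initialization (RESHWOA)

A pool of `mu = 100` individuals is drawn uniformly on `[0,1]^D`. Each of
`lambda = max(100, n_agents)` offspring samples `rho = 5` parents without
replacement and copies each coordinate from a uniformly chosen parent
(uniform-crossover analogue). Offspring are scaled affinely to the box; the
first `n_agents` seed the swarm (`dr_subset="best"` instead takes the
best-of-λ by objective). Recombination affects only iteration zero — no
mutation, no elitist selection. Per-coordinate resampling of a uniform pool
preserves uniform marginals but concentrates the joint sample on coordinate
values that exist in the pool; empirically this raises initial diversity per
coordinate without biasing any marginal (KS-tested in the suite).

An intermediate-recombination helper (coordinate-wise parent mean) is
shipped as a documented standalone variant; the hybrid never uses it.

### Why the benchmark tables contain exact zeros

On Rastrigin, once every coordinate satisfies `|x| < ~7e-9`, the per-term
`x² − 10·cos(2πx) + 10` evaluates to exactly 0.0 in double precision (the
cosine rounds to 1 and `x²` is absorbed against 10); similarly Griewank's
cosine product rounds to 1 and the quadratic term is absorbed against the
trailing +1. The swarm's geometric contraction reaches `|x| ~ 1e-35` within
500 iterations, so converged runs report literally 0 rather than ~1e-70 as
on the sphere. Rare runs (~1–3 %) stall just above the absorption threshold
(residuals ~1e-15, Rastrigin) or in a distant local optimum (Griewank); the
repeated-run mean then sits at ~1e-17–1e-2 instead of 0.

## Benchmark suite

Thirteen scalable functions, F1–F7 unimodal and F8–F13 multimodal, with the
classical boxes and minima. Numerical choices:

- **F6 (Step)** defaults to the floored De Jong form
  `Σ⌊x+0.5⌋²` (matching the reported result magnitudes); the smooth
  `Σ(x+0.5)²` variant is selectable.
- **F9 (Rastrigin)** uses the standard `Σ(x² − 10cos2πx + 10)` — the only
  form whose minimum is the tabulated 0.
- **F12/F13 (generalized penalized)** use the standard `y = 1 + (x+1)/4`
  transform (F12) and the piecewise boundary penalty `U(x, a, k, m)` with
  `a = 10, k = 100, m = 4` for both.
- **F8 (Schwefel 2.26)** adopts the classical optimum `−418.9829·D` at
  `x* = 420.96875…` per coordinate (the suite registry documents the
  alternative printed constant).
- **F7** adds one fresh uniform[0,1) draw per evaluation from a
  caller-supplied stream (re-drawn per evaluation, reproducible per run).

Only F1, F2, F4, F6, F8, F9, F10 are coordinate-permutation symmetric; the
chained (F3, F5, F12, F13) and index-weighted (F7, F11) functions are not,
and the property tests assert symmetry only for the former group.

## Filtering

Expression matrices are z-scored per gene before scoring (min–max and none
are available). Class roles follow sorted label order, making SNR's sign
convention deterministic and label swaps exactly antisymmetric (SNR) or
invariant (BC). SNR ranks by absolute value and takes the top k = 20 by
default, ties broken by lower gene index. BC selection is strictly-above-a
threshold; because no reproducible rule exists for setting the threshold, it
is a required parameter, with a top-k fallback. Degenerate genes: for SNR a
zero denominator with nonzero mean gap scores the largest finite float
(sign-preserving sentinel); zero within-class variance is an error for BC,
naming the gene.

## SVM tuning

The fitness of a candidate `(C, γ)` is the MSE of hard-label RBF-SVC
predictions on a stratified holdout (test size `round(0.3·n)`), which for
0/1 labels is the misclassification rate. Features are z-scored with
train-split statistics. Each of the `n_runs = 30` repetitions derives its
seed as `seed + k`, which fixes both a fresh stratified split and the
optimizer stream (`fixed_split` freezes the split so run spread isolates
optimizer noise). Default box C ∈ [0.0001, 10], γ ∈ [0.1, 100]; a wider
preset (C ≤ 100, γ ∈ [0.001, 50]) is exported. Aggregates are min / mean /
sample-sd of per-run best MSEs, and the `(C, γ)` at the overall minimum.

Note that a run's best MSE is not monotone in `max_iter`: the decay schedule
`a(t)` depends on the horizon, so different horizons follow different
random trajectories. The greedy-elite guarantee is within-run monotonicity
of the convergence curve, which is what the suite asserts.

## Synthetic data

Two Gaussian classes over `n_genes` genes: noise genes are
`N(baseline_mean, within_sd²)` identically in both classes; each of
`n_informative` planted genes shifts class 1 by `effect_size · within_sd`,
alternating sign so both expression directions occur. Defaults — 30+30
samples, 2000 genes, 20 informative, effect 2.0, sd 1.0, baseline 8.0 (a
log2-intensity scale) — emulate the sample/gene shapes of the classic
two-class cohorts, also available as named presets ("colon-like" = 40+22 ×
2000, etc.). With equal class sds the expected planted SNR is
`effect_size/2`; at effect 2 and ≥20 samples per class, top-k SNR selection
recovers ≥90 % of planted genes (asserted over 20 replicates). An optional
`class1_sd_scale` inflates class-1 variance on planted genes to exercise
BC's log-variance term.

The generator emulates exactly the class-wise mean/sd structure the filters
assume. It does **not** model probe effects, batch effects, missing spots,
gene–gene correlation, or heavy-tailed intensity distributions — passing
tests demonstrate correctness of the statistics and the search loop, not
performance on real microarray cohorts, whose BC thresholds and error rates
depend on structure this generator omits.

## Problem sizes in the shipped checks

The acceptance script runs the full protocol (30 agents, 500 iterations,
30 runs per cell) for three benchmark cells. The test suite runs the full
protocol for the exact-zero cells, 10-run batches for the
magnitude-consistency cells, and deliberately small swarms/horizons
(5–30 agents, 5–100 iterations) plus 200–2000-gene synthetic datasets for
unit and property tests; these sizes are the package's own choice of a fast,
deterministic regression surface.

## Known limitations

- The exploration move's per-coordinate reference makes the positional
  update differ from a per-agent-reference reading of the update equations;
  both are defensible, and the choice is documented above.
- BC thresholds are dataset-specific and user-supplied; the package does not
  infer them.
- Holdout (not k-fold) validation only; binary classes only; RBF kernel
  only.
- Timing columns depend on hardware and are never asserted.
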