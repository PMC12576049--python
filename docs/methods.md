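# Methods

## Data model

Right-censored data are triplets `(x_i, t_i, δ_i)`; `δ_i = 1` marks an
observed event, `0` a censoring. When events and censorings tie at the
same time, events are counted first in the risk set (the usual
Kaplan–Meier convention). Survival curves and cumulative hazard functions
(CHFs) are right-continuous step functions; evaluation at `t` returns the
value at the largest knot ≤ t, and before the first knot the kind-specific
initial value (1 for survival, 0 for CHF). Conversions use
`Λ = −ln max(S, 10⁻¹²)`; the floor keeps logs finite where a curve reaches
zero, and the round trip is exact above it.

The model contract is a single method, `predict_survival(rows, grid)`,
returning probabilities clipped to [0, 1] and forced non-increasing along
the grid (`np.minimum.accumulate`) so that tiny numerical wobbles in
wrapped estimators cannot violate the survival-curve shape that
downstream code (e.g. RMST) relies on. CHFs default to `−ln S`; adapters
may supply an exact `predict_chf`. The shipped adapters wrap
scikit-survival's Cox (Breslow baseline; ridge 10⁻⁴ for stability with
one-hot categoricals) and random survival forest. The forest coarsens
training times onto ≤ 250 quantile bins before fitting (each time snapped
up to its bin edge, so no event moves later): per-tree risk tables scale
with the number of unique times, and this bounds prediction cost with a
negligible effect on the fitted curves. Forest defaults (100 trees,
min_samples_leaf = 50, √p features per split) favour smooth, stable
curves over micro-resolution — explanation methods average predictions
heavily and benefit from a regularized base learner.

Default time grids are the ordered unique observed event times, thinned to
at most 50 quantile-spaced points; effect/interaction computations use
25–50 points, which is visually and numerically indistinguishable from the
full grid for step curves while keeping prediction matrices small.

## Synthetic cohorts

All three generators draw event times by inverse-transform sampling on
the cumulative hazard: `T` solves `Λ(T | x) = −ln U`. The covariate part
factorizes as `Λ(t|x) = e^{η(x)} A_g(t)`, so only one or two base curves
`A_g` are needed; they are tabulated by trapezoidal integration on a
40 001-point grid over fifty follow-up horizons and inverted by monotone
interpolation (sampler correctness is verified by a
probability-integral-transform test at n = 30 000). Event times beyond
the tabulated horizon are clamped there; the horizon is long enough that
the clamped mass is negligible even for low-hazard covariate
combinations, and under administrative censoring at follow-up it is
unobservable anyway. Random censoring is
exponential, applied before administrative censoring at the follow-up
horizon; the default rates yield roughly 15–20 % randomly censored
subjects. Roughly 40 % of follow-up elapses before the median baseline
event.

Design parameters (chosen once, to reproduce the qualitative behaviour
each design exists to demonstrate):

* **td_treatment** (5-year horizon, Weibull shape 1.5): log hazard
  `−0.8·trt + 0·x1 − 0.25·x2 + 1.2·t·trt`. The treatment is protective
  early and harmful late; the true arm-wise survival curves cross at
  ≈ 1.1 years. The late harm is strong enough that the treatment remains
  the dominant predictor even for a proportional-hazards fit — with a
  milder reversal the two phases cancel in the partial likelihood and the
  Cox model sees a null treatment, which contradicts the behaviour the
  design is meant to show in importance rankings.
* **correlated** (5-year horizon, Weibull shape 1.5): `(x1, x2)` bivariate
  standard normal with ρ = 0.99 and log-hazard coefficients (−1, +1).
  Only the difference `x2 − x1` (sd ≈ 0.14) carries signal. The very high
  correlation is deliberate: at ρ = 0.9 a forest still reconstructs the
  bivariate structure through sequential splits and its PDP retains a
  0.3–0.5 spread, which defeats the attenuation phenomenon the design
  demonstrates; at ρ = 0.99 the PDP flattens below 0.2 while ALE still
  recovers both signs.
* **interaction** (20-month horizon, exponential baseline): log hazard
  `−0.3(x1+x2+x3) + 1.0·x1·x2` on independent standard normals. The
  product term dominates the main effects, so the two-way H² for (x1, x2)
  is large at every horizon and (x1, x3) is a pure estimation-noise
  ceiling.

What the generators deliberately do not emulate: informative or
covariate-dependent censoring, left truncation, competing risks,
time-varying covariates, non-Gaussian feature marginals, measurement
error. Tests passing on these cohorts show the estimators implement their
definitions and recover known structure — not that any real data set is
as well-behaved.

## Metrics

The Brier score uses Graf's IPCW decomposition with the censoring
survival `Ĝ` estimated by Kaplan–Meier on flipped event indicators from
the *training* data (the censoring mechanism is a property of the study,
best estimated where the model was built). `Ĝ(t⁻)` is the left limit,
implemented as evaluation at `nextafter(t, 0)`. A zero `Ĝ` at a needed
time raises an error naming the time rather than producing an unbounded
weight. Per-subject contributions are retained; the CPI t-tests consume
their time averages. Integrated scores are time-normalized trapezoids, so
a constant curve integrates to itself. Concordance and time-dependent AUC
are not implemented: the importance machinery only requires a
time-dependent loss, and the loss interface (`LossFn`) is pluggable.

## Feature effects

ICE/PDP grids: quantile strategy with g = 25 for numeric features
(preserves the marginal), observed levels for binary/categorical. The
default centering reference is the minimum observed value. Centering is
exact by construction (the reference column is subtracted), and
`pdp ≡ mean(ice)` holds to machine precision because the PDP is literally
the mean of the ICE array.

ALE uses quantile interval bounds with the lowest bound nudged just below
the minimum so every observation falls in a left-open interval; duplicate
quantile edges are collapsed (merging empty bins rightward and reducing
g, which is visible in the returned grid). Centering subtracts the
observation-weighted mean of the accumulated curve evaluated at each
observation's interval upper edge. M-plot neighborhoods default to the
⌈n/g⌉ nearest observations by feature value (ties by row order); a fixed
half-width can be given instead, and empty neighborhoods yield NaN, never
an extrapolated number.

Categorical levels are ordered for ALE by embedding the matrix of
between-level distances (two-sample Kolmogorov–Smirnov per numeric
column, total variation of frequency tables per categorical column,
summed) with classical MDS to one dimension; orientation is fixed by
mapping the first level in data order to the non-positive side, making
the order deterministic up to that convention.

## Interactions

H² statistics evaluate all partial-dependence functions at the observed
feature values of a seeded subsample (default min(n, 300) rows — the
double sums are O(m²) model evaluations) and mean-center each function
per timepoint before forming numerator and denominator; "normalization"
beyond centering is supplied by the ratio itself. Timepoints with a zero
denominator are reported as missing and excluded from the time marginal,
never coerced to 0 or 1. Values can exceed 1 when the interaction
variance exceeds the joint-PD variance; they are reported raw, with no
significance threshold attached.

## Importance

PFI defaults to 10 seeded permutations, reported as the mean difference
curve with per-repeat values retained; an exhaustive mode enumerates all
n! permutations for tiny n (used by tests as an oracle). CPI replaces
numeric columns with second-order Gaussian knockoffs (equicorrelated
construction on the correlation scale, `s = min(1, 2λ_min)`;
near-singular correlation matrices are ridge-regularized with a warning).
Binary/categorical columns are conditionally resampled from a seeded
random-forest classifier fitted on the remaining columns — Gaussian
knockoffs do not apply to discrete marginals. Inference is a one-sided
paired t-test on per-subject time-averaged loss differences (CPI), or a
Wilcoxon signed-rank alternative for LOCO; p-values are Holm-adjusted
across features. LOCO refits through the adapter's `refit` with
hyperparameters unchanged. For PFI and CPI the "reduced" loss entering
the difference is the permuted/knockoff loss; only LOCO actually refits.

## Local explanations

**SurvLIME.** The neighborhood is g Gaussian perturbations of the
explained point (scale 0.1 × per-feature training sd; the point itself is
included), weighted by the Epanechnikov kernel `w = 1 − d²/r` on
standardized distances with r = 0.5, clipped at zero. Both the scale and
r are exposed as arguments — the neighborhood definition is the method's
softest spot and results should be checked across settings. The surrogate
is solved in closed form as weighted least squares on
`ln Λ(t|x_k) = b₀ + ln Λ₀(t) + bᵀx_k` with per-(point, time) weights
`w_k · Λ(t|x_k)`; the baseline Λ₀ defaults to the training Nelson–Aalen
curve. Two numerical guards matter: timepoints where a predicted survival
saturates at the 10⁻¹² floor get zero weight (their CHF is capped, and
the Λ-proportional weights would otherwise concentrate exactly there),
and the intercept b₀ absorbs any offset between the black box and the
supplied baseline (without it, a featureless black box would be assigned
nonzero coefficients purely to soak up the baseline mismatch).
Categorical features are one-hot expanded before perturbation and each
perturbed block is snapped back to a valid single level by argmax.

**SurvSHAP(t).** The value function substitutes background-row values for
out-of-coalition features and averages (marginal/interventional
estimation — a deliberate approximation of the conditional expectation in
the Shapley definition; under correlated features it evaluates the model
off-manifold, like the PDP). Default background: up to 100 seeded
training rows. The permutation estimator averages marginal contributions
over sampled orderings and is exact under full enumeration; the kernel
estimator solves one Shapley-kernel-weighted regression per timepoint
with a shared coalition design, enforcing per-time local accuracy exactly
by eliminating one feature. Both exact modes agree to ≤ 10⁻⁸.

**Counterfactuals.** `E(·)` is the RMST truncated at the last grid time —
an unrestricted mean is undefined under censoring. The optimizer is a
seeded particle swarm (50 particles, 200 iterations, inertia 0.7,
cognitive/social 1.5) with the explained point seeded into the swarm, so
the best-so-far loss starts at the trivial solution and is non-increasing
by elitism; `converged` reports whether the final quarter of iterations
still improved. Numeric features only; the hinge-plus-distance objective
has no natural treatment of categorical moves.

## Experiments and seeds

`run_experiment` validates explainer names and adapter capabilities (e.g.
LOCO needs `refit`) before any compute, splits 70/30 stratified by event
indicator, and derives one child seed per stochastic stage from the
experiment seed via `numpy.random.SeedSequence.spawn`, so no global
random state exists and re-running a config reproduces artifacts
bit-for-bit. The acceptance script runs each design at n = 3000 (the
cohorts' native size) with 25–50-point time grids and the default H²
subsample of 300 rows; these sizes were chosen as the smallest at which
the measured quantities are stable across seeds.

## Known limitations

* Single-feature effects only (|A| = 1); no second-order ALE or
  two-feature PDP surfaces.
* The H² subsample (m = 300) makes per-time curves noticeably noisy;
  the time marginal is the stable summary.
* SurvSHAP's marginal value function and the PDP share the off-manifold
  extrapolation caveat under correlated features.
* SurvLIME inherits LIME's dependence on the neighborhood distribution;
  coefficients should be read as local, scale-dependent summaries.
* No support for left truncation, interval censoring, competing risks or
  time-varying covariates.
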