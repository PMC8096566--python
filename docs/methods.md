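# Methods

## Problem and model

A fixed-bed adsorption column saturates over time: the outlet-to-inlet
concentration ratio C/C₀ rises sigmoidally from ~0 to ~1 (the breakthrough
curve).  Rather than solving the liquid/solid mass-balance PDEs, the package
regresses C/C₀ on the four operating variables (C₀, H₀, U, t) with a
least-squares support vector machine.

LSSVM replaces the ε-insensitive loss and inequality constraints of the
classical SVM with equality constraints and a squared-error penalty, so
training is a single symmetric (N+1)×(N+1) linear solve rather than a
quadratic program.  The publication-standard formulation stops at the KKT
stationarity conditions; the bordered system implemented here
([[0, 1ᵀ], [1, K + I/γ]]·[b; a] = [0; y]) is their unique linear consequence
(the Suykens form).  The solver is a dense symmetric direct factorization
with a least-squares fallback when the estimated condition number exceeds
10¹²; at a few hundred training points iterative methods would gain nothing.

The RBF kernel is K(x, x′) = exp(−‖x − x′‖²/σ²), deliberately without the
factor-2 convention in the denominator: σ² is a free hyperparameter tuned
jointly with γ, so the convention only relabels the axis.

## Normalization and splitting

Features are mapped to [−1, 1] by D_N = 2(D − D_min)/(D_max − D_min) − 1.
Defaults: the normalizer is fitted on the **training** partition only (no
test-set leakage), and only the inputs are normalized — C/C₀ already lives in
[0, 1].  Both choices are switchable (`normalize_fit_on="all"`,
`normalize_target=True`) because published column studies often normalize
everything on the full table.  The 75/25 train/test split is uniformly random
with a mandatory seed (default 42); a `sequential` mode exists for
sensitivity checks.  Units are carried as opaque labels; after normalization
every computation is unit-agnostic.

## Hyperparameter search

PSO runs on (log₁₀γ, log₁₀σ²) over the box log₁₀γ ∈ [−2, 8],
log₁₀σ² ∈ [−3, 3]: useful γ values span many decades and the box brackets
everything a breakthrough-scale problem can need.  Velocity update uses
inertia w = 0.7298 and cognitive/social weights c₁ = c₂ = 1.49618
(Clerc–Kennedy constriction equivalents); velocities are clamped to 20% of
each dimension's range and positions are clamped to the box with the
velocity zeroed at the boundary.  The objective is the LSSVM mean squared
error on an inner validation fold (20% of the training partition, fixed
seed).  A pure training-error objective is degenerate — it is monotone
improving in γ, driving the search to the box edge — which is why
`objective_mode="train"` exists only as an explicit option.  A solver failure
on a candidate scores a large penalty (10¹²) instead of raising, so one bad
particle cannot kill a run.

The default pipeline budget is swarm 30 × 100 iterations.  The validation-MSE
surface in (log₁₀γ, log₁₀σ²) is smooth with a broad, near-flat optimum, so
this reduced budget reaches the same plateau as a much larger swarm; the test
suite additionally verifies PSO never underperforms a 10×10 log-grid over the
same box.  Exact published (γ, σ²) pairs are not a recovery target: with a
near-flat optimum in γ, many (γ, σ²) pairs are statistically equivalent.

## Validation statistics

R² = 1 − SS_res/SS_tot with SS_tot about the observed mean; MAE with absolute
values; %AAD = 100·MAE (C/C₀ is already dimensionless); MSE = RMSE².  STD is
the standard deviation of the residuals about their own mean.  A printed
variant of STD circulating in this literature uses the deviation of the
*predictions* about the observed mean — that measures prediction spread, not
error spread, and is inconsistent with error-table magnitudes of ~0.01; it is
available behind `std_as_printed=True` for comparison but is not the default.

## Applicability domain (leverage / Williams plot)

Hat matrix H = X(XᵀX)⁻¹Xᵀ on the normalized 4-column input matrix over all
evaluated points, with a pseudo-inverse fallback on rank deficiency.  No
intercept column is added by default, so the parameter count in the warning
leverage H* = 3(f+1)/p is f = 4 (an intercept variant is a one-line `f=5`
argument).  Standardized residuals are R_i = e_i/(s√(1 − h_ii)) with s the
residual RMS; plain (not leave-one-out) residuals are used — the
"cross-validated" qualifier attached to this quantity in the source
literature is never operationalized there.  A point is in-domain iff
|R_i| ≤ 3 and 0 < h_ii < H*; every point receives exactly one of
{in_domain, high_leverage, outlier_residual, both}.

## Frozen GMDH comparator

The comparator is a published, fully printed three-layer network of
two-input quadratic nodes (4 → 3 → 2 → 1) for the same breakthrough problem.
Only evaluation is implemented; GMDH self-organization is out of scope.
Coefficients are transcribed digit-for-digit, including two oddities kept
as printed rather than "corrected": the output node nearly duplicates
layer-3 node 1 but flips the cross-term sign (−1.972 vs +1.972) and rounds
1.248 to 1.24, and one layer-1 node suffered a typesetting loss of a term
separator (resolved as the only reading consistent with the printed constant
terms).  Because the publication never maps x₁…x₄ to physical variables or
states the input scaling, `reproduction_search` evaluates all 24 column
permutations × {normalized, raw} scaling × both output-node variants and
ranks them by %AAD.  The original 204-point laboratory table is available
only on request from its authors and is not redistributed here, so the
search documents the reproduction attempt on whatever table the user
supplies; on synthetic data the comparator is expectedly poor (it was fitted
to the real resin data), and its statistics are reported as computed, not
calibrated.  The ANN column that usually accompanies such comparisons cannot
be reproduced at all (its weights were never published) and is carried as a
clearly labelled literature value.

## Synthetic generator

`SyntheticConfig` emulates what the analysis assumes about real columns:
within each operating condition, C/C₀ is a monotone sigmoidal front.  The
front is logistic, C/C₀(t) = 1/(1 + e^(−k(t − t₅₀))) with
t₅₀ = a·H₀/(U·C₀^β) — midpoint later for taller beds, earlier for faster
flow and (β > 0) higher feed concentration.  A logistic was chosen over
Thomas/Yoon–Nelson forms for closed-form clarity; the package models no
adsorption physics, so any monotone sigmoid serves.  Defaults, fixed once:
a = 700, β = 0.5, k = 0.05 min⁻¹, condition grid C₀ ∈ {8, 24} mg/L ×
H₀ ∈ {7, 11} cm × U ∈ {80, 160, 240}, time grid 0–120 min × 17 points (so
the fronts' midpoints fall inside the grid and the 12 × 17 = 204 records
match the scale of a real column study), additive Gaussian noise
σ = 0.01 on C/C₀ truncated to [0, 1].

What passing on synthetic data does and does not show: the generator
produces noisy but exactly logistic, homoscedastic, gridded data.  Real
breakthrough tables have condition-dependent front shapes, heteroscedastic
and possibly autocorrelated measurement error, and irregular sampling —
success here demonstrates that the pipeline can learn a clean sigmoidal
response surface and recover the injected noise floor, not that it matches
any particular laboratory system.

## Numerical choices and degenerate inputs

- Ratios above 1.05 are rejected at load (small experimental overshoot above
  1 is tolerated); negative predictors and missing cells are row-indexed
  errors.
- Constant (zero-range) feature columns make min–max normalization undefined
  and are rejected by name.
- Values outside the fitted normalization range map outside [−1, 1] without
  clipping, with a logged warning (extrapolation is visible, not hidden).
- An N = 1 training set yields the constant model (a₁ = 0, b = y₁), the
  exact solution of the KKT system.
- h_ii = 1 (exact leverage point) makes the standardized residual undefined
  and raises.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical configs are bitwise-reproducible.

## Known limitations

- No mechanistic mass-balance simulation; predictions outside the sampled
  operating envelope are extrapolations of a kernel smoother and are only
  flagged, not corrected.
- LSSVM is dense: every training point is a support vector, so prediction
  cost grows linearly in the training size (irrelevant at N ≈ 200).
- The PSO objective's inner validation fold makes tuned hyperparameters
  depend (weakly) on the fold seed; the final accuracy plateau does not.
- The GMDH reproduction search can rank conventions but cannot certify the
  original convention without the original table.
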