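# Methods

## Model and assumptions

The classifier is a stacked generalization over three base learners of
deliberately different inductive biases — bagged trees (random forest),
boosted trees, and a sparse multinomial linear model — combined by a
multinomial logistic meta-learner. The stack assumes (a) class membership
is governed by the covariates alone (potential, not actual, vegetation:
no temporal dynamics, no disturbance, no CO₂-fertilization feedback), and
(b) training points are spatially autocorrelated, which is countered at
evaluation time by blocking rather than modelled.

Meta-features are the concatenated per-learner class-probability vectors
(3K columns), not hard votes: probabilities preserve calibration
information that a vote would destroy. The meta-learner carries a small
L2 ridge (C = 100 in scikit-learn's parameterization) because perfectly
separable stacked features otherwise drive the multinomial deviance
optimum to infinity; with informative base learners the ridge is far too
weak to influence the fitted map.

## Tuned hyperparameters (package defaults)

| learner | parameter | default |
|---|---|---|
| random forest | trees | 452 |
| | min node size | 9 |
| | mtry (capped at the feature count) | 10 |
| gradient-boosted trees | boosting rounds | 20 |
| | max depth | 5 |
| | learning rate | 0.5 |
| | min loss reduction (gamma) | 10 |
| | row subsample / column subsample | 1 / 0.5 |
| lasso GLM | λ (per-observation L1 penalty) | 1.1 × 10⁻⁵ |

Everything not listed stays at the underlying library's defaults. The
lasso λ follows the glmnet convention (penalty per observation); it is
mapped to scikit-learn's `C` as `C = 1/(n·λ)` at fit time, so the
effective penalty is independent of partition size. Features are
standardized inside the GLM pipeline (glmnet's default behaviour); trees
see raw covariates.

## Spatial blocking

The blocking grid lives in a world sinusoidal equal-area projection on
the authalic sphere (R = 6371.0072 km), origin 0°E/0°N; block indices are
`floor(x/s), floor(y/s)` with s = 100 km. Sinusoidal was chosen because a
metric blocking grid needs near-equal block areas at all latitudes and
the projection is a two-line formula (x = R·λ·cos φ, y = R·φ) with no
external projection machinery. Blocks are dealt round-robin into k folds
after a seeded permutation, with no class stratification; a rare class
may therefore be absent from a training partition, in which case its
probability column is an explicit zero (renormalized) rather than a
dropped class — matrix shapes stay global.

## Evaluation conventions

- Logloss uses natural log (nats per observation), probabilities clipped
  to [1e-15, 1 − 1e-15].
- The R²_logloss baseline is the class-prevalence constant predictor of
  the *training partition* that produced each point's prediction; the
  per-class variant uses one-vs-rest binary logloss with the class's
  training prevalence as baseline. Both definitions are this package's
  reconstruction of the skill-score construction — the standard
  `1 − LL/LL_baseline` form — and are fixed here as the package
  definition.
- The baseline's logloss is clipped from below only, so a degenerate
  single-class truth yields baseline logloss exactly 0 and raises rather
  than returning an arbitrary ratio.
- The meta-learner is evaluated out-of-fold by nested application: for
  each outer fold, base learners generate an inner OOF matrix on the
  remaining k−1 folds, the meta-learner trains on that matrix only, and
  the refitted base learners + meta predict the held-out fold. Reported
  CV numbers therefore contain no stacking leakage.
- A class never predicted gets precision treated as 0, hence F1 = 0.

## Map products

Probabilities are stored and reported in percent (0–100, pixel sums
exactly 100); internal model math stays in [0, 1] with a single
conversion at the prediction boundary. Hard classes are the per-pixel
argmax with ties broken to the lowest legend index (ties are measure-zero
for continuous probabilities; the convention only matters for constructed
inputs). The margin of victory is the first minus second highest class
probability in percentage points. Legend aggregation sums mapped source
probabilities; because the translation scheme is a total function onto
six targets, mass is conserved exactly and no renormalization occurs.

## Transitions and areas

Pixel areas are computed analytically per latitude band with the
spherical-zone formula `R²·Δλ·(sin φ_top − sin φ_bottom)` on the authalic
sphere, instead of reprojecting rasters to an equal-area projection: the
area totals are identical by construction and the computation introduces
no resampling artifacts. The MoV confidence filter is inclusive (≥) and
by default applies to *both* epochs' maps — the most conservative choice;
`filter_mode` exposes current-only and future-only variants because the
alternative conventions are defensible. Raising the threshold can only
shrink every transition-table cell (monotonicity is tested). Scenario
agreement counts confident changes after filtering.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the method's
guarantees depend on:

- covariate fields are white noise convolved with an isotropic Gaussian
  kernel of scale `corr_length − 1` cells (so `corr_length = 1` is the
  identity), standardized and affinely placed on °C/mm/m-like scales;
  temperature-kind layers add a monotone latitudinal gradient, and
  precipitation-kind layers are log-normal (positive, right-skewed);
- labels come from a recorded rule: classes are carved off by nested
  quantile thresholds alternating between two latent layers, with target
  prevalences ∝ skew⁻ⁱ — threshold placement makes the imbalance exact
  and deterministic rather than relying on rejection sampling;
- observations are clustered two-stage samples (uniform cluster centres,
  Gaussian scatter) with uniform label-flip noise;
- future scenarios shift temperature layers additively and scale
  precipitation layers multiplicatively, leaving terrain and mask alone.

It does **not** emulate real climatologies' marginal distributions,
cross-covariate correlation structure, pseudo-observation infill of
under-sampled regions, or non-stationary label rules. Passing tests
therefore demonstrate that the pipeline recovers a covariate-driven
signal under spatial blocking, heavy imbalance and label noise — not that
any particular real-world accuracy is attainable.

## Standard study conditions

The standard fixture used by the test suite and the acceptance script:
128×128 grid of 0.25° cells centred near the equator, 8 covariates
(4 temperature, 3 precipitation, 1 terrain; `corr_length` 6 cells, a
mesoscale-like autocorrelation), K = 6 classes with prevalence skew 3
(most/least prevalent ratio ≈ 250, matching the two-orders-of-magnitude
imbalance typical of pollen compilations), 2,500 points in 60 clusters
(scatter SD 3 cells), 10 % label noise, fivefold spatial CV repeated five
times. These sizes keep a full repeated-CV evaluation within minutes on
one core while leaving several hundred distinct 100-km blocks for the
fold permutation.

## Numerical choices and degenerate inputs

- All generators and fits are pure functions of their arguments including
  seeds; fold permutations derive from `SeedSequence([seed,
  repeat_index])`.
- Probability-cube validation tolerates 1e-4 percent of float drift in
  pixel sums; the prediction path itself stays within ~1e-12.
- A training partition reduced to a single class raises, naming the fold;
  non-finite features raise before any fitting.
- A constant stacked feature (e.g. a base learner that always emits the
  same vector) warns but still fits.
- Grid latitude extent is validated against [−90, 90]; block assignment
  validates coordinates against [−180, 180]×[−90, 90].

## Known limitations

- The GLM base learner uses saga coordinate descent; with the tiny default
  λ on near-separable data it is the slowest component and its coefficient
  ranking (used in consensus importance) is computed on standardized
  features.
- `consensus_importance` can legitimately return an empty list when the
  learners disagree at small top-k.
- Transition accounting assumes co-registered grids; no resampling is
  provided.
- The pipeline writes single-band ASCII grid rasters (plain text,
  GDAL-readable); multi-band container formats are out of scope.
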