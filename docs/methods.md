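# Methods notes

## The B-score model

The B-score treats OA structural progression as motion along a single line
in shape space. Shapes are corresponded point sets in mm; the OA vector is
the line through the mean shape of a non-OA reference group and the mean
shape of an OA group, and a knee's score is its orthogonal projection onto
that line, origin at the non-OA mean, unit = one sample SD (n−1) of the
non-OA group's own projections, positive toward the OA mean.

Assumptions worth stating explicitly:

- **Linearity.** OA change is modelled as one direction; curvature of the
  true progression manifold, and any shape change orthogonal to the line,
  are invisible to the score.
- **Group definitions drive the vector.** The reference implementation of
  group selection takes knees with KLG 0 (non-OA) and KLG ≥ 2 (OA);
  `select_groups_by_klg` applies the stricter longitudinal form (grade 0
  at every visit vs ≥ 2 at every visit) when serial readings exist.
  `build_oa_vector` itself accepts any two labelled groups.
- **Per-sex models.** Origin, direction and SD unit are all computed per
  sex by default. Only the origin is unambiguously sex-specific in the
  method's usual statement; a pooled-direction variant
  (`BScoreModel(pooled_direction=True)`) keeps per-sex origins and SD
  units but shares one direction, for users who prefer the other reading.
  Sigma is always computed from the same non-OA sample that defines the
  means; with the n−1 SD the defining sample has score SD exactly 1.
- **Projection space.** Projection is done in the full flattened
  coordinate space. When the OA vector lies in the span of a PCA shape
  model (it always lies in the span of the training data), projecting
  PCA-reduced coordinates gives the same score; full-space projection is
  exact and avoids choosing a mode count. PCA (`ShapePCA`) is retained for
  synthesis and compression.

## Alignment

`GeneralizedProcrustes` iteratively superposes every shape onto the
evolving mean (SVD/Kabsch least squares, proper rotations only),
re-centres the mean at the origin each pass, and stops when the mean moves
by < `tol` (Frobenius, default 1e-8 mm) or after `max_iter` = 100 passes.
The initial reference is the centred cohort mean — this makes the
procedure a fixed point on already-aligned input — falling back to the
first shape if that mean degenerates (e.g. antipodal orientations).
Scaling is **off** by default: OA involves genuine widening/flattening of
the articular surfaces, which similarity alignment would absorb into the
scale factor. A `scaling=True` flag enables similarity alignment for
experimentation. Left knees are mirrored about x = 0 and re-indexed by a
configurable left↔right correspondence map (identity for the synthetic
template, which is built with symmetric correspondence).

## Repeatability

`bland_altman_sdd` computes the mean (bias) and n−1 SD of paired score
differences; the smallest detectable difference is the 95%
limit-of-agreement half-width 1.96·SD(d). The multiplier is the
conventional normal 1.96, not a t-quantile (configurable). Bias is
reported alongside the half-width rather than assumed zero.
`distinguishable_grades` rounds range/SDD to the nearest integer (ties
away from zero): a 10-unit range at SDD 0.251 gives 39.84 → 40 grades.
Under i.i.d. per-measurement Gaussian error σₑ the SDD converges to
1.96·√2·σₑ, the closed form used as the simulation oracle.

## Outcomes and risk models

Outcome thresholds default to NRS pain ≥ 4 (moderate) / ≥ 8 (severe),
WOMAC function ≥ 20 / ≥ 35, WOMAC pain ≥ 4 / ≥ 8; every threshold is
overridable for sensitivity analysis (e.g. severe pain at 7/8/9, severe
function at 32/34/36 — sources differ on 35 vs 36 for severe function;
35 is the default here). "Current" = baseline exceedance; "future" =
median of all post-baseline timepoints (even count → mean of the middle
two). Timepoints are abstract indices; the follow-up window is a property
of the data. Function analyses can be done per person via
`select_function_knee` (highest-B-score knee; ties → right knee, then
lexicographic id).

Risk is plain maximum-likelihood logistic regression (statsmodels), with
KLG entered as four indicators against a KLG-0 reference; TKR is
deliberately modelled the same way rather than by a hazard model. Risk
curves are reported in percent with Wald CIs computed on the linear
predictor and inverse-logit transformed, which keeps intervals inside
[0, 100] and bracketing the estimate; linear predictors beyond ±50 are
clamped with a warning. Complete separation is detected (statsmodels'
warning escalated, plus a coefficient-norm guard) and reported as an
error naming the predictors; rank-deficient designs are rejected before
fitting. Quartile assignment within a KLG stratum uses linearly
interpolated sample quartiles with boundary values going to the lower
quartile; strata smaller than 8 scored knees or without outcome variation
are skipped with a warning. AUC is rank-based concordance (ties = 1/2).
Knees are treated as independent observations; no person-level clustering
correction and no multiple-testing adjustment are applied (p-values carry
conventional 0.05/0.01/0.001 stars).

## Synthetic cohorts

The generator reproduces the *statistical* structure the method needs,
not femoral anatomy. Defaults (the study conditions for all tests):

- latent severity: mixture of non-OA N(0, 1) and OA N(4, 1.5²) components,
  OA fraction 0.4; both knees of a person share a component and correlate
  0.6 within it (a person-level mechanism chosen for simplicity; the
  correlation is configurable);
- template: a 120-vertex Fibonacci-sphere ellipsoid (semi-axes 40/35/25 mm,
  condyle scale) with 0.3 mm seeded jitter; topology from the convex hull;
  the 20% of vertices nearest the equatorial plane form the "rim" band
  standing in for the cartilage-plate edge where osteophytic change
  concentrates;
- deformation: 0.8 mm of radial rim growth and 0.1 mm of central
  flattening per severity unit, plus a 1 mm-rms per-sex offset field,
  three individual variation modes (SD 1.0/0.6/0.3 mm) and 0.1 mm i.i.d.
  coordinate noise;
- KLG: severity cut-points (−0.5, 1.0, 2.5, 4.0) with 20% probability of
  a ±1-grade misreading — so every observed grade ≥ 2 spans ≥ 4 B-score
  units, the overlap structure that motivates a continuous score;
- outcomes: one uniform draw per knee/timepoint/instrument mapped through
  stacked exceedance probabilities, making P(score ≥ threshold) exactly
  inverse-logit(intercept + slope·severity) for both severities at once
  while producing integer instrument scores. Moderate-outcome
  coefficients (−1.619, 0.289) take risk from ~10% at severity −2 to ~60%
  at +7; TKR uses (−4.0, 0.5).

All randomness flows from one seed through `SeedSequence` substreams per
component and per subject, so output is bit-reproducible and enlarging
the cohort never perturbs earlier subjects.

What passing tests on these cohorts does **not** show: recovery of real
OAI effect sizes, anatomically realistic deformation patterns, realistic
missingness, or reader-specific KLG error structure. The generator's
linear severity-to-shape map is exactly the regime in which the B-score
is an ideal estimator; real femurs need not be so kind.

## Numerical choices and problem sizes

- Procrustes tolerance 1e-8 mm; Kabsch uses SVD with a determinant
  correction for proper rotations.
- PCA mode signs follow the largest-|loading|-positive convention.
- Mesh files are written as double-precision ASCII (PLY `property double`,
  %.17g), and CSVs are read with round-trip float parsing, so write/read
  cycles are lossless.
- Reference problem sizes: 250-subject (500-knee) cohorts for model
  construction checks, 10,000 pairs for repeatability Monte Carlo, 100
  replicates at n = 5000 for logistic coverage — sizes at which every
  stochastic check is comfortably stable on a laptop.

## Known limitations

- Single-direction severity model (see above); no longitudinal shape
  trajectories.
- No segmentation or correspondence estimation: inputs must already be
  corresponded point sets in a common protocol.
- CLI model files do not carry the Procrustes frame; `build-vector` and
  `score` assume pre-aligned inputs (true for the simulator's output) —
  library users align explicitly with `GeneralizedProcrustes`.
- Heat maps are per-face numeric tables; rendering is left to the user.
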