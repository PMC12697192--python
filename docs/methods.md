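# Methods

This note records the models, conventions and numerical choices behind
`ctrsa`, and what the synthetic studies do and do not establish about
real data.

## Coordinate conventions and the 6-DOF decomposition

All geometry is lab-frame millimetres, right-handed; angles are
degrees; time is months since surgery (the baseline examination,
acquired within days of surgery, is indexed month 0).

Migration is the pose change of an implant relative to its reference
bone (femur for the stem, pelvis for the cup) between the baseline and
a follow-up examination. The measurement chain in `analyze_pair`:

1. the follow-up exam is mapped into baseline space by a least-squares
   rigid superposition of the reference-bone markers (Kabsch, SVD form;
   a reflection solution is corrected by flipping the smallest singular
   direction);
2. the implant model is fitted by point-to-point ICP in both exams,
   initialised from a rigid fit of named implant landmarks (stem: tip,
   shoulder, neck point, head center; cup: center, pole, rim point) —
   emulating the landmark localisation an automated pipeline provides;
3. the relative motion `S ∘ pose_followup ∘ pose_baseline⁻¹` is
   expressed in the segment frame and split into a reference-point
   translation and Cardan angles.

Translations are positive medially (x), superiorly (y), anteriorly (z).
Rotations are Cardan angles in x-then-y-then-z order about the frame
axes; at migration magnitudes (≲ 2°) the ordering effect is far below
reporting precision (the first-order skew-symmetric extraction agrees
to 0.01° up to about 1°; the difference is the second-order commutator
term). Euclidean totals are `sqrt(x² + y² + z²)` of each triple.

The **stem frame** is implant-based: y along the stem long axis (tip →
shoulder), x the component of the neck axis orthogonal to y, z = x × y.
The **cup frame** uses the scanner-table axes of the baseline
examination with its origin at the implant reference point, because the
near-spherical cup supports no stable implant-based frame. The
translation reference point is the implant-model surface centroid by
default (`translation_reference`), configurable to a named landmark
(head center, cup center); published migration values do not state
which point they refer to, and the choice matters only when rotation is
nonzero.

**Sides.** Results are reported as if all hips were right-sided: for a
left hip Tx, Ry and Rz change sign, Ty, Tz and Rx do not. To make this
rule exact (not only to first order), the stem-frame x axis is signed
along the projected neck axis for right hips and opposite to it for
left hips, so a left hip is measured in the mirror-image frame of the
equivalent right hip; conjugation algebra then gives exactly the
(−Tx, Ty, Tz, Rx, −Ry, −Rz) pattern that `mirror_to_right` inverts. The
test suite verifies that an exactly mirrored scene reproduces the
right-sided table to 1e-9.

**Quality gates.** The marker-configuration condition number is
σ_max/σ_min of the centred coordinate matrix (capped at 1e12 for
rank-deficient sets); configurations ≥ 120 are flagged. The mean error
of rigid-body fitting is the RMS residual after superposition; values
≥ 0.35 mm flag unstable markers. (RMS was chosen over mean absolute
residual; the commercial definition is unpublished, and the alternative
is a one-line change.) Gates flag records — they never silently drop
them; exclusion is a downstream, logged decision. Only truly collinear
marker sets (rank < 2), for which the rotation is not unique, raise a
degenerate-fit error.

**ICP.** Nearest-neighbour correspondence on the model surface samples
(cKDTree), rigid update per iteration, convergence when no model point
moves more than 1e-6 mm, at most 200 iterations. The parametric models
are sampled on azimuthally irregular golden-angle spirals, so the point
set has no rotational symmetry and the pose of a noiseless cloud is
uniquely recoverable; the sample sets are exactly symmetric under
z → −z (the stem/neck plane), mirroring the near-symmetry of real
implants and keeping mirrored (left-hip) scenes fittable by proper
rotations of the same model.

## Synthetic studies

The generator emulates a 26-subject, two-year THA follow-up: exams at
0, 3, 12, 24 months; the CT-based method simulated for all subjects and
the marker-based method for a 10-subject subgroup; a duplicated visit
(default 3 months) with rigid repositioning (rotation ≤ 15°,
translation ≤ 50 mm — conventions, since real repositioning magnitudes
are not published) for precision estimation; 9–10 markers per segment
placed uniformly in ellipsoidal shells whose size (`marker_spread_mm`,
default 30) drives the condition number from well-conditioned toward
collinear; roughly 14/26 left hips, realised as exact sagittal mirrors
of right-sided constructions.

**Trajectories.** Each DOF follows a continuous piecewise-linear curve
`s_early·min(t, 3) + s_late·max(0, t−3)`, zero at month 0. Default mean
slopes put the two-year motion in the range reported for collared
uncemented stems and press-fit cups (stem subsidence ≈ 0.1 mm and
retroversion ≈ 0.5°, cup proximal migration ≈ 0.3 mm and inclination
decrease ≈ 0.5°, most of it before 3 months). Per-subject slope
deviations are Gaussian (`subject_sd`, default 0.01 units/month early,
an eighth of that late).

**Noise.** Each examination carries an independent 6-DOF measurement
error, isotropic Gaussian per component with a method-specific SD
(`noise_sd_ctrsa` 0.035, `noise_sd_mbrsa` 0.08 mm/°), realised
geometrically as a small rigid perturbation of the observed implant
pose. These defaults land the double-exam precisions near the reported
ranges (CT translations ≈ 0.06–0.16 mm, marker-based ≈ 0.17–0.38 mm).
Because both double-exam replicates are compared to the same baseline,
the baseline's error cancels in their difference, so the difference SD
is σ√2; across follow-ups the shared baseline error instead appears as
a per-subject offset — which is exactly the random intercept of the
longitudinal model. Optional isotropic per-point noise
(`point_noise_sd`, default 0) and sporadic marker instability
(`marker_instability_prob`, displacement SD `instability_magnitude_mm`)
exercise the registration and the ME gate separately; they are kept out
of the default noise budget so that the per-DOF SDs remain the single
calibrated precision driver.

Determinism: all randomness descends from `StudyConfig.seed` through a
fixed `SeedSequence` spawning order; identical configs give
byte-identical serialized studies.

**What passing tests do not show.** The simulator works on labelled
geometry: it contains no imaging, segmentation or landmark-detection
errors, no scanner-dependent distortion, no bone remodelling, and its
noise is Gaussian and independent across exams. Zero-noise closure and
calibration results therefore validate the measurement and statistics
chain, not the imaging front end of any clinical system.

## Statistics

**Precision** per DOF is `SD(replicate-2 − replicate-1) × t`, t the
two-sided 5% Student-t critical value with df = n_pairs − 1 (df = n
available via `df_rule`; published tables rarely state the convention,
and the cells used for verification round identically under both).
Report-time rounding is half-up to 2 decimals and never enters
computation.

**Bland–Altman** pools the three per-subject follow-up comparisons
without within-subject adjustment, matching the standard construction
in this literature; a repeated-measures LoA variant is out of scope.
Limits are bias ± 1.96·SD of the paired differences.

**Least-square means** come from a repeated-measures mixed model
(method, timepoint, method×timepoint fixed; subject random intercept;
REML) evaluated per method and timepoint, with Wald CIs from the
model-based GLS covariance of the fixed effects.

**Longitudinal model.** Per DOF:
`y_ij = b0 + b1·t_ij + b2·max(0, t_ij − 3) + u_i + e_ij`, u_i a random
subject intercept, REML estimation. Time runs from surgery, so the
month-0 observations (identically zero, since migration is measured
against the baseline exam itself) are part of the data; without an
observation before the breakpoint the hinge equals t − 3 everywhere and
the early slope is not identifiable — `fit_piecewise_lme` adds the
zero rows when given follow-ups only, and raises on designs that still
cannot separate the slopes. Slope tests use a Student-t reference with
within-subject residual df (n_obs − n_subjects − 2), a standard
within-between approximation; the breakpoint (3 months) is fixed, not
selected. Random slopes are available behind a flag and off by default
— a random intercept is the literal standard specification and is what
the shared-baseline error structure produces. Because variance
components commonly sit on the zero boundary at study sizes, fits retry
with derivative-free optimizers when a gradient step fails, and
fixed-effect covariances are computed from the estimated variance
components (GLS form) rather than the REML Hessian; noiseless data
floors the residual variance at 1e-12 to keep that covariance finite.

**Concordance.** Exact binomial intervals from beta quantiles: lower
bound the α/2 quantile of Beta(k, n−k+1) (0 when k = 0), upper the
1−α/2 quantile of Beta(k+1, n−k) (1 when k = n); validated in tests
against the defining binomial tail equations to 1e-10. Percentages are
rounded half-up to integers at report time only. Plan-table geometry is
decoupled from the size draws: one canonical stem/cup model pair serves
all subjects' geometry, since the concordance statistics depend only on
the categorical draws.

## Problem sizes used in the automated checks

The acceptance-style tests run at sizes chosen to make their tolerances
statistically comfortable on one CPU: 100 random scenes for zero-noise
closure (tolerance 1e-6; observed errors ~1e-13), 500 simulated
subjects for precision calibration (10% tolerance against t·σ√2,
sampling error ≈ 3%), 200 replicates × 25 subjects for slope recovery
(bias tolerance 10% of the early slope), and 2000 draws for interval
coverage. Implant models use ~180–360 surface samples, which keeps ICP
in the millisecond range without affecting the exactness properties.

## Known limitations

- Point-to-point ICP with landmark initialisation is a stand-in for the
  unpublished commercial registration objective; output semantics
  (6-DOF migration per segment frame) are identical, internals are not.
- The cup's scanner-table frame assumes consistent patient positioning
  at baseline; an anatomically corrected pelvic frame is not
  implemented.
- Translation values depend on the chosen implant reference point when
  rotations are nonzero (centroid by default, configurable).
- The Bland–Altman LoA ignore the correlation induced by repeated
  measures on the same subject.
- Serialized point clouds (PLY) store float32; round-tripping through
  disk preserves geometry to ~1e-3 mm, below measurement noise but
  above the in-memory closure tolerances.
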