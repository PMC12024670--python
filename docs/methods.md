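# Methods

This document specifies the models, conventions, and numerical choices behind
`rulakit`. Everything here is deterministic given a seed; all angles are in
degrees, all image coordinates in pixels with y increasing downward.

## 1. RULA scoring engine (`rulakit.core`)

A posture is described by five joint angles (upper-arm flexion, lower-arm
flexion, wrist deviation, neck flexion, trunk flexion), eleven boolean posture
flags, and four integer score increments. Scoring follows the standard RULA
worksheet:

| Region | Bands (score: condition) | Modifiers |
| --- | --- | --- |
| Upper arm | 1: −20° ≤ θ ≤ 20°; 2: 20° < θ ≤ 45° or θ < −20°; 3: 45° < θ ≤ 90°; 4: θ > 90° | +1 shoulder raised, +1 abducted, −1 supported (floored at 1) |
| Lower arm | 1: 60° ≤ θ ≤ 100°; 2: otherwise | +1 arm across midline / out to side |
| Wrist | 1: neutral; 2: 0 < \|θ\| ≤ 15°; 3: \|θ\| > 15° | +1 bent from midline |
| Wrist twist | 1 mid-range; 2 near end of range | — |
| Neck | 1: 0° ≤ θ ≤ 10°; 2: 10° < θ ≤ 20°; 3: θ > 20°; 4: θ < 0° (extension) | +1 twist, +1 side tilt |
| Trunk | 1: \|θ\| ≤ 2° (seated, supported); 2: \|θ\| ≤ 20°; 3: \|θ\| ≤ 60°; 4: beyond | +1 twist, +1 side tilt |
| Legs | 1 supported; 2 otherwise | — |

Conventions:

- Band boundaries belong to the lower-scoring band (`<=` comparisons).
- The seated-trunk "upright" tolerance defaults to ±2° (configurable).
- The wrist "neutral" band carries a 1e-9° tolerance: it is a pure
  floating-point guard so that angles reconstructed through 2D geometry still
  count as neutral, not a physiological band.
- The trunk is banded on the magnitude of its deviation from upright; a small
  recline is treated like the equivalent small flexion.
- Sub-scores feed lookup tables A (arm/wrist) and B (neck/trunk/legs);
  `score_a = posture_a + muscle_use_arm + force_load_arm` (same for B); the
  grand 1–7 score comes from table C with inputs ≥ 8 (A) / ≥ 7 (B) clamped to
  the last row/column.
- Default increments model static seated work without load handling:
  muscle-use +1 for both groups, force/load 0, legs supported.

Both a scalar API and a vectorised array path exist; the scalar functions are
wrappers over the array kernels, so the two cannot disagree.

## 2. Pose branch (`rulakit.pose`)

Input: two 17-keypoint skeletons (COCO/MoveNet layout) — one sagittal, one
frontal — plus manual annotations for transverse-plane items (neck/trunk
twist, forearm rotation, wrist bent-from-midline, arm support, hand-direction
unit vector). Only one body side (default right) is scored.

Sagittal measurements (signed; `f = +1` when the subject faces image-right):

- trunk flexion = signed angle of the hip→shoulder line against image-up;
- upper-arm flexion = signed angle between the shoulder→hip line and
  shoulder→elbow axis;
- lower-arm flexion = unsigned angle between shoulder→elbow and elbow→wrist;
- neck flexion = signed angle between the upward extension of the trunk line
  and the shoulder→ear axis (extension negative);
- wrist deviation = signed angle between the forearm line and the annotated
  hand-direction vector. Without that annotation the wrist is declared
  unmeasurable (error), unless `wrist_from_annotations_only` is set.

Frontal threshold rules (all thresholds configurable):

- abduction: 180° minus the hip–shoulder/shoulder–elbow angle > 20°;
- shoulder raised: shoulder-line inclination from horizontal > 5°
  (e.g. a 3 cm offset across a 38 cm shoulder width ≈ 4.5° → not raised);
- arm across midline: scored wrist's x beyond the mid-hip vertical;
- neck side tilt: eye-line inclination > 1°;
- trunk side tilt: mid-hip→mid-shoulder inclination from vertical > 5°.

The image vertical is treated as gravity-aligned (cameras levelled). All
extracted quantities are invariant to uniform scaling and translation of the
keypoints. Keypoints below the confidence threshold (default 0.3) raise an
occlusion error naming the keypoint.

## 3. IMU branch (`rulakit.stream`)

An `AngleStream` is a fixed-rate sequence of complete postures. Every frame is
scored independently; the take is summarised by the fraction of frames in each
grand-score level 1–7 and per-region mean sub-scores. The continuous overall
score is the time-weighted mean Σ k·fraction(k), algebraically identical to
the arithmetic mean of per-frame grand scores. No filtering or resampling is
applied.

## 4. Agreement statistics (`rulakit.agreement`)

- **Weighted kappa**: κ_w = (P_o − P_e)/(1 − P_e) with weights
  w_ij = 1 − |i−j|/(k−1) (linear, default) or 1 − ((i−j)/(k−1))² (quadratic).
  The 95% CI uses the non-null asymptotic variance of Fleiss, Cohen & Everitt
  (1969); the test of κ = 0 uses the corresponding null variance. Degenerate
  marginals (1 − P_e = 0) raise an undefined-kappa error.
- **Level rounding**: continuous aggregated scores are rounded half-up
  (`floor(x + 0.5)`) and clipped to each family's level count
  (overall 7; upper arm 6; lower arm 3; wrist 4; neck 6; trunk 6; legs 2).
- **Bland–Altman**: differences d = x − y; limits of agreement
  mean(d) ± 1.96·sd(d) with the sample (n−1) SD.
- **Mann–Whitney U** (scipy, midrank ties, two-sided asymptotic default) with
  rank-biserial effect size r_rb = 1 − 2U/(n₁n₂): −1 when every x exceeds
  every y, +1 for the opposite separation.
- **Bonferroni**: min(1, p·m), default m = 6 (overall + five regions).
- **Shapiro–Wilk** (scipy) as the normality gate, 3 ≤ n ≤ 5000.
- **Post hoc power** of the two-tailed t-test for a point-biserial
  correlation: df = n − 2, noncentrality δ = r√n/√(1−r²), evaluated with the
  noncentral t distribution. At r = 0.45, α = 0.05, n = 45 this yields
  91.05%. (The exact bivariate-normal model gives ≈ 88–89%; the fixed-regressor
  t-test model is the default because it matches standard power calculators.)

## 5. Synthetic cohorts (`rulakit.simulate`)

Each participant has one true posture: angles drawn from truncated normals,
flags from Bernoulli draws, anthropometry resampled from published
female-cohort summary statistics (mean/SD truncated at min/max; height
165 ± 6.35 cm, shoulder width 37.97 ± 2.75 cm, …). Segment lengths: upper arm
= (elbow span − shoulder width)/2; forearm = (wrist span − elbow span)/2;
trunk = 0.288·height; shoulder→ear = 0.105·height.

**True-angle defaults** (calibrated once so that the IMU-branch cohort mean
overall RULA sits in the moderate-risk range near 4.8; acceptance interval
4.3–5.3):

| Angle | mean | SD | bounds |
| --- | --- | --- | --- |
| upper-arm flexion | 40 | 22 | [−10, 120] |
| lower-arm flexion | 110 | 25 | [20, 160] |
| wrist deviation | 12 | 8 | [−30, 45] |
| neck flexion | 15 | 13 | [−15, 60] |
| trunk flexion | 7 | 6 | [−5, 40] |

Flag probabilities: shoulder raised 0.15, abducted 0.30, supported 0.10,
across midline 0.40, wrist bent 0.35, wrist twist end-range 0.50, neck twist
0.15, neck side tilt 0.15, trunk twist 0.05, trunk side tilt 0.05.

**IMU noise model**: per-frame angle = true + linear drift
(default 0.02°/s) + stationary AR(1) jitter (coefficient 0.9, stationary SD
2°). Default capture: 30 s at 60 Hz. Flags are held at their true values.

**Pose noise model**: the true angles receive a per-region additive bias
(default +4° trunk, modelling the pose branch's trunk over-scoring) plus
Gaussian angle noise (default SD 6°); the perturbed posture is rendered into
two stick-figure skeletons by forward kinematics, and every keypoint gets
Gaussian pixel jitter (default 1 px at 4 px/cm). Frontal flags are expressed
geometrically with separated render angles (abduction 30° vs 5°, shoulder
raise 10° vs 0°, eye tilt 6° vs 0°, trunk lean 8° vs 0°) so the noise-free
round trip is exact.

**Kappa calibration**: expected overall κ decreases monotonically with the
pose angle-noise SD. `calibrate_pose_noise` evaluates the Monte-Carlo mean κ
on a noise grid (0.5–24°, 40 cohorts per point), inverts by interpolation and
refines with a local linear fit. With all other defaults the achievable range
is roughly 0.53 (at 0.5°) down to 0.15 (at 24°), so the 0.45 target sits well
inside; the calibrated SD lands near 3.3° and 200 replicate cohorts recover a
mean κ within ±0.05 of the target.

## 6. Numerical and reproducibility choices

- All randomness flows through one `numpy.random.Generator` seeded from the
  config; identical seeds yield byte-identical files and reports (JSON written
  with sorted keys, floats serialised by `repr` for exact round-trips).
- The AR(1) jitter uses `scipy.signal.lfilter` plus an exact stationary start
  (an extra e₀·φᵗ term with e₀ drawn at the stationary SD), so the first frame
  is not artificially quiet.
- Hot loops (calibration, replicate recovery) use an internal array path that
  shares its angle sampler with the public stream renderer; a test pins the
  two paths to equality at 1e-12.
- Truncated normals use `scipy.stats.truncnorm`; Shapiro–Wilk and
  Mann–Whitney are delegated to scipy rather than re-derived.
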