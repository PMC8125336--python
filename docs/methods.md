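# Methods

This note documents the models, parameter defaults and numerical choices
behind `aclrisk`, and what the synthetic-data experiments do and do not
demonstrate.

## Sensor model and orientation estimation

The IMU convention is: accelerometer in m/s² measuring specific force
(+9.81 on the local z axis at upright rest), gyroscope in deg/s,
timestamps strictly increasing with < 10% step jitter. A static upright
trial (≥ 1 s, mean gyro magnitude < 5 deg/s) defines the re-alignment: the
minimal rotation taking the mean accelerometer vector onto (0, 0, +g).
Because no magnetometer is used, heading is unobservable; it is pinned to
zero at calibration, which also fixes the identity of the
antero-posterior/medio-lateral axes. All downstream axis semantics (x = ML,
y = AP) inherit from that choice.

The Mahony complementary filter integrates the gyroscope on the quaternion
manifold (exponential-map update) with a proportional–integral correction
toward the accelerometer vertical. Defaults: Kp = 1.0, Ki = 0.3 —
common mid-range gains; both configurable. The correction is *gated*: it is
applied only when the specific-force magnitude is within 30% of 1 g.
Gating is standard practice for impact-laden recordings; without it, the
landing burst (a large, non-gravitational acceleration) drags the tilt
estimate by several degrees within a 0.3 s window, which is the same order
as the sway signal itself. With a gate, the filter falls back to pure gyro
integration through the impact and re-engages afterwards. The filter
initialises from the first sample's accelerometer tilt.

The sway path is the intersection of the line through the sensor origin
along its longitudinal axis S with the world-fixed plane 1 cm below:
`xy = −depth · (S_x/S_z, S_y/S_z)` in cm. This line–plane construction
(rather than orthogonal vector projection) reproduces the "1 cm below"
geometry exactly and reduces to `depth·tan(tilt)` proportionality at small
angles. It requires S_z > 0.1 (tilt < ~84°), enforced with an error naming
the offending sample.

## Event detection

* Contact: first off→on LED transition after the search time.
* Stabilization time: ‖ω‖ (3-axis gyro norm) is smoothed with a zero-phase
  4th-order Butterworth low-pass at 10 Hz (configurable) before searching
  for the first strict local minimum after contact; plateaus resolve to
  their earliest sample. The smoothing exists because the rectified raw
  norm is minima-ridden; 10 Hz keeps the landing oscillation (~1 Hz
  quarter-cosine) intact.
* Squat window: the baseline is the mean of 0.5 s / 50%-overlap windowed
  SDs of the angle-vector magnitude on the static trial; movement starts
  when a per-sample trailing 0.5 s rolling SD exceeds 5× baseline. Because
  the trailing window lags the true onset by a few samples, the detector
  walks back from the crossing to the first sample whose magnitude exceeds
  the quiet level (pre-crossing median) by 2× baseline; this one-sided
  refinement recovers the onset to ~1 sample. The descent ends at the
  argmax of θ_y; a maximum at the final sample is rejected as a truncated
  descent. The 5× factor, window length and overlap are named configuration
  constants.

## Features

Sway measures follow the classical posturographic definitions: PL is the
Euclidean arc length of the sway trace, PL_ML/PL_AP the total variation of
its x/y coordinates, and EA the area of the bivariate confidence ellipse
`EA = 2π F_level(2, n−2) √(det S)` with the sample covariance S and
level = 0.99 (configurable). Coverage of this ellipse is verified by Monte
Carlo in the tests. A collinear point cloud yields EA = 0 with a warning.

The jump features are computed on `[contact, contact + Ts]` and divided by
Ts; the squat features on `[t_start, t_end]` and divided by T_DP. The same
interval is used for computation and normalization (both exposed as
options). Landing RMS values are computed after rotating the accelerometer
into the absolute frame with the *static* correction and removing gravity
from the vertical channel — without gravity removal RMS_z would be
dominated by the constant 9.81 offset and carry no group contrast. Reported
units keep the conventional cm / cm² / m/s² labels even though the
time-normalization changes dimensions; this matches how such features are
usually tabulated.

Feature vectors average exactly 5 repetitions per task (fewer allowed
behind an explicit flag, with a warning).

## Synthetic cohorts (feature tier)

Per-group multivariate Gaussians with published R/NR means and SDs for the
13 features. Default inter-feature correlation: r = 0.7 within the jump
instability block (PL_ML, EA, RMS_z, RMS_xy), r = 0.2 elsewhere. The block
reflects that these features all measure one underlying landing
instability; strong redundancy is the only way a feature can separate the
groups by ~11 SDs univariately while carrying only a modest share of
permutation importance. Nonnegative quantities are enforced by rejection
(whole-row resampling), not clipping, to avoid point masses at zero.

LESS records are generated label-consistently: per-athlete integer median
targets are binomial within the label's admissible range (NR: Binomial(5,
m/5); R: 6 + Binomial(13, (m−6)/13)), which matches the requested group
means (defaults 3.5 and 7.5) by construction. Jump-to-jump jitter preserves
the median exactly and vanishes at the scale edges; items are filled
uniformly within their 0/1 (items 1–15) or 0/1/2 (items 16–17) ranges. The
EA–LESS rank coupling allocates medians within each group by a noisy EA
severity ranking; the noise scale is calibrated by internal bisection so
the cohort Spearman correlation approaches the requested value (default
0.88). Because the two groups are far apart in EA, the between-group
component alone contributes ρ ≈ 0.7 at the default 26/13 composition;
requested values below that floor are clamped to the nearest achievable.

## Synthetic trials (signal tier)

Trials are additive piecewise signals, not biomechanical simulations; the
phase order is hard-coded (stance → flight → landing for the jump; hold →
descent → ascent for the squat) and the sample rate defaults to 100 Hz.

*Jump.* The landing window carries three superimposed components. (1) A
rotation about the sensor's long axis with rate `A·cos(πτ/2Ts)` — its
rectified magnitude falls monotonically to zero exactly at contact + Ts and
rises afterwards, so the stabilization-time rule recovers Ts to the sample;
the heading is integrated with a left-aligned cumulative sum so the
finite-difference gyro reproduces the profile on the grid. (2) A sway tilt
trace constructed to meet the PL/PL_AP/PL_ML/EA targets: arc length is
allocated exactly by splitting the window into x-only, y-only and
fixed-slope diagonal slots (the mixing fraction solves the Minkowski bound
`√(L_AP² + L_ML²) ≤ PL ≤ L_AP + L_ML` analytically), positions follow
triangle waves a quarter period apart (decorrelating the axes), and the
amplitudes are fixed-point-iterated against the ellipse-area target.
(3) Alternating-sign acceleration bursts, concentrated on an early active
stretch with amplitude ≥ ~30 m/s², scaled so the gravity-removed window RMS
is exact; the amplitude floor keeps the accelerometer gate off on every
burst sample, so the orientation estimate is undisturbed.

Published group-level path-length triples can violate the per-trial
geometric bounds (group averaging and rounding do not preserve them), and a
PL at the Minkowski bound forces a collinear, zero-area path. The recipe
therefore projects an infeasible PL onto the feasible interval at
construction, and the jump synthesizer grants additional arc length (up to
the staircase limit) when the ellipse-area target would otherwise be
unrealizable. The generator measures the path it actually built and stores
the result as `realized_features` — the ground truth that round-trip tests
and users should compare extractions against; `requested` preserves the
original numbers.

*Squat.* θ_y rises from the hold as a quarter-sine (97%) plus a small
linear term (3%) — the blend gives the peak a defined slope so its argmax
is robust to orientation noise — reaching θ_ymax at t_start + T_DP, then
descends during the ascent phase. Sway wiggles ride on both tilt axes. The
medio-lateral wiggle adds directly to θ_y, so its envelope is capped by the
requirement that the θ_y argmax stay at the ramp peak; consequently the
squat's sway targets are realized best-effort (typically below the
requested values) while θ_ymax and T_DP are exact. Again,
`realized_features` records what was actually built. Orientation noise is
0.005°, accelerometer noise 0.02 m/s² — intentionally clean; the tier
exists to verify the processing chain, not to emulate sensor-grade noise.

What passing the signal round-trip shows: the orientation, event and
feature code inverts the generator's signal model to within 10% across the
calibrated parameter range. What it does not show: robustness to real
landing spectra, soft-tissue artifacts, sensor bias/drift or misdetected
repetitions — none of which the additive model produces.

## Benchmark and importance

Stratified grouped 9-fold cross-validation is the default (39 athletes →
folds of 4–5, each athlete tested once); the literal "9 random 30/9
hold-outs" scheme is available as `random-holdout` for fidelity to the
original description, which cannot be realized as disjoint ninths of 39.
Features are z-scored with training-fold statistics only — distances
between features spanning 0.2 cm² and 250 m/s² are meaningless otherwise.
Metrics default to pooled confusion counts across folds (per-fold averaging
available). SVMs use C = 1 and inhomogeneous polynomial kernels of degree
1/2/3; the decision trees map "maximum number of splits" 4/20/100 to
`max_leaf_nodes` s+1. The goodness index is bounded by √2 (both rates at
zero); the "random" label is reserved for the neighbourhood of the chance
distance √0.5 ≈ 0.707 between the good band (≤ 0.70) and the bad band.

Permutation importance grows a hand-rolled bagged-tree forest (500 trees,
bootstrap size n, √p features per split, one permutation per tree per
feature by default) because per-tree out-of-bag accuracy differences — the
definition of MDA — are not exposed by library forests. Zero-variance
features get MDA 0 with a warning. Spearman bands: none ≤ 0.1 <
mild/modest ≤ 0.3 < moderate ≤ 0.6 < strong < 1 = perfect, boundaries
assigned to the lower band.

## Determinism and problem sizes

A single root seed derives all stage seeds (`numpy` SeedSequence); fixed
seeds give bit-identical cohorts, trials, confusion counts and importance
values. The test suite runs feature-tier checks at up to 4000 athletes per
group (moment convergence; SD sampling noise at n = 1000 would make a 5%
per-feature bound flaky), the ellipse coverage at 10⁴–10⁵ points, the
bench surrogate at 50 cohorts of 39, and the signal round trip on single
repetitions per recipe — sizes chosen to make sampling error comfortably
smaller than every asserted tolerance.

## Known limitations

* The signal model is an idealization: no flight-phase dynamics, no
  push-off burst, no bias/drift, clean noise floors.
* The squat's sway targets are under-realized by design (see above).
* Heading is unobservable without a magnetometer; AP/ML identity is only
  as good as the upright calibration.
* Classifier results on synthetic cohorts reflect the calibrated group
  separation, which is large; they demonstrate the pipeline's correctness,
  not expected field performance on new athletes.
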