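# Methods

This note documents the models, conventions, parameter choices and known
limitations of `musefatigue`, in the order of the processing chain.

## Coordinate and joint conventions

All geometry uses image coordinates: origin top-left, y increasing
downward.  "Hip below knee" therefore means `y_hip > y_knee`, and the squat
drop ratio δ is *positive* for a deep squat and negative for a standing
figure.  The COCO-17 joint set is canonical; since it lacks a neck
landmark, the torso-length measurement uses the shoulder midpoint as a neck
proxy (its confidence is the minimum of the two shoulder confidences).
Absent joints are carried explicitly at confidence 0 — parsing never drops
or invents a joint, which the round-trip tests enforce.

## Validity gating

A frame is evaluated for a posture only when every joint that posture's
rule reads clears the confidence threshold (`conf_min = 0.3`, a common
operating point for bottom-up estimators; configurable).  Lower-limb rules
require hips, knees and ankles; the hands-on-hips rule requires shoulders,
elbows, wrists and hips.  This completeness check is what prevents
occlusion-induced misclassification: a frame with a missing knee can never
be labeled a squat, only NONE.

## Posture rules and their numerical conventions

Thresholds (defaults): squat `δ > 0.10` with both knee interior angles
`< 120°`; akimbo `η ∈ (0.30, 0.45)` both sides, elbow angles
`∈ (80°, 120°)`, torso ratio `τ ∈ (0.3, 0.7)`, per-side hip-above-wrist
order check; leg lift: raised knee interior angle `∈ (70°, 130°)`,
support-leg flexion `≤ 15°`, ankle separation `γ > 0.05`.

Decisions that were genuinely open and how they were resolved:

- **Angle semantics.**  Squat and raised-leg thresholds apply to the
  *interior* hip–knee–ankle angle (straight leg ≈ 180°); the support-leg
  criterion applies to *flexion*, defined as 180° minus the interior
  angle.  This is the only consistent reading under which a one-leg stance
  satisfies all three leg-raise criteria simultaneously.
- **Both-knees vs. min-knee squat.**  The default requires *both* knee
  angles below 120°; a `squat_knee_mode="min"` flag switches to the
  min-over-knees reading.  Under the default, squat and leg-lift are
  mutually exclusive (a support leg at ≥ 165° interior cannot also be
  < 120°); under min-mode they can co-fire, and the fixed priority order
  SQUAT > AKIMBO > LEG_LIFT resolves the label.
- **η uses the absolute horizontal difference**; without it the left-side
  offset would be systematically signed and the (0.30, 0.45) band would be
  unreachable on one side.  η below 0.3 corresponds to arms hanging
  naturally, which is the non-akimbo rest state.
- **Open intervals, strict comparisons.**  Boundary values fail (η exactly
  0.30 is not akimbo; γ exactly 0.05 is not a leg lift).  The support-leg
  flexion bound is the one closed comparison (≤ 15°), as stated.
- **Hip/wrist order check.**  Implemented per side, literally in y-down
  coordinates (`y_hip < y_wrist`, i.e. hips above wrists in the image),
  behind an `enforce_hip_wrist_order` flag (default on) because the
  intended direction is anatomically debatable for a hands-on-hips pose.
- **Degenerate geometry** (coincident joints, zero shoulder width) raises
  in the individual geometry operations but yields a plain non-detection
  inside the combined classifier, so a corrupt frame can never crash a
  batch run.

All detectors are invariant under uniform image rescaling (every measure is
normalized by frame width, frame height or shoulder width) and under
horizontal mirroring; both invariances are property-tested.

## Temporal confirmation and scoring

A posture accrues credit only while an unbroken run of identical labels has
reached `m = 5` frames; the first `m − 1` frames of a run are *not*
back-credited (counter semantics: a run of 7 frames yields 3 confirmed
frames).  This is deliberate and documented because prose descriptions of
"confirmed after five frames" could also be read as crediting the whole
run; the counter reading is the one the per-frame accumulation loop
implements, and the test suite pins it against an independent trace.

Durations are measured in seconds (`f_i = confirmed frames × dt`,
`dt = 1/30 s` by default, matching 1080p/30 fps acquisition), so the score
ceiling `F_max = 20` is in weighted-seconds.  Durations are computed as one
frame-count multiply rather than a running sum of `dt`, so whole-second
runs land exactly on their boundary — the 180-confirmed-frame squat gives
`F = 3.0` and `S_v = 0.15` exactly, and the `≥ γ` rule flags it.  Besides
the fixed pilot scale (default), a window-relative normalization
(`S_max = w_max · T_win`) is available for fixed observation windows; the
two disagree in general and the fixed scale is the one against which
`γ = 0.15` was calibrated.

## Zone aggregation

`N_t` counts unique visitor ids with at least one frame in the zone
(re-entries do not increment it); `N_f` counts those whose *zone-restricted*
subsequence is flagged by the full pipeline.  Confirmation is re-run on the
restricted subsequence, so a run split across a zone boundary must
re-confirm inside each zone and fatigue does not carry over between zones —
a modeling choice, flagged here because an alternative (carry-over) reading
exists.  Empty zones report FI = 0 with an explicit flag and are excluded
from museum-wide means.  The published band table leaves (0.33, 0.34) and
(0.66, 0.67) unassigned; the implementation uses the continuous partition
low `[0, 1/3]`, medium `(1/3, 2/3]`, high `(2/3, 1]`, which agrees with the
table at two-decimal resolution and makes the classifier total.

Per-zone pre/post "decrease of X%" follows the percentage-point convention
`100 · (FI_pre − FI_post)`; a separate `relative_change` operator covers
ratio-style comparisons (image metrics, completeness).  The camera-image to
floor-plan mapping is user-supplied calibration (a planar homography from
≥ 4 correspondences); no projection model is assumed.

## Camera coverage

Coverage is evaluated in 2-D plan view; installation height is folded into
the effective observation radius.  A cell is covered when its *center*
passes the radius test, the FOV wedge test (wedge symmetric about the
heading; both boundaries closed, with a 1e-9 relative epsilon absorbing
float noise) and the occlusion test (the sight segment must not intersect
any obstacle polygon).  FOV is constrained to [90°, 120°].  The greedy
planner picks the candidate with the largest marginal gain in r-covered
cells (ties: lowest camera id) and stops at the budget or zero gain; the
exhaustive planner is the small-instance optimality oracle (guard: at most
2^20 subsets), with ties resolved to fewer cameras then lexicographic ids.
Because r = 1 coverage is a monotone submodular objective, greedy CAP is
guaranteed ≥ (1 − 1/e) of optimal; the acceptance suite measures the
realized ratio on random instances.

## Image quality and gating

Kernels and borders (named but not fully specified by the source
formulas): 4-neighbor Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]`, standard 3×3
Sobel pair, replicate borders, population (1/N) normalization throughout.
The five gate features are made concrete as: DCT high-frequency energy
ratio (energy outside the first ⌈n/2⌉ coefficients per axis, orthonormal
DCT), variance of per-window RMS contrast (16×16 windows, stride 16),
Laplacian variance, max–min of global channel means, and Pearson
correlation with the previous frame (1.0 when there is none; for a
zero-variance pair, 1.0 iff the frames are identical).  Grayscale
conversion is the plain channel mean.  Gate calibration statistics
(feature means/sds) must be supplied or fitted on a reference clip — there
are no hidden defaults, and a zero calibration sd is an error rather than
a silent division.  The deblurring/low-light enhancement networks are out
of scope; `CommandEnhancer` attaches any external model as a
file-in/file-out command template, and the gate routes frames between the
enhanced ("ROBUST") and fallback ("BYPASS") paths.

## Synthetic data: what it emulates and what it does not

The generator poses a canonical stick figure with anthropometric segment
ratios, sized so a standing figure's torso ratio falls inside (0.3, 0.7).
Scripted events satisfy their detector with explicit margins (squat
δ = 0.2, knees 100°; akimbo η = 0.375, elbows 100°, wrists 20 px below the
hips; leg lift raised knee 100°, support flexion ≈ 12°, γ ≈ 0.084); margins
are figure parameters so boundary behavior is directly testable.  Noise is
i.i.d. Gaussian pixel jitter plus per-joint Bernoulli dropout.  Because
confirmation counts frames, `event_for_confirmed` scripts events by
*confirmed* duration by prepending the m − 1 lead-in frames.

Populations give fatigued visitors a scripted budget of exactly 3.5
weighted-seconds (safely above the 3.0 decision boundary) and others 1.0,
keeping the per-zone binomial truth unambiguous.  Population tracks sample
at 5 fps — frame-count confirmation makes the weighted-seconds truth
independent of the sampling rate, and this keeps a 50-seed × 200-visitor
recovery run under a minute.  What the generator does *not* emulate:
correlated estimator error, identity switches, perspective foreshortening,
crowding occlusion structure, or realistic posture kinematics.  Passing
tests therefore demonstrate correctness of the rules, the confirmation
logic and the aggregation arithmetic under the stated geometry — not
field-accuracy of the thresholds on real footage.

## Problem sizes

Default verification runs use: 240-frame scripted tracks for framewise
recovery; 1,000 random label sequences for the confirmation trace; 50
seeds × 200 visitors for binomial FI recovery; 200 random coverage
instances (≤ 12 candidates, ≤ 30 cells) with the exhaustive oracle on a
quarter of them; and small analytic rasters for the image metrics.  These
sizes were chosen so the whole chain verifies in well under a minute while
keeping the binomial and submodular tolerances meaningful.

## Known limitations

Rule-based classification covers exactly three postures; 2-D geometry is
viewpoint-sensitive (the thresholds assume a roughly frontal or oblique
view); person identity is taken from the input stream (no re-identification
or tracking); no physiological calibration of the weights or of
`F_max`/`γ` is performed; units of the score ceiling are an interpretation
(weighted-seconds) since the pilot scale is otherwise dimensionless; and
the coverage model's cell-center visibility can over- or under-state
coverage of partially visible cells.
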