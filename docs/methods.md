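# Methods

`impactkit` detects helmet impacts in triggered recordings from
instrumented mouthguards. Each recording is a 100 ms window sampled at
1000 Hz (10 ms pre-trigger, 90 ms post-trigger, armed by a 10 g
threshold) containing triaxial linear acceleration (g), triaxial angular
velocity (rad/s), and one infrared (IR) proximity reading indicating
whether the tray sits on the upper dentition. Video activity labels
(helmet contact with direction, body contact, no contact, idle,
obstructed, no view) provide ground truth. The pipeline is: preprocess →
extract 411 features → filter by IR placement → build a labeled dataset
from video cross-referencing → train an RBF-SVM with forward feature
selection costed by leave-one-out cross-validation (LOOCV).

## Preprocessing

Device triads are rotated into the head anatomical frame (AP = +anterior,
LR = +left, IS = +superior, right-handed; angular channels
coronal/sagittal/horizontal are rotations about AP/LR/IS). Channels are
low-pass filtered at the sensor bandwidths — 500 Hz accelerometer, 184 Hz
gyroscope — with a 4th-order Butterworth applied forward-backward
(zero-phase, the convention of impact biomechanics, SAE J211-style; this
doubles the effective order). The 500 Hz cutoff coincides with Nyquist,
where the design is ill-posed, so cutoffs at or above 0.99× Nyquist pass
through unchanged. Linear velocity comes from trapezoid integration of
acceleration (g → m/s² with 9.80665, zero initial velocity); angular
acceleration from a five-point central stencil (exact for quartics;
one-sided 4-point/2-point differences at the edges keep length 100).
Gravity is not subtracted: a 10 g-triggered 100 ms window carries no
usable orientation reference, and the bias is small against the trigger.
Linear acceleration is *not* moved to the head centre of gravity for the
spectral/time features, to avoid coupling angular content into them; the
head-neck model does apply the rigid-body transform
a_CoG = a + α×r + ω×(ω×r) for its own features.

Rotation and per-axis identical filtering commute, so the
rotate-then-filter order is not load-bearing.

## The 411-feature registry

| block | count | content |
|---|---|---|
| time domain | 24 | peak \|linear acceleration\|, Δ linear velocity, peak \|angular acceleration\|, Δ angular velocity, each per AP/LR/IS (or coronal/sagittal/horizontal) and vector magnitude; FWHM impulse durations of linear and angular acceleration per component and magnitude |
| PSD | 152 | rectangular-window one-sided periodogram amplitudes: linear acceleration at 10–200 Hz, angular acceleration at 10–180 Hz, 10 Hz steps, 4 channels each |
| wavelet grid | 152 | per-frequency time-max Morlet amplitudes on the same grids |
| wavelet descriptors | 32 | per channel: peak amplitude, its frequency, its timing relative to the time-domain peak, and the 10% bandwidth |
| head-neck model | 51 | linkage kinematics (33) + coupling ratios (18), below |

With N = 100 at 1000 Hz the DFT bins fall exactly on the 10 Hz grid, so
"PSD at 10–200 Hz in 10 Hz intervals" needs no interpolation; the raw
periodogram (no detrend, boxcar window) satisfies Parseval exactly. The
180 Hz angular ceiling respects the 184 Hz gyroscope bandwidth; 200 Hz
for linear keeps clear of undersampling. PSD values are one-sided power
densities (units²/Hz) — "amplitude" conventions vary; this one is pinned
and tested against direct DFT sums.

The Morlet transform uses the analytic wavelet with centre frequency
ω₀ = 6 (PyWavelets `cmor2.0-0.9549`), amplitudes as the modulus, no
cone-of-influence masking (the window is only 100 ms and truncation
affects all recordings identically). "Change in" velocity per directional
component is max − min over the window; for the magnitude series it is
the max (a magnitude change is sign-ambiguous; this choice is pinned).
Directional maxima use |·| so left- and right-going impacts score alike.
FWHM is measured about the global peak with linear sub-sample
interpolation, clamped at window edges, 0 for an all-zero series. The
10% bandwidth searches upward from the peak frequency for the first grid
point whose time-max amplitude falls below 10% of the scalogram maximum
(full remaining span if none does). A zero channel yields descriptors
(0, lowest grid frequency, 0, 0).

## Head-neck linkage model

A head rigid body rides on a neck link (length 10.8 cm) through a
universal joint — rotation about LR (atlanto-occipital flexion) then IS
(atlanto-axial axial rotation) — with the head CoG 5 cm above the joint.
Head pose over the window is integrated from the signals: orientation by
per-step exponential map of the body-frame angular velocity (midpoint
rule), CoG position by double trapezoid integration of the CoG-transformed
acceleration rotated into the world frame; identity/zero initial
conditions.

Given the head pose, orientation splits as R_head = R_neck · R_LR(θ₁) ·
R_IS(θ₂): three equations, five rotational unknowns, leaving a
2-parameter family. The torso attachment (neck base) is required to move
least from its initial position — the massive-torso assumption — which
closes the system. That minimisation has a closed form: writing the neck
axis in the head frame as u(θ₁, θ₂), the base is B = J − L·R_head·u with
J the head-base joint point, and |B − B₀| over unit u is minimised by
aligning u with the head-frame direction of (J − B₀), giving
d = ||J − B₀| − L|. Angles are recovered on the (−π/2, π/2) branch;
samples whose optimal axis leaves the branch are flagged and carried from
the previous sample. B₀ sits one neck length along the head's initial
−IS axis, which makes d invariant under a global rigid rotation of the
whole trajectory (tested). A consequence worth noting: pure head
translation with fixed orientation is solved with a small neck tilt and
d = √(L²+Δ²) − L, strictly smaller than the displacement Δ a
rigidly-vertical neck would imply — the minimiser is taken seriously
rather than the intuitive zero-angle configuration.

Model features (33): percent time the head-neck joint angles agree in
sign with the same-plane neck-torso angles (angles within 1e-3 rad count
as matching either sign, so a stationary window scores 100%); peak
|angles|, angular velocities and accelerations of the five angle series;
peak displacement/velocity/acceleration of the torso-base, head-base and
head-CoG points; per-axis CoG displacement and velocity peaks; peak base
offset d. Coupling ratios (18): the six series of angular acceleration
about each axis over linear acceleration along each normal axis, with
samples below a 0.5 g denominator deadband excluded (all-excluded series
report zeros); mean, standard deviation, and peak |ratio| of each.

## Infrared placement and ground truth

Per subject-event, a two-component 1-D Gaussian mixture is fitted to the
IR readings (EM, deterministic initialisation at the 25th/75th
percentiles, fixed seed) and the threshold is the weighted-density
crossing between the component means (root-bracketed on the log-density
difference). The fit is degenerate — midpoint fallback, flagged — when
the means are closer than 2.5 pooled sd: EM splits even unimodal data
into components ~1.9 pooled sd apart, while genuinely bimodal
on/off-teeth readings sit near 6. Readings at the threshold classify as
on-teeth.

Ground-truth rules are conjunctive and order-independent:

* **impact**: on-teeth ∧ matched to a helmet-contact interval dilated by
  ±2 s (1 s timestamp resolution plus synchronisation error) ∧ direction
  consistent ∧ not high-frequency noise;
* **nonimpact**: on-teeth ∧ timestamp strictly inside a no-contact or
  idle interval (no dilation — dilation exists to catch clock skew on
  impacts) ∧ no contact-like or view-limited interval matching under
  dilation;
* anything else is excluded, never re-labeled. Overlapping categories
  resolve by precedence helmet contact > view-limited > body contact >
  quiet.

Direction consistency: the peak linear-acceleration vector *or* the
end-of-window Δv vector must lie in a 90° cone about the sector axis of
the video direction, with acceleration pointing away from the impacted
surface (frontal → −AP, rear → +AP, left → −LR, right → +LR, top → −IS;
LR = +left, so a blow to the player's left pushes the head rightward).
The 90° aperture and the axis mapping are configurable — video
conventions vary.

High-frequency rejection compares periodogram power of the
linear-acceleration magnitude above 200 Hz against 0–200 Hz, *excluding
the DC bin*: the magnitude series is nonnegative, so its mean is an
offset, not band content, and counting it would let any signal pass. The
rule catches sustained electronics oscillation (whose rectified power
sits at twice the carrier, above 200 Hz even after folding); brief
broadband clacks demodulate into low-frequency envelope content and are
legitimately retained for the classifier to handle.

## Classifier

RBF-kernel SVM; C = 1, γ = 1/d on standardised features, decision
threshold 0 — all recorded in the serialised model and configurable,
since these defaults are a choice, not a given. Greedy forward selection
scores every candidate feature set by a LOOCV cost, either 1 − AUC or
1 − F-measure; a candidate is accepted only on strict improvement, ties
break toward the lowest registry index, and selection also stops at 10
features or zero cost. Standardisation statistics are recomputed inside
every fold; the held-out sample never touches them (tested by manual fold
reconstruction). A fold whose training labels collapse to one class is
flagged and scored 0, conserving n. ROC/PR curves sweep the unique
scores with ties grouped; areas are trapezoidal; the PR curve extends to
recall 0 at its first precision value (one of several conventions —
pinned). Reported percentages round to one decimal, half away from zero.
The baseline classifier thresholds the peak linear-acceleration magnitude
with identical sweep semantics.

Screening statistics: two-sided Mann-Whitney U per feature (exact null
up to a smaller sample of 8 without ties, else the continuity- and
tie-corrected normal approximation; identical samples report p = 1),
Bonferroni over the full 411-feature registry (threshold 0.05/411 ≈
1.22e-4 — the family is the registry even when some features are
degenerate, which score p = 1); PCA on the standardised matrix with
zero-variance columns dropped; Pearson correlations with zero-variance
columns reported as 0 and flagged.

## Synthetic cohorts

The generator emulates the study's phenomenology so the whole pipeline is
testable without field data; its defaults are the study conditions and
are not tuned per run.

* **Impacts**: a half-sine pulse, 8–30 ms, opening 2 ms before the
  trigger; peak amplitude 10 g floor plus an exponential tail of scale
  12 g clipped at 65 g, reproducing the published right-skewed
  distribution (mean ≈ 22 g, median ≈ 19 g). The pulse direction is drawn
  within a 20° cone about the video sector axis (real blows are oblique;
  together with a body sway capped at 0.15 g during impacts, the margin
  keeps the 45° direction check satisfied by construction even for the
  weakest pulses). Coherent 20–80 Hz angular velocity rides under a
  pulse-length envelope. 40% of impacts carry brief (σ 0.8–1.6 ms)
  post-pulse high-frequency ringing with crest 0.8–1.35× the pulse peak,
  crest-aligned to the sampling grid — the jaw/device clack documented
  for this sensor generation — with energy capped below the
  high-frequency rejection threshold.
* **Nonimpacts**: one to three brief (σ 0.3–1.2 ms) 120–350 Hz spikes,
  peak 10 g floor plus an exponential tail of scale 8.5 g clipped at
  104 g (mean ≈ 18.5 g, median ≈ 16 g); a sustained 40–90 Hz quadrature
  jostle bout (1.5–5 g, σ 10–25 ms) and a few-Hz quadrature body sway
  (0.5–3 g) supplying genuine velocity change and head displacement, as
  running and device handling do; angular content as filtered high-band
  spikes plus a quadrature head-shake bout (0.3–3 rad/s).
* **Placement**: IR readings bimodal with modes 6 pooled sd apart
  (100 ± 20 vs 220 ± 20), each mode truncated at 2.5 sd so planted
  placement truth is decidable by construction. Off-teeth recordings
  reuse the nonimpact signal model with a low-mode draw.
* **Timeline**: events 30 s apart; each impact gets a helmet-contact
  interval offset by a clock skew within ±1 s; nonimpacts sit strictly
  inside long quiet intervals; no-view confounders are planted to
  exercise exclusion. White noise: 0.5 g RMS acceleration, 0.2 rad/s
  angular.

The mixture of mechanisms is deliberate: peak kinematics, velocity
changes, pulse widths, displacement and peak wavelet frequencies all
overlap between classes (as the published distributions do), while
low-frequency (10–30 Hz) spectral power remains structurally higher for
impacts — pulses put amplitude × duration into that band, spikes and
sub-trigger jostle cannot. Passing end-to-end tests on these cohorts
therefore demonstrates that the pipeline finds the *right kind* of
feature and rejects the plants it should; it does not demonstrate
performance on real mouthguard data, whose artifact families (chewing,
loose coupling, multi-impact windows) are richer than this model.

What the default cohort does **not** emulate: subject-to-subject
calibration spread (identity rotation, fixed 2–3 cm lever arm),
drift/bias, multiple impacts per window, class imbalance, inter-rater
label noise.

## Problem sizes and runtime

Default end-to-end cohort: 60 impacts + 60 nonimpacts + 100 off-teeth +
3 confounders, chosen to exercise every rule while keeping forward
selection (411 candidates × n LOOCV folds per step) at a few minutes on
one core. The published-cohort-scale flow test uses 156 + 231 with
selection bypassed by a pinned feature list. IR threshold recovery uses
100 replicates of 20000 readings each (event-scale continuous placement
sampling): the density crossing sits in the component tails, so its
recovery error scales like sd/√n amplified by tail sensitivity, and the
0.1 pooled-sd tolerance corresponds to reading counts of this order.

## Known limitations

* The six-unknown linkage inversion assumes the optimal neck axis stays
  on the principal joint branch; violent inversions are carried over and
  flagged rather than solved on a secondary branch.
* The 51-feature model block admits more than one reasonable
  enumeration; this registry's (sign-match 2, angles 15, point
  kinematics 9, CoG components 6, base offset 1, ratios 18) is pinned
  and versioned so tables and models refuse silent mismatches rather
  than coercing across variants.
* Rank-sum p-values switch regimes at a smaller-sample size of 8;
  near the boundary the approximation can deviate ~10% from enumeration
  at very small p.
* The IR threshold assumes bimodality; single-mode events fall back to a
  flagged midpoint and should be reviewed.
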