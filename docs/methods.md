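# Methods

## Problem and model

`sit2stand` reconstructs the sagittal-plane angular kinematics of
sit-to-stand and stand-to-sit movements for a three-segment body model —
shank (S), thigh (T) and back (B) — from only two inertial measurement
units, mounted on the shank and the lower back.  Each instrumented
segment is treated as a rigid link pivoting about a fixed joint (ankle,
hip); joint translation is neglected, which is exact for the ankle (the
foot stays planted) and an approximation for the hip.  With the segment
at angle θ from vertical, angular velocity ω and angular acceleration α,
a sensor at distance L from the pivot measures

    a_x   = g sin θ − L α
    a_y   = g cos θ − L ω²
    gyr_z = ω

in its own frame (y proximal along the segment, x forward, z
mediolateral).  Out-of-plane channels are carried through I/O but ignored
by the model.

## Per-segment state estimation

The state x = [θ, ω, α] evolves under the discrete kinematic integrator
F (θ ← θ + ω ΔT + α ΔT²/2, ω ← ω + α ΔT) with process noise
Q = diag[(ΔT/2)², (0.1 ΔT)², 0.04²] and is observed through the nonlinear
measurement model above with noise R = diag[(g/10)², (g/10)², 0.005²].
An extended Kalman filter linearizes the measurement at the predicted
mean; the covariance update uses the Joseph form plus explicit
symmetrization, keeping P positive semi-definite in floating point.  The
small gyro variance makes ω track the gyroscope tightly while the
accelerometer channels anchor the absolute angle through gravity,
eliminating gyro-integration drift.

Initialization (trials begin seated and still): θ₀ = atan2(mean aₓ, mean a_y)
over the first 25 samples, ω₀ = α₀ = 0, P₀ = diag[0.1², 0.1², 0.5²].
θ is not clamped to any range during filtering.

## Two-tier unsupervised classification

**Tier 1 (stationary vs transition).**  The scalar feature
MA₅(|θ_S ω_S θ_B ω_B|) — a forward five-sample moving average, truncated
at the tail — is near zero whenever either segment is at rest and large
during transitions.  The classification threshold is the right edge of
the first bin of the histogram of the feature's local-maximum values,
with bins anchored at zero and the width set by Scott's rule
h = 3.49 σ̂ m^(−1/3).  Samples strictly above threshold are transitions;
runs of one or two samples disagreeing with both neighbours are flipped,
iterated to a fixed point.  The alternative feature |θ_S ω_S| + |θ_B ω_B|
and peak-vs-all-samples readings are available as configuration options
but are not the default.

A consequence worth knowing: because the threshold is a statistic of the
trial's peak population, it is a heavy-tailed random variable.  Episode
boundaries are typically located within one or two samples, but a trial
combining a weak-amplitude transition with fast high-amplitude ones can
push the threshold high enough to shave up to ~10 samples off that
transition's stand-side edge, and slow transitions with mid-movement
pauses can fragment into multiple detections (see Limitations).

**Tier 2 (naming the states).**  Each transition episode is summarized by
four features: least-squares slopes of ω_S and ω_B against time, and the
net changes of θ_S and θ_B across the episode.  k-means (k = 2, ten
restarts, fixed seed, features z-scored) separates rises from descents;
the cluster with the lower mean net shank-angle change is sit-to-stand
(standing pins the shank near vertical).  With exactly two episodes each
forms its own cluster, so a single pair of movements suffices.
Stationary episodes take the end state of the preceding transition; the
leading episode takes the origin state of the transition that follows.

## Thigh reconstruction

The thigh, uninstrumented, is pinned by posture in stationary states
(θ_T = 90° seated, 0° standing; ω_T = α_T = 0) and crosses between them
along a logistic sigmoid in time — a single-neuron model whose weight w
(per sample) sets the speed, bias b the centre (episode midpoint), gain
G = π/2 the range, and direction input x ∈ {0, 1} (the tier-2 result)
selects the rising or falling branch.  The two branches sum to G at every
instant, so the two directions are exact time mirrors and one fitted w
serves both.  ω_T and α_T are the closed-form derivatives.  w is fitted
by bounded scalar least squares (w ∈ [0, 1], tolerance 1e−6) minimizing
pooled RMSE against reference thigh angles over the detected transition
windows; the default w = 0.135 per sample at 50 Hz.  The raw sigmoid is
used without endpoint rescaling (boundary step < 2% at typical
durations); an affine endpoint-matching mode exists but is off by
default.

## Evaluation battery

NRMSE = RMSE / (max − min of the reference), unitless; normalization by
mean or SD is available as an option.  Bland–Altman agreement reports the
mean difference, the sample SD of differences, and the percentage of
points within mean ± 2 SD (boundary inclusive).  Transition timings are
episode lengths × ΔT, compared across groups with two-sided
Mann–Whitney U tests (exact null when both groups ≤ 20, tie-corrected
normal approximation otherwise) under Bonferroni correction over the
three pairwise contrasts.  Grand-average profiles linearly resample each
transition onto 101 points of normalized time before pointwise averaging.

## Synthetic cohorts

The generator produces ground-truth kinematics, per-sample four-state
labels, and sensor streams rendered through the forward model with
additive Gaussian noise (defaults: accelerometer SD 0.05 m/s², gyroscope
SD 0.005 rad/s — the gyro value mirrors the filter's R; the filter's
accelerometer variance (g/10)² is a tuning value, not a sensor spec).

Design choices, made once for realism and fixed:

- **Transition shape (shank/back):** a finite-support logistic
  (steepness k = 1.0) affinely rescaled to meet the flanking postures
  exactly, with a 3-sample raised-cosine velocity ease-in; the terminus
  stays sharp (knee lock standing up, chair contact sitting down).  Each
  segment moves monotonically between postures.
- **Thigh:** the plain logistic family of the reconstruction model
  (w = 0.135 per sample), since the thigh's motion is temporally
  concentrated between seat-off and full extension.
- **Stationary wobble:** consistent (θ, ω, α) band-limited Gaussian
  processes — slow postural sway (~0.3 Hz, 0.002 rad RMS) and
  physiological 8–12 Hz micro-tremor (0.006 rad/s RMS) — because no human
  is perfectly still, and the peak-histogram threshold rule needs a
  realistic population of near-zero stationary peaks to be well defined.
- **Postures:** standing θ_S = 0.12, θ_B = 0.08 rad (quiet-stance shank
  inclination plus strap-mount tilt); seated angles drawn per participant
  with a physical floor on the seated-minus-standing difference (bent
  knees force the shank back; sitters slouch or recline).
- **Durations:** stationary dwells ≈ 4 s; transition means per group
  preset — YH 1.44/1.55 s, OH 1.80/1.77 s, PwP 2.29/2.18 s
  (rise/descent), with between-participant and within-trial jitter.
- **Pauses (OH/PwP presets):** a brief (~0.15 s) deep velocity notch at
  the transition midpoint, slowing to ~25% of local speed rather than
  freezing — residual motion never quite vanishes in a real pause.
- **Rest tremor (PwP preset):** 4–6 Hz band noise at 0.02 rad/s RMS on
  stationary angular velocity.

Per-participant randomness derives from (seed, participant index) so
cohorts are reproducible and order-independent.

## What the synthetic tests do and do not show

Passing on synthetic cohorts demonstrates internal consistency: the EKF
inverts the very model that rendered the streams, and the thigh truth
follows the family the reconstruction assumes.  Real recordings add
unmodelled effects — sensor-to-segment mounting offsets and calibration
mismatch against motion capture (which dominate angle NRMSE on real
data), hip translation, out-of-plane motion, non-monotone trunk flexion
during transitions, and non-Gaussian sensor artefacts.  Agreement numbers
from the generator are therefore optimistic: shank/back angle NRMSE is
~1–3% here versus ~16–30% reported against optical reference in
comparable real-data settings.

Known limitations:

- The four-way product feature requires monotone segment motion; a
  realistic forward trunk-flexion excursion makes ω_B cross zero
  mid-transition and fragments detection.  The generator deliberately
  omits it; on real data the same mechanism would show up as brief
  mid-transition dips healed (or not) by the spurious-correction rule.
- Slow, paused transitions (OH/PwP presets) run close to the Scott
  threshold and frequently fragment, biasing detected transition times
  well below the generating durations.  Group-level timing comparisons on
  such cohorts reflect the method's fragmentation behaviour, not the true
  movement durations.
- Stationary-state naming is inherited from the transition sequence, so a
  tier-2 error propagates to the adjacent stationary episode.
- The sitting thigh angle is fixed at 90°; people sitting with feet
  tucked or reclining violate this by tens of degrees.

## Numerical conventions

Sample indices are 0-based; episode intervals are half-open [start, end).
Feature value exactly equal to the threshold classifies as stationary.
A degenerate trial (fewer than two feature peaks, or zero spread) raises
a degenerate-data error rather than guessing.  k-means uses Lloyd's
algorithm, 10 restarts, tolerance 1e−6, seed 0 by default.  All
randomness in the generator flows from a single integer seed.  Problem
sizes in the shipped tests and the acceptance script (cohorts of 10–12
participants, 3–5 cycles) were chosen so the full battery runs in well
under a minute while keeping the group statistics stable.
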