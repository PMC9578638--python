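# sit2stand

Three-segment sit-to-stand kinematics from **two** body-worn inertial
sensors.

Sit-to-stand and stand-to-sit transitions are key functional-mobility
events, often degraded in older adults and in people with Parkinson's
disease.  Instrumenting every body segment is uncomfortable and
power-hungry; `sit2stand` reconstructs the sagittal-plane angular
kinematics (angle θ, angular velocity ω, angular acceleration α) of the
**shank, back and thigh** from just a shank IMU and a lower-back IMU, and
simultaneously segments and names the four movement states — sitting,
standing, sit-to-stand (SiSt), stand-to-sit (StSi).  It is written for
movement-analysis researchers and biomedical engineers working with
wearable sensor data.

## Method at a glance

1. **Planar sensor model.**  A segment pivoting about a fixed joint with
   a sensor at distance L measures
   `a_x = g sinθ − Lα`, `a_y = g cosθ − Lω²`, `gyr_z = ω`.
2. **Extended Kalman filter.**  The state `x = [θ, ω, α]` evolves under
   the kinematic integrator `F` with
   `Q = diag[(ΔT/2)², (0.1ΔT)², 0.04²]` and is observed through the model
   above with `R = diag[(g/10)², (g/10)², 0.005²]`; run independently per
   sensor to give shank and back kinematics.
3. **Two-tier unsupervised classification.**  Tier 1 thresholds the
   smoothed feature `MA₅(|θ_S ω_S θ_B ω_B|)` at the right edge of the
   first histogram bin of its peaks (Scott's rule bin width) to split
   stationary from transition episodes; tier 2 clusters each transition's
   4-D descriptor (slopes of ω_S, ω_B; net Δθ_S, Δθ_B) with k-means
   (k = 2) and resolves sitting/standing from the preceding transition.
4. **Thigh reconstruction.**  With no thigh sensor, θ_T is pinned at 90°
   seated / 0° standing and crosses between them along a logistic
   sigmoid `θ_T = G·σ(±w(t−b))` whose speed `w` (default 0.135 per sample
   at 50 Hz) is fitted by least squares against reference data.
5. **Evaluation.**  NRMSE (RMSE over the reference range), Bland–Altman
   agreement, transition timings, and Mann–Whitney U + Bonferroni group
   comparisons.

A synthetic-data module simulates whole cohorts — younger healthy (YH),
older healthy (OH), Parkinson's-like (PwP) — with ground-truth
kinematics, labels, postural sway, physiological tremor, mid-transition
pauses and sensor noise, so the entire pipeline is testable end to end
without any recordings.

## Worked example

```sh
python examples/classify_transitions.py
```

```
feature threshold (Scott's rule): 3.234e-05
detected episodes:
     0.00-   4.02 s  sit
     4.02-   5.54 s  sit_to_stand
     5.54-   9.76 s  stand
     9.76-  11.10 s  stand_to_sit
    ...
four-state sample accuracy vs ground truth: 99.19%
```

The trial contains three sit→stand→sit cycles; the pipeline finds all
six transitions, and 99.19% of samples carry the correct state label —
episode boundaries land within a few 20 ms samples of the true movement
onsets.  Similarly,

```sh
python examples/simulate_and_estimate.py
```

```
shank  theta RMSE = 0.109 deg   omega RMSE = 0.0057 rad/s
back   theta RMSE = 0.082 deg   omega RMSE = 0.0053 rad/s
```

shows the EKF recovering segment angles to a tenth of a degree under
realistic sensor noise, and `examples/reconstruct_thigh.py` fits the
thigh transition speed (`w = 0.1344` on that trial) and rebuilds the
unmeasured thigh angle to within ~1°.  `examples/evaluate_agreement.py`
prints the agreement metrics and the group timing comparison.

## Command line

The same pipeline is available as a thin CLI:

```sh
sit2stand simulate --group YH --participants 3 --cycles 3 --seed 0 --out data/
sit2stand classify --shank data/yh_00_shank.csv --back data/yh_00_back.csv \
    --reference data/yh_00_truth.csv --out results/
sit2stand evaluate --estimated results/kinematics.csv \
    --reference data/yh_00_truth.csv --out agreement.json
```

Streams are plain CSV (`time_s, ax, ay, az, gx, gy, gz`, SI units; XLSX
and g-unit inputs supported); episodes and reports are JSON.  Exit codes:
0 success, 2 input/schema error, 3 degenerate data, 4 numerical failure.

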