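# Methods

This note documents the models, conventions and numerical choices
behind `thermoknee`, and what the synthetic cohort does and does not
emulate.

## Coordinate and unit conventions

Image coordinates are 0-based, origin at the top-left pixel, x right,
y down; keypoints are rounded half-up to pixel centres. Temperatures
are °C, loads kg, board coordinates mm with (0, 0) at the board centre,
x medio-lateral (positive toward the participant's right) and y
antero-posterior (positive forward). Time is seconds from the start of
the recording; slopes are reported in °C/min.

## Synthetic cohort

The generator emulates the statistical structure the analysis relies
on, not anatomy or camera physics.

**Kinematics.** Sit-to-stand cycle periods are drawn uniformly from
3–4 s (the metronome-paced cadence) until the 10-min duration is
filled; only complete cycles are generated and any remainder is spent
sitting, so the cycle count is unambiguous. Within a cycle the knee
centres rise by a raised-cosine vertical excursion (default 40 px).
Phase labels derive from the excursion: sitting below 25 % of the
amplitude, standing above 75 %, transition between — smooth,
differentiable, and with unambiguous labels. A zero-amplitude
configuration is treated as a static standing pose.

**Zone layout.** Six zones per knee (SL, SM, P, LJLA, MJLA, PT) are
placed at fixed anatomical offsets from the knee centre, mirrored
between legs (SM medial of SL above the patella, joint-line areas
lateral/medial below, PT inferior). The offsets, the excursion and the
blob footprint all scale with `layout_scale` so small test frames keep
the same geometry-to-footprint ratio as the default 382×288 frame.
Zone centres are rounded to integer pixels; a layout that leaves the
frame raises a configuration error. Metal skin markers are not
rendered (the keypoint route is marker-free); the ROI route receives
its per-frame displacement externally.

**Thermal field.** Each frame is a uniform skin background (31 °C)
plus one Gaussian deviation per zone (σ = 30 px at full scale),
truncated at 4σ. Where blobs overlap, the deviation of **largest
magnitude** wins rather than summing; together with integer zone
centres and an amplitude stored at generation time this makes the
centre pixel of every zone equal its true temperature **bit-exactly**,
which the exact-recovery tests rely on. Default baselines put the
maximum at SM (32.3 °C) and the minimum at P (30.3 °C), so ROI max/min
extraction lands on those zones by construction. Per-pixel i.i.d.
Gaussian noise (std 0.04 °C, the camera's thermal sensitivity) is
added last. Default trends: SM +0.08 °C/min, P and PT −0.05 °C/min,
other zones flat. `coupling_gain` (default 1 °C/min per unit excess
share) adds warming to the heavier leg's SM zone proportional to its
share above 0.5; `cooling_gain` (default 0) is the analogous extra
cooling of the heavier leg's patella, provided so that cooling-mode
agreement scenarios are constructible at zero noise — without it the
two legs' patella slopes tie exactly and the cooling comparison is
indeterminate.

**Tracker.** Observed keypoints are true centres plus isotropic
Gaussian error with radial RMS 9.3 px (per-axis std 9.3/√2).
Likelihoods are Beta-distributed (concentration 200) around the mean
0.99; a `dropout_prob` fraction of entries (default 1 %) instead draw
uniformly below the 0.5 cut. The paper-grade tracker reports only a
mean likelihood, so the Beta/dropout mixture is a modelling choice.

**Load cells.** The instantaneous board total follows the excursion:
full body mass standing, a 5 % chair-residual sitting, raised-cosine
transitions. The total splits left/right by `left_share` and fore/rear
by `rear_share` (default 0.65); the corner sum equals the total
exactly before noise. Per-cell Gaussian noise defaults to 0.1 kg
(configurable; the acquisition itself is specified unfiltered).

**Determinism.** All randomness derives from the config seed through
fixed sub-stream keys; the thermal-noise stream is keyed by absolute
frame index, so a frame is identical whether rendered alone or in a
batch, and identical configs give bit-identical files.

**What is not emulated.** No photorealistic anatomy, no radiometric
camera model (emissivity, reflected temperature), no clothing or
occlusion, no operator error in ROI placement (the semi-automatic
route is driven by ground-truth knee centres, i.e. an idealized
operator). Consequently the semi-automatic route here can show a
*smoother* trend than the automatic one — its RMSE-vs-trend can come
out below the automatic value, whereas with human operators the
ordering is typically reversed. Passing tests therefore demonstrate
correctness of the computations and recoverability of configured
effects, not field performance on real recordings.

## Extraction

**Frame sampling.** Targets are k·interval for k = 1, 2, … up to the
nominal duration (one frame period past the last timestamp); the t=0
frame is never a target, so a 600 s run yields exactly 20 frames at
30 s and 600 at 1 s. Each target maps to the nearest acquired frame,
ties to the earlier frame (the camera clock need not divide the
interval).

**ROI extrema** scan the ROI clipped to the frame; ties break to the
row-major first occurrence; argument positions are full-frame
coordinates. ROI repositioning preserves size and errors only if the
ROI leaves the frame entirely.

**Keypoint sampling** averages the (2r+1)×(2r+1) window (default r=1,
a 3×3 mean to damp single-pixel noise; r=0 gives single-pixel
exactness) centred at the rounded keypoint, window clipped to the
frame. Entries below the likelihood cut or outside the frame are
omitted and counted — never interpolated; interpolation happens once,
in the comparison stage, where the automatic series is resampled onto
the semi-automatic grid.

**Robust lowess.** The smoother fits each point by weighted linear
regression over its `max(2, ceil(span·n))` nearest neighbours in time
(span default 2 %), with tricube distance weights multiplied by
bisquare robustness weights recomputed for five iterations from the
residuals via the 6·MAD rule. Two numerical guards matter in the
exact-fit regime: residuals at float rounding level (≤ 1e-9 relative)
are treated as an exact fit when computing the robust scale, and
robustness weights only ever decrease across iterations, so a rejected
spike stays rejected instead of oscillating back in. A pure line is
reproduced to ~1e-14 and a single spike in 600 points is suppressed
essentially completely. The filter is idempotent in its design regime
(trend + isolated spikes); on dense noise a second pass contracts the
curve further, as any local smoother does.

## Balance-board processing

The static weight is the median of the totals above their 75th
percentile — robust to the fact that a moving participant spends
little time at the exact peak. Standing/sitting thresholds (80 % /
25 % of static weight) are package choices, config-exposed; the cycle
count is the number of sitting→standing passages. Shares clip negative
corner readings to zero and mark samples invalid below 1 kg total
(0.5 kg per leg for foot-region shares). The asymmetry flag uses the
**mean** standing share with a strict `> 0.52` comparison (the
per-sample maximum is also reported). CoP uses the standard
corner-moment formula with configurable sensor spans (defaults
433 × 238 mm, the published sensor spacing); shares are
span-independent. Corner percentages are time-integrated over standing
samples. No filtering is applied to board data.

## Method comparison

The automatic profile is linearly interpolated onto the semi-automatic
timestamps; edge extrapolation is forbidden (points outside coverage
are dropped and counted) and fewer than three overlapping points is an
error. R² is 1 − SSres/SStot of the OLS fit of automatic on
semi-automatic values, computed on raw profiles by default (a flag
smooths first). The "strong correlation" cutoff defaults to R² ≥ 0.5,
which cleanly separates the strong and weak clusters seen in this kind
of comparison; it is config-exposed. Bland–Altman limits are
bias ± 1.96·sd with the sample (n−1) standard deviation and no
repeated-measures correction. The four canonical comparisons are
ligament-max and patella-min per leg (ROI max ↔ SM zone, ROI min ↔ P
zone).

"Most thermally responsive leg" is operationalized as the OLS slope of
the (smoothed, by default) zone profile: larger slope wins in heating
mode, more negative in cooling mode; slopes within 1e-6 °C/min tie and
the case is excluded as indeterminate. AG / NAG / PAG labels follow
the truth table (both match / neither / exactly one); DAG is accepted
as an alias of NAG. Stratification groups by gender, BMI cutoff
(default 25 kg/m², separating normal-weight from overweight members of
a healthy adult cohort) and the asymmetry flag; empty groups are
reported as absent and single-member groups report an undefined sd.

## Pipeline

A single `RunConfig` (YAML-loadable) is the source of truth; the
effective config, package versions and all statistics are embedded in
`report.json`, which is byte-identical across runs of the same config.
Per-participant seeds derive deterministically from the run seed.
Stage failures abort with the stage name and participant id. Figures
(profile plots, board traces, CoP scatter with corner percentages,
agreement bars, regression and Bland–Altman panels, RMSE comparison)
are rendered for the first participant plus cohort charts.

## Problem sizes

Tests and the acceptance script use the full study conditions wherever
the quantity depends on them: 600 s runs at 20 Hz, automatic
extraction at 1 Hz on full 382×288 frames, default noise, and 20
replicates for the slope-recovery experiment. Logic-only checks whose
outcome is scale-free at zero noise (agreement-label cohorts, pipeline
determinism, I/O round-trips) use shorter runs and `layout_scale`-
reduced frames, which keep the identical geometry ratio.

## Known limitations

* The semi-automatic route is an idealized operator (ground-truth ROI
  placement); real operator variability is not modelled.
* The thermal field is a blob model on a uniform background — suitable
  for testing extraction logic, not for emissivity or radiometric
  studies.
* Keypoint detection itself (network training/inference) is out of
  scope; tracks are inputs.
* Cooling-mode agreement carries no signal unless `cooling_gain` is
  set: with default trends both patellae cool identically and only
  noise separates them.
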