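# Methods

This note documents the models, defaults and numerical choices behind
`hipgait`, and what the synthetic cohort does and does not show about real
recordings.

## The synthetic gait model

The generator (`hipgait.synthetic`) is the package's stand-in for a
clinical cohort; its defaults encode the study conditions the analysis
targets: 24 healthy controls, 20 patients roughly two weeks after THA,
60 Hz sampling, 30 s straight-line walking trials.

**Stride timeline.** Each subject draws a personal stride time and stride
length from group-level normals (healthy 1.10 s / 1.30 m, patient 1.20 s /
1.15 m; between-subject SD 0.08 s / 0.10 m), then per-stride values with
small within-subject SDs (0.02 s / 0.03 m). Left initial contacts (ICs)
start the stride grid; right ICs sit half a stride later; terminal
contacts (TCs) at 60% of each stride (a standard stance fraction).

**Hip angles.** The sagittal hip angle is a fixed 2-harmonic cyclic
template `cos(2πφ) + 0.25·cos(4πφ + 0.6)` scaled per stride so the minimum
equals the subject's extension-peak target and the max−min equals the
stride's ROM. Healthy targets: ROM 40° (flexion +30°, extension −10°).
Per side, subjects carry independent random effects on ROM and extension
peak (SD `inter_subject_sd` = 2°); per stride, ROM jitters with SD
`intra_subject_sd` = 1.5° and the whole waveform shifts by a baseline
jitter of SD 0.75° (stride-to-stride posture variation — without it the
extrema-symmetry features would be implausibly noise-free). Patients get
the configured operated-side deficits: ROM −8°, extension peak +5°
(i.e. less extension). The operated side is drawn uniformly left/right.
Frontal/transverse hip channels are fixed-amplitude sinusoids carried for
realism; they enter no feature.

**Pelvis.** Tilt oscillates at two cycles per stride (its physiological
pattern), obliquity and rotation at one. Group ROM defaults:
healthy 3°/4°/8° (sagittal/frontal/transverse), patient 4°/5°/6° — the
directions follow the clinical picture of increased compensatory tilt and
restricted transverse rotation after THA; the magnitudes are package
defaults, all configurable.

**Trajectories.** The pelvis advances with piecewise-constant speed
L_k/T_k per stride; the anterior heel-minus-pelvis coordinate is
`A·cos(2πφ)` (peak exactly at each IC) and the toe-minus-pelvis coordinate
`−A'·cos(2π(φ−0.6))` (trough exactly at each TC), plus swing-phase
vertical lift. This is a deliberately minimal kinematic model: it makes
coordinate-based event detection exact up to sampling resolution and makes
the heel-position stride length equal the generated stride length, so the
generator's ground truth can certify the segmentation stage. The truth
includes the toe-off of the virtual right stride preceding the first right
IC, since that event lies inside the recording.

**Reference channels.** The paired "reference system" measurement of each
angle is truth + static offset (uniform in ±12.5° by default) + white
noise (SD 0.3°). By default one offset per hip-angle *type* is shared by
both sides (`bilateral_offsets=True`): the calibration-pose misalignment
it models acts on both limbs alike, which is the regime in which symmetry
features — not only ROM features — validate with sub-degree errors despite
double-digit offsets. Setting `bilateral_offsets=False` draws fully
independent per-channel offsets; extrema-symmetry features then shift by
exactly the left/right offset difference (asserted as such in the tests).

**What the generator does not model.** Soft-tissue artefact, sensor drift,
turning strides, force-plate data, raw dynamic IMU signals (only static
calibration records are simulated), inter-system cycle-count mismatch
(both feature tables come from the same detected events, which is why the
Set 1 features validate with exactly zero error — the informative part of
the validation exercise is Set 2), and any demographic covariates. Passing
tests therefore certify the *pipeline mathematics* under controlled
conditions, not clinical performance on real recordings.

## Calibration

Gyroscope bias: component-wise mean of the static record. Accelerometer
bias: algebraic (Kåsa) least-squares sphere fit — solve
`2x·c + (r² − |c|²) = |x|²` for centre `c` and radius `r`. The radius is
estimated jointly rather than fixed at local gravity and is reported next
to the RMS sphere residual as a sanity check. Degenerate (coplanar or
collinear) sample clouds are rejected via the design-matrix singular
values (relative threshold 1e-10) because the centre is then
unidentifiable along the normal direction.

## Joint angles

Relative rotation `parent⁻¹·child`, decomposed with an intrinsic Z–X–Y
Euler sequence (flexion, abduction, internal rotation) — a common
lower-limb convention; the sequence is a parameter. Interface quaternions
are scalar-first; unit norm is enforced to 1e-6. Samples whose middle
angle lies within 1° of ±90° are flagged (gimbal proximity), not
rejected. Recomposition of the decomposed angles reproduces the relative
rotation to ~1e-15, which the tests assert.

## Segmentation

IC = local maxima of anterior heel-minus-pelvis position, TC = local
minima of anterior toe-minus-pelvis position, with a minimum peak
separation of 0.5× the median inter-peak interval from a first
unconstrained pass (a parameter-light guard against double peaks).
Extrema at the array boundaries are not detectable — the first IC of a
trial that starts exactly at foot strike is intentionally not reported.

Stride parameters follow the standard definitions: stride length is the
ground-projected (vertical axis dropped) Euclidean distance between heel
positions at consecutive ipsilateral ICs; cadence is 60 divided by the
ipsilateral-to-contralateral IC interval; speed = stride length / stride
time (an exact identity per emitted stride). Strides without an interior
contralateral IC get NaN cadence and a flag.

Cycle normalization uses endpoint-preserving linear interpolation to 101
points (0–100% inclusive). The duration outlier rule is applied
*two-sided* (mean ± 2 sample SD, ddof = 1) even though the motivating
description is one-sided ("plus 2 SD"); two-sided is the standard practice
and the one-sided mode remains available. Bounds are computed once from
the input durations, so re-applying the rule to its own output is not
guaranteed idempotent — this is deliberate and tested.

## Features

Symmetry features are signed left − right (an operated-minus-nonoperated
view is provided for patient trials). "Maximum extension" is the minimum
of the sagittal hip angle, extension being negative. Set 1 values are
constant across the cycle they index and come from the stride that starts
at the cycle's IC. Feature tables are ordered by (subject, cycle) and
written with 17 significant digits for lossless round trips.

## Validation statistics

RMSE/MAE are computed per subject over that subject's cycles, then
averaged across subjects; the 95% CI is the t-based CI of the
across-subject mean (`mean ± t₀.₉₇₅,ₙ₋₁·SD/√n`) — the CI construction is
recorded in the report metadata since other conventions exist. r/r² are
pooled over all cycles. The CMC is the Kadaba within-condition form; when
the between-waveform variance exceeds the total variance the root is
imaginary and the result is reported as undefined with a reason code,
never clamped to 0. The group test is a pooled-variance two-sample t-test
(Welch optional); normality is screened with a χ² goodness-of-fit test
against a fitted normal (Sturges bins, tail bins merged to expected ≥ 5,
dof = bins − 3), returning an inconclusive `None` below 8 samples.

## Classification

The SVM protocol is fixed: RBF kernel, C = 1.7, standardize = true,
stratified 12-fold CV, per-cycle cases. "Kernel scale auto" is a
toolbox-internal heuristic in the original setting; here it is defined as
the median pairwise Euclidean distance between the standardized training
samples of each fold (γ = 1/scale²), with a fixed scalar available.
Standardization statistics are computed on each training fold only.
Per-cycle folding mirrors the study design but leaks subject identity
across folds; an optional subject-grouped CV mode
(`group_by_subject=True`) is provided for leakage-free estimates. The
positive class defaults to *patient* (clinically conventional) and is
configurable — reported sensitivities/specificities always state it.

AUC uses the rank statistic with averaged ties (equivalent to trapezoidal
ROC integration) and is cross-checked against an exhaustive pair-counting
oracle and scikit-learn in the tests.

MRMR uses the greedy mutual-information difference criterion
(relevance I(f; label) minus mean redundancy I(f; selected)) with
equal-frequency 10-bin discretization before MI estimation. Constant
features carry zero relevance and are appended last deterministically;
score ties break on column order.

## Problem sizes and determinism

Default analysis runs use 24 + 20 subjects at 30 s per trial (~1000 gait
cycles); the test suite uses 15–20 s trials and 5 + 5-subject cohorts
where cohort size is not the point. All randomness flows from a single
seed through `numpy.random.SeedSequence` spawns; pipeline outputs are
written with sorted JSON keys and fixed float formats, making repeat runs
byte-identical (tested).

## Known limitations

- The event detector assumes straight, forward walking with a monotone
  pelvis trajectory; it has no turning-stride handling.
- The χ² normality check is a coarse screen at small n.
- Per-cycle CV accuracy should be read as an upper bound; use the
  subject-grouped mode for deployment-style estimates.
- Classification accuracies obtained on synthetic cohorts characterize
  the pipeline under the configured effect sizes, not clinical
  performance.
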