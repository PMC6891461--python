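# hipgait

IMU-based gait analysis for discriminating the gait of patients after
total hip arthroplasty (THA) from healthy gait.

Shortly after hip replacement, patients typically walk with a reduced
sagittal hip range of motion (ROM) and a diminished extension peak on the
operated side, an altered pelvis motion, and shorter, slower strides.
`hipgait` implements the full analysis chain a wearable-sensor gait lab
needs to turn joint-angle and foot/pelvis trajectory recordings into a
clinical classification:

1. **IMU calibration** — gyroscope bias as the static sample mean;
   accelerometer bias as the centre of the least-squares gravity sphere
   through multi-orientation static samples.
2. **Joint angles** — Euler decomposition (intrinsic Z–X–Y:
   flexion, abduction, internal rotation) of the parent⁻¹·child relative
   segment rotation.
3. **Gait-cycle segmentation** — initial/terminal contacts from the
   anterior heel-(toe-)minus-pelvis coordinate extrema; each stride
   resampled to the 0–100% gait-cycle axis (101 points); cycles outside
   mean ± 2 SD of the cycle duration discarded.
4. **Features** — per gait cycle: *Set 1* (spatio-temporal): stride length,
   stride time, cadence, speed; *Set 2* (joint-kinematic): left−right
   sagittal hip ROM / max-flexion / max-extension symmetry, and pelvis ROM
   in the sagittal, frontal and transverse planes. ROM and symmetry
   features are chosen to be robust to the static joint-angle offsets that
   sensor-to-segment calibration leaves behind.
5. **Validation statistics** — per-subject RMSE/MAE (mean ± SD across
   subjects, t-based 95% CI), pooled Pearson r and r², range-of-motion
   error (ROME), the Kadaba coefficient of multiple correlation
   `CMC = √(1 − [Σ(Y_pt − Ȳ_t)²/(T(P−1))] / [Σ(Y_pt − Ȳ)²/(PT−1)])`,
   and two-sample t-tests with a χ² normality check.
6. **Classification** — RBF-kernel SVM (box constraint C = 1.7, kernel
   scale "auto" = median pairwise distance on standardized training
   features, stratified 12-fold cross-validation, per-cycle cases), with
   pooled confusion-matrix metrics
   `ACC = (TN+TP)/(TP+TN+FP+FN)·100`, `SEN = TP/(TP+FN)·100`,
   `SPEC = TN/(TN+FP)·100` and rank-statistic AUC, plus greedy
   minimum-redundancy maximum-relevance (MRMR) feature ranking.

Because clinical gait recordings cannot be redistributed, the package
ships a first-class **synthetic cohort generator** (`hipgait.synthetic`)
that emulates the two groups — 24 healthy controls and 20 post-THA
patients by default — including ground-truth events, configurable
operated-side deficits, and a paired "reference system" channel formed by
adding static per-channel offsets (up to 12.5°) and noise to the truth
waveforms. Every stage of the pipeline is tested against this generator's
ground truth.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_validate_features.py
python analysis/03_classify.py
python analysis/04_rank_and_correlate.py
```

On the default seeded cohort this prints (abridged):

```
1043 gait cycles validated ({'healthy': 594, 'patient': 449})
feature                   RMSE     MAE   r
hip_rom_sym_deg          0.441   0.349   0.9971
pelvis_trans_rom_deg     0.645   0.603   0.9876
max Set 2 RMSE: 0.741 deg (< 1.3 deg)

set1: ACC  95.6%  SEN  91.8%  SPEC  98.5%  AUC 0.977
set2: ACC  98.3%  SEN  97.6%  SPEC  98.8%  AUC 0.998

MRMR ranking: 1. speed_mps  2. hip_rom_sym_deg  3. pelvis_trans_rom_deg ...
r(speed, stride_time)   = -0.80
r(speed, stride_length) = +0.91
```

Reading: even though the paired reference channels carry static offsets up
to 12.5°, every joint-kinematic feature validates with an RMSE well below
1.3° — the offsets cancel in ROM and symmetry features. The SVM trained on
the joint-kinematic Set 2 separates post-THA from healthy gait better than
the spatio-temporal Set 1, and hip ROM symmetry and gait speed carry the
most class information.

The same stages are available as a CLI (`hipgait simulate | calibrate |
segment | extract-features | validate | classify | rank | run`); `hipgait
run --out dir --seed N` executes everything and writes a manifest; two
runs with the same config and seed are byte-identical.

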