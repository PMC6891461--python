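"""Per-gait-cycle feature computation and feature-table assembly.

Two feature sets are computed for every retained gait cycle:

* **Set 1** — spatio-temporal parameters: stride length (m), stride time
  (s), cadence (steps/min), speed (m/s).
* **Set 2** — joint-kinematic features (deg): left-minus-right sagittal hip
  ROM, maximum-flexion and maximum-extension symmetry, and pelvis ROM in the
  sagittal, frontal and transverse planes.

"Maximum extension" is realized as the minimum of the sagittal hip angle
(extension negative, standard clinical convention). Symmetry features are
signed left minus right. ROM features are invariant to static per-channel
offsets; the two extrema-symmetry features are invariant to a *common*
offset on both sides and shift by exactly the offset difference under
side-specific offsets.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .segmentation import (GaitCycle, N_CYCLE_POINTS, detect_gait_events,
                           compute_stride_parameters, segment_gait_cycles,
                           outlier_mask)
from .synthetic import TrialRecording

__all__ = [
    "SET1_COLUMNS",
    "SET2_COLUMNS",
    "FEATURE_COLUMNS",
    "TABLE_COLUMNS",
    "compute_set2",
    "build_feature_table",
    "feature_correlation_matrix",
]

SET1_COLUMNS = ["stride_length_m", "stride_time_s", "cadence_spm", "speed_mps"]
SET2_COLUMNS = ["hip_rom_sym_deg", "hip_maxflex_sym_deg", "hip_maxext_sym_deg",
                "pelvis_sag_rom_deg", "pelvis_front_rom_deg",
                "pelvis_trans_rom_deg"]
FEATURE_COLUMNS = SET1_COLUMNS + SET2_COLUMNS
TABLE_COLUMNS = ["subject_id", "cycle_index", "label"] + FEATURE_COLUMNS

# pelvis channel -> anatomical plane feature
_PELVIS_PLANES = {"pelvis_tilt": "pelvis_sag_rom_deg",
                  "pelvis_obliquity": "pelvis_front_rom_deg",
                  "pelvis_rotation": "pelvis_trans_rom_deg"}


def _check_cycle(cycle: GaitCycle) -> np.ndarray:
    v = np.asarray(cycle.values, float)
    if v.shape != (N_CYCLE_POINTS,):
        raise ValueError(f"cycle must have {N_CYCLE_POINTS} samples")
    return v


def compute_set2(left_hip_sagittal: GaitCycle, right_hip_sagittal: GaitCycle,
                 pelvis_cycles: dict[str, GaitCycle]) -> dict[str, float]:
    """Set 2 features for one stride (all cycles aligned to the same IC)."""
    left = _check_cycle(left_hip_sagittal)
    right = _check_cycle(right_hip_sagittal)
    out = {
        "hip_rom_sym_deg": float((left.max() - left.min())
                                 - (right.max() - right.min())),
        "hip_maxflex_sym_deg": float(left.max() - right.max()),
        "hip_maxext_sym_deg": float(left.min() - right.min()),
    }
    for channel, feature in _PELVIS_PLANES.items():
        v = _check_cycle(pelvis_cycles[channel])
        out[feature] = float(v.max() - v.min())
    return out


def operated_side_view(row_operated_side: str, set2: dict[str, float]
                       ) -> dict[str, float]:
    """Re-sign the symmetry features as operated minus non-operated."""
    sign = 1.0 if row_operated_side == "left" else -1.0
    out = dict(set2)
    for key in ("hip_rom_sym_deg", "hip_maxflex_sym_deg", "hip_maxext_sym_deg"):
        out[key] = sign * out[key]
    return out


_FEATURE_CHANNELS = ("hip_flexion_left", "hip_flexion_right",
                     "pelvis_tilt", "pelvis_obliquity", "pelvis_rotation")


def trial_cycles(trial: TrialRecording, channel_source: str = "truth"
                 ) -> tuple[list[dict[str, GaitCycle]], list, np.ndarray]:
    """Segment one trial into per-stride cycle bundles.

    Events are always detected from the marker trajectories; ``channel_source``
    selects whether the angle waveforms come from the trial's truth channels
    or from the paired reference-system channels. Returns the retained cycle
    bundles (keyed by channel name), the matching left-side stride parameters
    and the retain-mask applied by the duration outlier rule.
    """
    if channel_source == "truth":
        source = trial.channels
    elif channel_source == "reference":
        if trial.reference_channels is None:
            raise ValueError(f"trial {trial.subject_id} has no reference channels")
        source = trial.reference_channels
    else:
        raise ValueError("channel_source must be 'truth' or 'reference'")

    events = detect_gait_events(trial.positions, trial.fs)
    if len(events.ic_left) < 2:
        return [], [], np.zeros(0, bool)
    strides = [sp for sp in compute_stride_parameters(
        events, trial.positions, trial.fs, sides=("left",))]
    per_channel = {
        name: segment_gait_cycles(source[name], events.ic_left, trial.fs,
                                  side="left", channel=name)
        for name in _FEATURE_CHANNELS
    }
    durations = np.array([c.duration for c in per_channel["hip_flexion_left"]])
    mask = outlier_mask(durations)
    bundles = []
    kept_strides = []
    for k in np.flatnonzero(mask):
        bundles.append({name: cyc[k] for name, cyc in per_channel.items()})
        kept_strides.append(strides[k])
    return bundles, kept_strides, mask


def build_feature_table(cohort: list[TrialRecording],
                        channel_source: str = "truth") -> pd.DataFrame:
    """Assemble the labeled per-cycle feature table for a cohort.

    One row per retained gait cycle; Set 1 values are attached from the
    stride containing the cycle; rows are ordered by (subject, cycle).
    Subjects with zero retained cycles are skipped with a warning.
    """
    rows = []
    for trial in cohort:
        bundles, strides, _ = trial_cycles(trial, channel_source)
        if not bundles:
            warnings.warn(f"subject {trial.subject_id}: no retained gait "
                          "cycles, skipped", stacklevel=2)
            continue
        for bundle, stride in zip(bundles, strides):
            set2 = compute_set2(bundle["hip_flexion_left"],
                                bundle["hip_flexion_right"],
                                {k: bundle[k] for k in _PELVIS_PLANES})
            rows.append({
                "subject_id": trial.subject_id,
                "cycle_index": stride.index,
                "label": trial.group,
                "stride_length_m": stride.stride_length,
                "stride_time_s": stride.stride_time,
                "cadence_spm": stride.cadence,
                "speed_mps": stride.speed,
                **set2,
            })
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(table):
        table = table.sort_values(["subject_id", "cycle_index"],
                                  kind="stable").reset_index(drop=True)
    return table


def feature_correlation_matrix(table: pd.DataFrame,
                               feature_set: str = "set1") -> pd.DataFrame:
    """Pairwise Pearson r within one feature set.

    Zero-variance features yield NaN rows/columns (pandas convention), which
    callers should treat as undefined.
    """
    cols = {"set1": SET1_COLUMNS, "set2": SET2_COLUMNS,
            "all": FEATURE_COLUMNS}.get(feature_set)
    if cols is None:
        cols = list(feature_set) if not isinstance(feature_set, str) else None
    if cols is None:
        raise ValueError("feature_set must be 'set1', 'set2', 'all' or a list")
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    return table[cols].corr(method="pearson")
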