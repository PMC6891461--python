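"""Synthetic gait-cohort generator.

Produces seeded cohorts of healthy and post-THA walking trials with the
statistical structure the downstream analysis assumes:

* bilateral sagittal/frontal/transverse hip angles and global pelvis angles
  built from a smooth 2-harmonic cyclic template with per-stride amplitude
  and timing jitter plus subject-level random effects;
* on the operated side of patients, a reduced sagittal hip range of motion
  and a raised (less negative) extension peak;
* heel/toe/pelvis trajectories whose anterior heel-minus-pelvis (resp.
  toe-minus-pelvis) coordinate peaks (resp. bottoms out) exactly at the
  ground-truth initial-contact (resp. terminal-contact) events, so that
  coordinate-based event detection can be validated sample-accurately;
* an optional paired "reference system" channel per angle, equal to the
  truth waveform plus a static per-channel offset and white noise — the
  regime in which offset-invariant features are expected to validate well;
* static IMU calibration records (gyroscope bias + noise; accelerometer
  samples on a gravity sphere around the bias point).

Every function is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CohortConfig

__all__ = [
    "TrialTruth",
    "TrialRecording",
    "CalibrationRecord",
    "generate_subject",
    "generate_cohort",
    "add_reference_channel",
    "simulate_static_imu",
    "ANGLE_CHANNELS",
    "POSITION_KEYS",
]

ANGLE_CHANNELS = (
    "hip_flexion_left", "hip_flexion_right",
    "hip_abduction_left", "hip_abduction_right",
    "hip_rotation_left", "hip_rotation_right",
    "pelvis_tilt", "pelvis_obliquity", "pelvis_rotation",
)
POSITION_KEYS = ("heel_left", "heel_right", "toe_left", "toe_right", "pelvis")

# fraction of the gait cycle spent in stance (terminal contact at 60%)
_STANCE_FRACTION = 0.6

# fixed amplitudes (deg) of the non-sagittal hip channels; these are carried
# for realism but never enter the feature sets
_HIP_ABDUCTION_AMP = 5.0
_HIP_ROTATION_AMP = 4.0


def _hip_shape(phase: np.ndarray) -> np.ndarray:
    """Unit-free cyclic template for the sagittal hip angle.

    Peak flexion near initial contact (phase 0), peak extension in terminal
    stance, with a secondary harmonic for a realistic asymmetric profile.
    """
    return np.cos(2 * np.pi * phase) + 0.25 * np.cos(4 * np.pi * phase + 0.6)


_SHAPE_GRID = _hip_shape(np.linspace(0.0, 1.0, 20001))
_SHAPE_MIN = float(_SHAPE_GRID.min())
_SHAPE_RANGE = float(_SHAPE_GRID.max() - _SHAPE_GRID.min())


@dataclass
class TrialTruth:
    """Ground-truth events and per-stride parameters of a synthetic trial."""

    ic_left: np.ndarray
    ic_right: np.ndarray
    tc_left: np.ndarray
    tc_right: np.ndarray
    stride_times: dict[str, np.ndarray]
    stride_lengths: dict[str, np.ndarray]
    hip_rom: dict[str, np.ndarray]  # per-stride sagittal ROM, deg
    hip_flexion_peak: dict[str, float]  # subject-level targets, deg
    hip_extension_peak: dict[str, float]

    def to_jsonable(self) -> dict:
        return {
            "ic_left": self.ic_left.tolist(),
            "ic_right": self.ic_right.tolist(),
            "tc_left": self.tc_left.tolist(),
            "tc_right": self.tc_right.tolist(),
            "stride_times": {k: v.tolist() for k, v in self.stride_times.items()},
            "stride_lengths": {k: v.tolist() for k, v in self.stride_lengths.items()},
            "hip_rom": {k: v.tolist() for k, v in self.hip_rom.items()},
            "hip_flexion_peak": dict(self.hip_flexion_peak),
            "hip_extension_peak": dict(self.hip_extension_peak),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "TrialTruth":
        arr = np.asarray
        return cls(
            ic_left=arr(d["ic_left"], float),
            ic_right=arr(d["ic_right"], float),
            tc_left=arr(d["tc_left"], float),
            tc_right=arr(d["tc_right"], float),
            stride_times={k: arr(v, float) for k, v in d["stride_times"].items()},
            stride_lengths={k: arr(v, float) for k, v in d["stride_lengths"].items()},
            hip_rom={k: arr(v, float) for k, v in d["hip_rom"].items()},
            hip_flexion_peak={k: float(v) for k, v in d["hip_flexion_peak"].items()},
            hip_extension_peak={k: float(v) for k, v in d["hip_extension_peak"].items()},
        )


@dataclass
class TrialRecording:
    """One subject's multi-channel kinematic recording.

    ``channels`` maps angle names (see :data:`ANGLE_CHANNELS`) to 1-D degree
    series; ``positions`` maps marker names to (N, 3) metre trajectories with
    axes (anterior, lateral, vertical). ``reference_channels`` is the paired
    offset-corrupted measurement of the same angles, when attached.
    """

    subject_id: str
    group: str  # "healthy" | "patient"
    operated_side: str  # "left" | "right" | "none"
    fs: float
    channels: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]
    reference_channels: dict[str, np.ndarray] | None = None
    ref_offsets: dict[str, float] | None = None
    truth: TrialTruth | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        lengths |= {len(v) for v in self.positions.values()}
        if len(lengths) > 1:
            raise ValueError("all channels/positions must share length")
        if self.group == "patient" and self.operated_side == "none":
            raise ValueError("patient trials must declare an operated side")
        for key, pos in self.positions.items():
            if not np.all(np.isfinite(pos)):
                raise ValueError(f"non-finite samples in position {key!r}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class CalibrationRecord:
    """Static IMU recording used for bias estimation."""

    gyro: np.ndarray  # (N, 3) rad/s
    accel: np.ndarray  # (N, 3) m/s^2
    true_gyro_bias: np.ndarray | None = None
    true_accel_bias: np.ndarray | None = None


def _phase_and_index(t: np.ndarray, boundaries: np.ndarray,
                     durations: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map sample times to (stride index, within-stride phase).

    Samples before the first boundary get negative phase extrapolated with
    the first stride's duration; samples after the last boundary continue
    into the (virtual) final stride.
    """
    idx = np.clip(np.searchsorted(boundaries, t, side="right") - 1,
                  0, len(durations) - 1)
    phase = (t - boundaries[idx]) / durations[idx]
    return idx, phase


def generate_subject(config: CohortConfig, group: str,
                     subject_seed: int, subject_id: str | None = None
                     ) -> TrialRecording:
    """Generate one synthetic walking trial.

    Raises ``ValueError`` if the configured trial duration is shorter than
    two mean strides (no full gait cycle could be segmented).
    """
    config.validate()
    gp = config.group_params(group)
    rng = np.random.default_rng(subject_seed)
    if subject_id is None:
        subject_id = f"{group[:1]}{subject_seed:08d}"

    if config.trial_duration < 2 * gp.stride_time_mean:
        raise ValueError(
            "trial_duration shorter than two strides: no full gait cycle")

    operated = "none"
    if group == "patient":
        operated = "left" if rng.random() < 0.5 else "right"

    # --- subject-level draws -------------------------------------------------
    stride_time_subj = max(0.5, rng.normal(gp.stride_time_mean, gp.stride_time_sd))
    stride_length_subj = max(0.3, rng.normal(gp.stride_length_mean, gp.stride_length_sd))

    rom_target: dict[str, float] = {}
    ext_peak: dict[str, float] = {}
    for side in ("left", "right"):
        rom = config.hip_rom_healthy + rng.normal(0.0, config.inter_subject_sd)
        ext = config.hip_extension_peak + rng.normal(0.0, config.inter_subject_sd)
        if side == operated:
            rom -= config.delta_rom_operated
            ext += config.delta_extension_operated
        rom_target[side] = max(5.0, rom)
        ext_peak[side] = ext

    pelvis_rom_subj = {
        "pelvis_tilt": gp.pelvis_rom_tilt,
        "pelvis_obliquity": gp.pelvis_rom_obliquity,
        "pelvis_rotation": gp.pelvis_rom_rotation,
    }
    pelvis_subj_sd = 0.5 * config.inter_subject_sd
    pelvis_rom_subj = {k: max(0.5, v + rng.normal(0.0, pelvis_subj_sd))
                       for k, v in pelvis_rom_subj.items()}

    # --- stride timeline -----------------------------------------------------
    durations: list[float] = []
    total = 0.0
    while total <= config.trial_duration:
        T = max(0.4, rng.normal(stride_time_subj, config.stride_time_within_sd))
        durations.append(T)
        total += T
    durations.append(max(0.4, rng.normal(stride_time_subj,
                                         config.stride_time_within_sd)))
    durations_arr = np.asarray(durations)
    boundaries = np.concatenate([[0.0], np.cumsum(durations_arr)])  # left ICs
    n_strides = len(durations_arr)

    lengths = np.maximum(
        0.2, rng.normal(stride_length_subj, config.stride_length_within_sd,
                        size=n_strides))

    # per-stride hip ROM jitter
    rom_per_stride = {
        side: np.maximum(3.0, rom_target[side]
                         + rng.normal(0.0, config.intra_subject_sd,
                                      size=n_strides))
        for side in ("left", "right")
    }
    # stride-to-stride baseline (posture) jitter of the whole hip waveform
    baseline_jitter = {
        side: rng.normal(0.0, 0.5 * config.intra_subject_sd, size=n_strides)
        for side in ("left", "right")
    }
    pelvis_jitter_sd = 0.25 * config.intra_subject_sd
    pelvis_rom_stride = {
        k: np.maximum(0.2, v + rng.normal(0.0, pelvis_jitter_sd, size=n_strides))
        for k, v in pelvis_rom_subj.items()
    }

    # right-foot stride boundaries: half a stride after each left IC
    right_boundaries = boundaries[:-1] + 0.5 * durations_arr
    right_durations = np.diff(right_boundaries)
    right_durations = np.append(right_durations, durations_arr[-1])

    t = np.arange(0.0, config.trial_duration, 1.0 / config.fs)

    idx_l, phase_l = _phase_and_index(t, boundaries[:-1], durations_arr)
    idx_r, phase_r = _phase_and_index(t, right_boundaries, right_durations)

    # --- angle channels ------------------------------------------------------
    channels: dict[str, np.ndarray] = {}
    for side, idx, phase in (("left", idx_l, phase_l), ("right", idx_r, phase_r)):
        rom = rom_per_stride[side][idx]
        shape = _hip_shape(np.mod(phase, 1.0))
        channels[f"hip_flexion_{side}"] = (
            ext_peak[side] + baseline_jitter[side][idx]
            + (shape - _SHAPE_MIN) * (rom / _SHAPE_RANGE))
        channels[f"hip_abduction_{side}"] = (
            _HIP_ABDUCTION_AMP * np.sin(2 * np.pi * phase + 0.3))
        channels[f"hip_rotation_{side}"] = (
            _HIP_ROTATION_AMP * np.cos(2 * np.pi * phase + 1.1))

    channels["pelvis_tilt"] = (
        5.0 + 0.5 * pelvis_rom_stride["pelvis_tilt"][idx_l]
        * np.cos(4 * np.pi * phase_l + 0.4))
    channels["pelvis_obliquity"] = (
        0.5 * pelvis_rom_stride["pelvis_obliquity"][idx_l]
        * np.sin(2 * np.pi * phase_l))
    channels["pelvis_rotation"] = (
        0.5 * pelvis_rom_stride["pelvis_rotation"][idx_l]
        * np.cos(2 * np.pi * phase_l - 0.7))

    # --- positions -----------------------------------------------------------
    # pelvis advances with piecewise-constant speed L_k / T_k per left stride
    speeds = lengths / durations_arr
    pelvis_x_at_boundary = np.concatenate([[0.0], np.cumsum(lengths)])
    pelvis_x = pelvis_x_at_boundary[idx_l] + speeds[idx_l] * (t - boundaries[idx_l])
    pelvis = np.column_stack([
        pelvis_x,
        0.02 * np.sin(2 * np.pi * phase_l),
        0.95 + 0.015 * np.cos(4 * np.pi * phase_l),
    ])

    heel_amp = 0.27 * stride_length_subj
    toe_amp = 0.22 * stride_length_subj

    def foot(side: str, phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lat = 0.1 if side == "left" else -0.1
        ph = np.mod(phase, 1.0)
        swing = ph >= _STANCE_FRACTION
        u = (ph - _STANCE_FRACTION) / (1.0 - _STANCE_FRACTION)
        heel = np.column_stack([
            pelvis_x + heel_amp * np.cos(2 * np.pi * phase),
            np.full_like(phase, lat),
            0.05 + np.where(swing, 0.06 * np.sin(np.pi * np.clip(u, 0, 1)), 0.0),
        ])
        toe = np.column_stack([
            pelvis_x - toe_amp * np.cos(2 * np.pi * (phase - _STANCE_FRACTION)),
            np.full_like(phase, lat),
            0.02 + np.where(swing, 0.08 * np.sin(np.pi * np.clip(u, 0, 1)), 0.0),
        ])
        return heel, toe

    heel_l, toe_l = foot("left", phase_l)
    heel_r, toe_r = foot("right", phase_r)

    positions = {"heel_left": heel_l, "heel_right": heel_r,
                 "toe_left": toe_l, "toe_right": toe_r, "pelvis": pelvis}

    # --- ground truth --------------------------------------------------------
    end = t[-1] if len(t) else 0.0
    ic_left = boundaries[boundaries <= end + 1e-12]
    ic_right = right_boundaries[right_boundaries <= end + 1e-12]
    tc_left = (boundaries[:-1] + _STANCE_FRACTION * durations_arr)
    tc_left = tc_left[tc_left <= end + 1e-12]
    tc_right = right_boundaries + _STANCE_FRACTION * right_durations
    # toe-off of the virtual right stride preceding the first right IC
    tc_pre = right_boundaries[0] - (1.0 - _STANCE_FRACTION) * right_durations[0]
    if tc_pre > 0:
        tc_right = np.concatenate([[tc_pre], tc_right])
    tc_right = tc_right[tc_right <= end + 1e-12]

    n_left_full = len(ic_left) - 1  # complete left strides inside the trial

    def pel_x_of(times: np.ndarray) -> np.ndarray:
        # exact piecewise-linear pelvis trajectory (not grid-sampled)
        k = np.clip(np.searchsorted(boundaries[:-1], times, side="right") - 1,
                    0, n_strides - 1)
        return pelvis_x_at_boundary[k] + speeds[k] * (times - boundaries[k])
    truth = TrialTruth(
        ic_left=ic_left, ic_right=ic_right, tc_left=tc_left, tc_right=tc_right,
        stride_times={
            "left": np.diff(ic_left),
            "right": np.diff(ic_right),
        },
        stride_lengths={
            "left": lengths[:n_left_full],
            "right": np.diff(pel_x_of(ic_right)),
        },
        hip_rom={
            "left": rom_per_stride["left"][:n_left_full],
            "right": rom_per_stride["right"][:max(len(ic_right) - 1, 0)],
        },
        hip_flexion_peak={s: ext_peak[s] + rom_target[s] for s in ("left", "right")},
        hip_extension_peak=dict(ext_peak),
    )

    return TrialRecording(
        subject_id=subject_id, group=group, operated_side=operated,
        fs=config.fs, channels=channels, positions=positions, truth=truth,
        meta={"stride_time_subject": stride_time_subj,
              "stride_length_subject": stride_length_subj,
              "hip_rom_target": rom_target,
              "pelvis_rom_subject": pelvis_rom_subj},
    )


def generate_cohort(config: CohortConfig,
                    attach_reference: bool = False) -> list[TrialRecording]:
    """Generate the full two-group cohort deterministically from config.seed.

    Subject seeds are spawned from the master seed via ``SeedSequence`` so
    that cohorts are reproducible and subjects mutually independent. When
    ``attach_reference`` is true, each trial also carries the paired
    offset-corrupted reference channels drawn with the config's
    ``ref_offset_range`` / ``ref_noise_sd``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_total = config.n_healthy + config.n_patient
    children = ss.spawn(2 * n_total)
    trials: list[TrialRecording] = []
    for i in range(n_total):
        group = "healthy" if i < config.n_healthy else "patient"
        subject_seed = int(children[i].generate_state(1)[0] % (2**31 - 1))
        trial = generate_subject(config, group, subject_seed,
                                 subject_id=f"S{i:03d}_{group}")
        if attach_reference:
            ref_seed = int(children[n_total + i].generate_state(1)[0] % (2**31 - 1))
            trial = add_reference_channel(
                trial, config.ref_offset_range, config.ref_noise_sd, ref_seed,
                bilateral_offsets=config.bilateral_offsets)
        trials.append(trial)
    return trials


def _offset_key(channel: str, bilateral: bool) -> str:
    if bilateral and channel.startswith("hip_"):
        return channel.rsplit("_", 1)[0]  # strip side suffix
    return channel


def add_reference_channel(trial: TrialRecording, offset_range: float,
                          noise_sd: float, seed: int,
                          bilateral_offsets: bool = True) -> TrialRecording:
    """Attach a paired reference-system measurement of every angle channel.

    reference = truth + static offset + white noise. Offsets model the
    calibration-pose misalignment between measurement systems; with
    ``bilateral_offsets`` (default) one offset per hip angle *type* is shared
    by the left and right side, emulating a pose bias that acts on both limbs
    alike. The drawn offsets are stored on the returned trial for test
    introspection.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if offset_range < 0:
        raise ValueError("offset_range must be non-negative")
    rng = np.random.default_rng(seed)
    offsets_by_key = {}
    reference = {}
    offsets = {}
    for name, series in trial.channels.items():
        key = _offset_key(name, bilateral_offsets)
        if key not in offsets_by_key:
            offsets_by_key[key] = float(rng.uniform(-offset_range, offset_range))
        off = offsets_by_key[key]
        noise = rng.normal(0.0, noise_sd, size=len(series)) if noise_sd > 0 else 0.0
        reference[name] = series + off + noise
        offsets[name] = off
    return TrialRecording(
        subject_id=trial.subject_id, group=trial.group,
        operated_side=trial.operated_side, fs=trial.fs,
        channels=trial.channels, positions=trial.positions,
        reference_channels=reference, ref_offsets=offsets,
        truth=trial.truth, meta=dict(trial.meta),
    )


GRAVITY = 9.81  # m/s^2


def simulate_static_imu(bias_gyro, bias_accel, orientations,
                        n_per_orientation: int = 100,
                        noise_sd: float = 0.0,
                        gyro_noise_sd: float = 0.0,
                        seed: int = 0) -> CalibrationRecord:
    """Simulate the boxed-IMU static calibration procedure.

    The IMU rests in each of ``orientations`` (scipy Rotations mapping sensor
    frame to world) for ``n_per_orientation`` samples. The accelerometer
    senses the gravity reaction rotated into the sensor frame plus its bias;
    the gyroscope senses only its bias. White noise of the given SDs is added.
    """
    from scipy.spatial.transform import Rotation

    if len(orientations) < 1:
        raise ValueError("at least one orientation required")
    rng = np.random.default_rng(seed)
    bias_gyro = np.asarray(bias_gyro, float)
    bias_accel = np.asarray(bias_accel, float)
    g_world = np.array([0.0, 0.0, GRAVITY])

    accel_rows = []
    for rot in orientations:
        if not isinstance(rot, Rotation):
            rot = Rotation.from_quat(np.roll(np.asarray(rot, float), -1))
        g_sensor = rot.inv().apply(g_world)
        accel_rows.append(np.tile(g_sensor, (n_per_orientation, 1)))
    accel = np.vstack(accel_rows) + bias_accel
    if noise_sd > 0:
        accel = accel + rng.normal(0.0, noise_sd, size=accel.shape)
    n = accel.shape[0]
    gyro = np.tile(bias_gyro, (n, 1))
    if gyro_noise_sd > 0:
        gyro = gyro + rng.normal(0.0, gyro_noise_sd, size=gyro.shape)
    return CalibrationRecord(gyro=gyro, accel=accel,
                             true_gyro_bias=bias_gyro, true_accel_bias=bias_accel)
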