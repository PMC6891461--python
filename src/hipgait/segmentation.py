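"""Gait-event detection, stride parameters, cycle normalization, outliers.

Events are detected from marker-like trajectories: initial contact (IC) at
local maxima of the anterior heel-minus-pelvis coordinate, terminal contact
(TC) at local minima of the anterior toe-minus-pelvis coordinate, each with
a minimum peak separation of half the median stride time. Waveforms are cut
at consecutive ipsilateral ICs and linearly resampled to 101 points on the
0-100% gait-cycle axis. Cycles whose duration falls outside the cohort of
input durations' mean +- 2 SD (two-sided; bounds computed once on the input)
are discarded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "GaitEvents",
    "GaitCycle",
    "StrideParameters",
    "detect_initial_contacts",
    "detect_terminal_contacts",
    "detect_gait_events",
    "compute_stride_parameters",
    "segment_gait_cycles",
    "remove_outlier_cycles",
    "outlier_mask",
]

N_CYCLE_POINTS = 101  # 0..100% inclusive


@dataclass
class GaitEvents:
    """Ordered IC/TC event times (s) per foot."""

    ic_left: np.ndarray
    ic_right: np.ndarray
    tc_left: np.ndarray
    tc_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ic_left", "ic_right", "tc_left", "tc_right"):
            v = np.asarray(getattr(self, name), float)
            setattr(self, name, v)
            if np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing")

    def ic(self, side: str) -> np.ndarray:
        return self.ic_left if side == "left" else self.ic_right


@dataclass
class GaitCycle:
    """One stride of one channel on the normalized 0-100% axis."""

    values: np.ndarray  # exactly 101 samples
    duration: float  # s
    side: str = ""
    channel: str = ""
    index: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (N_CYCLE_POINTS,):
            raise ValueError(f"cycle must have exactly {N_CYCLE_POINTS} samples")
        if self.duration <= 0:
            raise ValueError("cycle duration must be positive")

    @property
    def rom(self) -> float:
        return float(self.values.max() - self.values.min())


@dataclass
class StrideParameters:
    """Spatio-temporal parameters of one stride.

    stride_length: ground-projected heel displacement between consecutive
    ipsilateral ICs (m); stride_time: IC-to-IC interval (s); cadence: 60
    divided by the ipsilateral-to-contralateral IC interval (steps/min,
    NaN when no contralateral IC falls inside the stride); speed:
    stride_length / stride_time (m/s).
    """

    stride_length: float
    stride_time: float
    cadence: float
    speed: float
    side: str
    index: int
    flags: tuple[str, ...] = ()


def _anterior(traj: np.ndarray) -> np.ndarray:
    traj = np.asarray(traj, float)
    return traj[:, 0] if traj.ndim == 2 else traj


def _detect_extrema(rel: np.ndarray, fs: float, minima: bool) -> np.ndarray:
    signal = -rel if minima else rel
    peaks, _ = find_peaks(signal)
    if len(peaks) >= 2:
        median_interval = float(np.median(np.diff(peaks)))
        distance = max(1, int(round(0.5 * median_interval)))
        peaks, _ = find_peaks(signal, distance=distance)
    return peaks / fs


def detect_initial_contacts(heel_trajectory, pelvis_trajectory,
                            fs: float) -> np.ndarray:
    """IC event times: local maxima of heel-minus-pelvis anterior position."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    heel = _anterior(heel_trajectory)
    pelvis = _anterior(pelvis_trajectory)
    if len(heel) != len(pelvis):
        raise ValueError("trajectories must share length")
    events = _detect_extrema(heel - pelvis, fs, minima=False)
    if len(events) < 2:
        warnings.warn("fewer than 2 initial contacts detected: no strides",
                      stacklevel=2)
    return events


def detect_terminal_contacts(toe_trajectory, pelvis_trajectory,
                             fs: float) -> np.ndarray:
    """TC event times: local minima of toe-minus-pelvis anterior position."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    toe = _anterior(toe_trajectory)
    pelvis = _anterior(pelvis_trajectory)
    if len(toe) != len(pelvis):
        raise ValueError("trajectories must share length")
    return _detect_extrema(toe - pelvis, fs, minima=True)


def detect_gait_events(positions: dict[str, np.ndarray], fs: float) -> GaitEvents:
    """Detect all four event streams from a trial's marker trajectories."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GaitEvents(
            ic_left=detect_initial_contacts(positions["heel_left"],
                                            positions["pelvis"], fs),
            ic_right=detect_initial_contacts(positions["heel_right"],
                                             positions["pelvis"], fs),
            tc_left=detect_terminal_contacts(positions["toe_left"],
                                             positions["pelvis"], fs),
            tc_right=detect_terminal_contacts(positions["toe_right"],
                                              positions["pelvis"], fs),
        )


def _ground(p: np.ndarray) -> np.ndarray:
    """Project a 3-D point onto the ground plane (drop the vertical axis)."""
    return p[..., :2]


def compute_stride_parameters(events: GaitEvents,
                              heel_positions: dict[str, np.ndarray],
                              fs: float,
                              sides: tuple[str, ...] = ("left", "right"),
                              ) -> list[StrideParameters]:
    """Per-stride spatio-temporal parameters from events + heel trajectories.

    Heel positions are sampled at the frame nearest each IC; stride length is
    the ground-plane Euclidean distance between consecutive ipsilateral heel
    positions. A stride with no interior contralateral IC gets NaN cadence
    and a ``no_contralateral_ic`` flag; zero displacement is flagged
    ``implausible_length``.
    """
    out: list[StrideParameters] = []
    for side in sides:
        contra = "right" if side == "left" else "left"
        ics = events.ic(side)
        contra_ics = events.ic(contra)
        heel = np.asarray(heel_positions[f"heel_{side}"], float)
        if len(ics) < 2:
            continue
        n = len(heel)
        for k in range(len(ics) - 1):
            t0, t1 = ics[k], ics[k + 1]
            i0 = min(int(round(t0 * fs)), n - 1)
            i1 = min(int(round(t1 * fs)), n - 1)
            length = float(np.linalg.norm(_ground(heel[i1]) - _ground(heel[i0])))
            stride_time = float(t1 - t0)
            inside = contra_ics[(contra_ics > t0) & (contra_ics < t1)]
            flags: list[str] = []
            if len(inside):
                cadence = 60.0 / float(inside[0] - t0)
            else:
                cadence = float("nan")
                flags.append("no_contralateral_ic")
            if length <= 1e-9:
                flags.append("implausible_length")
            out.append(StrideParameters(
                stride_length=length, stride_time=stride_time,
                cadence=cadence, speed=length / stride_time,
                side=side, index=k, flags=tuple(flags)))
    return out


def segment_gait_cycles(series: np.ndarray, ic_times: np.ndarray, fs: float,
                        side: str = "", channel: str = "") -> list[GaitCycle]:
    """Cut a channel at consecutive ICs and resample each stride to 101 pts.

    Linear interpolation on the normalized 0-100% axis; endpoints map to the
    two bounding ICs exactly.
    """
    series = np.asarray(series, float)
    ic_times = np.asarray(ic_times, float)
    if len(ic_times) < 2:
        raise ValueError("need at least two initial contacts")
    t_max = (len(series) - 1) / fs
    if ic_times[0] < -1e-9 or ic_times[-1] > t_max + 1e-9:
        raise ValueError("IC time outside the recorded series")
    t = np.arange(len(series)) / fs
    cycles = []
    for k in range(len(ic_times) - 1):
        t0, t1 = ic_times[k], ic_times[k + 1]
        grid = t0 + (t1 - t0) * np.linspace(0.0, 1.0, N_CYCLE_POINTS)
        values = np.interp(grid, t, series)
        cycles.append(GaitCycle(values=values, duration=float(t1 - t0),
                                side=side, channel=channel, index=k))
    return cycles


def remove_outlier_cycles(cycles: list[GaitCycle], n_sd: float = 2.0,
                          two_sided: bool = True) -> list[GaitCycle]:
    """Drop cycles whose duration lies outside mean +- n_sd * SD.

    The bounds are computed once from all input durations (sample SD,
    ddof=1); applying the rule to its own output is therefore not guaranteed
    to be a no-op. ``two_sided=False`` removes only over-long cycles.
    """
    if len(cycles) < 2:
        return list(cycles)
    durations = np.array([c.duration for c in cycles])
    mean = durations.mean()
    sd = durations.std(ddof=1)
    upper = mean + n_sd * sd
    lower = mean - n_sd * sd if two_sided else -np.inf
    return [c for c, d in zip(cycles, durations) if lower <= d <= upper]


def outlier_mask(durations: np.ndarray, n_sd: float = 2.0,
                 two_sided: bool = True) -> np.ndarray:
    """Boolean retain-mask for the duration-based outlier rule."""
    durations = np.asarray(durations, float)
    if len(durations) < 2:
        return np.ones(len(durations), bool)
    mean = durations.mean()
    sd = durations.std(ddof=1)
    upper = mean + n_sd * sd
    lower = mean - n_sd * sd if two_sided else -np.inf
    return (durations >= lower) & (durations <= upper)
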