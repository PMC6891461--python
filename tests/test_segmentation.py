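"""Event detection, stride parameters, cycle normalization, outlier rule."""

import numpy as np
import pytest

from hipgait.config import CohortConfig, GroupParams
from hipgait.segmentation import (GaitEvents, GaitCycle,
                                  detect_initial_contacts,
                                  detect_terminal_contacts, detect_gait_events,
                                  compute_stride_parameters,
                                  segment_gait_cycles, remove_outlier_cycles)
from hipgait.synthetic import generate_subject


@pytest.fixture(scope="module")
def noiseless_trial():
    cfg = CohortConfig(trial_duration=20.0, seed=0)
    return generate_subject(cfg, "healthy", 77)


def _event_errors(detected, truth):
    """Per detected event, distance (s) to the nearest ground-truth event."""
    return np.array([np.abs(truth - t).min() for t in detected])


class TestEventDetection:
    def test_ic_within_one_sample_of_truth(self, noiseless_trial):
        tr = noiseless_trial
        ev = detect_gait_events(tr.positions, tr.fs)
        for det, tru in ((ev.ic_left, tr.truth.ic_left),
                         (ev.ic_right, tr.truth.ic_right)):
            assert len(det) >= 10
            assert np.all(_event_errors(det, tru) <= 1.0 / tr.fs + 1e-9)

    def test_tc_within_one_sample_of_truth(self, noiseless_trial):
        tr = noiseless_trial
        ev = detect_gait_events(tr.positions, tr.fs)
        for det, tru in ((ev.tc_left, tr.truth.tc_left),
                         (ev.tc_right, tr.truth.tc_right)):
            assert np.all(_event_errors(det, tru) <= 1.0 / tr.fs + 1e-9)

    def test_constant_trajectories_yield_no_events(self):
        const = np.zeros((100, 3))
        with pytest.warns(UserWarning, match="fewer than 2"):
            ics = detect_initial_contacts(const, const, 60.0)
        assert len(ics) == 0
        assert len(detect_terminal_contacts(const, const, 60.0)) == 0

    def test_time_shift_equivariance(self, noiseless_trial):
        """Prepending k constant samples shifts every event by k/fs."""
        tr = noiseless_trial
        k = 30
        pad = {name: np.vstack([np.tile(p[0], (k, 1)), p])
               for name, p in tr.positions.items()}
        ev = detect_gait_events(tr.positions, tr.fs)
        ev_pad = detect_gait_events(pad, tr.fs)
        shifted = ev.ic_left + k / tr.fs
        matched = [np.abs(ev_pad.ic_left - t).min() for t in shifted]
        assert np.all(np.asarray(matched) <= 1.0 / tr.fs + 1e-9)

    def test_tc_count_tracks_ic_count(self, noiseless_trial):
        tr = noiseless_trial
        ev = detect_gait_events(tr.positions, tr.fs)
        assert abs(len(ev.tc_left) - len(ev.ic_left)) <= 1


class TestStrideParameters:
    def test_worked_example(self):
        """ICs at 0.0/1.2 s, heel ground travel 1.32 m, contra IC at 0.6 s."""
        fs = 10.0
        events = GaitEvents(ic_left=np.array([0.0, 1.2]),
                            ic_right=np.array([0.6, 1.8]),
                            tc_left=np.array([0.7]), tc_right=np.array([1.3]))
        heel_l = np.zeros((19, 3))
        heel_l[12:, 0] = 1.32  # at the second IC the heel is 1.32 m ahead
        heel = {"heel_left": heel_l, "heel_right": np.zeros((19, 3))}
        strides = compute_stride_parameters(events, heel, fs, sides=("left",))
        sp = strides[0]
        assert sp.stride_length == pytest.approx(1.32)
        assert sp.stride_time == pytest.approx(1.2)
        assert sp.speed == pytest.approx(1.1)
        assert sp.cadence == pytest.approx(100.0)

    def test_zero_displacement_flagged(self):
        events = GaitEvents(ic_left=np.array([0.0, 1.0]),
                            ic_right=np.array([0.5]),
                            tc_left=np.array([0.6]), tc_right=np.array([1.1]))
        heel = {"heel_left": np.zeros((11, 3)), "heel_right": np.zeros((11, 3))}
        strides = compute_stride_parameters(events, heel, 10.0, sides=("left",))
        assert strides[0].stride_length == 0.0
        assert "implausible_length" in strides[0].flags

    def test_missing_contralateral_ic_flagged(self):
        events = GaitEvents(ic_left=np.array([0.0, 1.0]),
                            ic_right=np.array([2.5]),
                            tc_left=np.array([0.6]), tc_right=np.array([2.9]))
        heel = {"heel_left": np.zeros((31, 3)), "heel_right": np.zeros((31, 3))}
        strides = compute_stride_parameters(events, heel, 10.0, sides=("left",))
        assert np.isnan(strides[0].cadence)
        assert "no_contralateral_ic" in strides[0].flags

    def test_speed_identity_holds_for_every_stride(self, noiseless_trial):
        tr = noiseless_trial
        ev = detect_gait_events(tr.positions, tr.fs)
        strides = compute_stride_parameters(ev, tr.positions, tr.fs)
        assert len(strides) > 10
        for sp in strides:
            assert sp.speed == pytest.approx(sp.stride_length / sp.stride_time,
                                             rel=1e-12)

    def test_on_grid_noiseless_recovery_is_exact(self):
        """With ICs on the sampling grid and zero jitter, the detected
        stride parameters equal the generator settings to 1e-6."""
        gp = GroupParams(stride_time_mean=1.2, stride_time_sd=0.0,
                         stride_length_mean=1.32, stride_length_sd=0.0)
        cfg = CohortConfig(trial_duration=14.4, fs=60.0, healthy=gp,
                           intra_subject_sd=0.0, inter_subject_sd=0.0,
                           stride_time_within_sd=0.0,
                           stride_length_within_sd=0.0)
        tr = generate_subject(cfg, "healthy", 1)
        ev = detect_gait_events(tr.positions, tr.fs)
        strides = compute_stride_parameters(ev, tr.positions, tr.fs,
                                            sides=("left",))
        assert len(strides) >= 5
        for sp in strides:
            assert sp.stride_time == pytest.approx(1.2, abs=1e-9)
            assert sp.stride_length == pytest.approx(1.32, abs=1e-6)
            assert sp.speed == pytest.approx(1.1, abs=1e-6)


class TestSegmentCycles:
    def test_uniform_ics_give_unit_cycles(self):
        fs = 60.0
        series = np.sin(np.arange(600) * 0.1)
        ics = np.arange(0, 600, 60) / fs
        cycles = segment_gait_cycles(series, ics, fs)
        assert len(cycles) == len(ics) - 1
        for c in cycles:
            assert c.duration == pytest.approx(1.0)
            assert len(c.values) == 101

    def test_linear_ramp_preserved(self):
        fs = 10.0
        series = np.arange(50, dtype=float)
        cycles = segment_gait_cycles(series, np.array([0.0, 2.0]), fs)
        v = cycles[0].values
        np.testing.assert_allclose(v, np.linspace(series[0], series[20], 101),
                                   atol=1e-12)

    def test_periodic_signal_gives_identical_cycles(self):
        fs = 100.0
        period = 1.0
        t = np.arange(0, 10, 1 / fs)
        series = np.sin(2 * np.pi * t / period)
        ics = np.arange(0.0, 9.5, period)
        cycles = segment_gait_cycles(series, ics, fs)
        for c in cycles[1:]:
            np.testing.assert_allclose(c.values, cycles[0].values, atol=1e-9)

    def test_ic_outside_series_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            segment_gait_cycles(np.zeros(30), np.array([0.0, 5.0]), 10.0)


def _mk_cycles(durations):
    return [GaitCycle(values=np.zeros(101) + i, duration=d, index=i)
            for i, d in enumerate(durations)]


class TestOutlierRule:
    def test_worked_duration_example(self):
        """Nine 1.0 s cycles plus one 2.0 s cycle: mean 1.1, SD 0.3162,
        upper bound 1.732 -> exactly the 2.0 s cycle is removed."""
        cycles = _mk_cycles([1.0] * 9 + [2.0])
        kept = remove_outlier_cycles(cycles)
        assert len(kept) == 9
        assert all(c.duration == 1.0 for c in kept)

    def test_equal_durations_keep_all(self):
        cycles = _mk_cycles([1.1] * 12)
        assert len(remove_outlier_cycles(cycles)) == 12

    def test_gaussian_tail_fraction(self, rng):
        durations = rng.normal(1.1, 0.05, size=20000)
        kept = remove_outlier_cycles(_mk_cycles(durations))
        frac_removed = 1 - len(kept) / 20000
        assert 0.035 < frac_removed < 0.06  # two-sided 2-SD tail ~ 4.6%

    def test_one_sided_mode(self):
        cycles = _mk_cycles([1.0] * 9 + [0.2])
        assert len(remove_outlier_cycles(cycles, two_sided=True)) == 9
        assert len(remove_outlier_cycles(cycles, two_sided=False)) == 10

    def test_bounds_computed_once_on_input(self):
        durations = [1.0] * 9 + [2.0]
        kept_once = remove_outlier_cycles(_mk_cycles(durations))
        kept_twice = remove_outlier_cycles(kept_once)
        assert len(kept_twice) == len(kept_once)  # equal durations survive
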