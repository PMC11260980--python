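"""Per-detector contracts against hand-built signals and brute-force scans.

These tests construct signals directly (no synthetic-gait generator), so
the detector logic is exercised independently of the model used elsewhere.
"""

import numpy as np
import pytest

from heelrise.config import DetectionConfig
from heelrise.cycle_segmentation import GaitCycle
from heelrise.event_detection import (METHODS, GaitEvent, detect_all,
                                      detect_hr_acceleration, detect_hr_fp_zc,
                                      detect_hr_imu_acc, detect_hr_imu_jerk,
                                      detect_hr_jerk, detect_hr_position,
                                      detect_hr_velocity, detect_mst)
from heelrise.io import TrialRecording
from heelrise.signal_core import KinematicChain, UniformSeries

RATE = 1125.0
CYCLE = GaitCycle(ic_start=0.0, ic_end=1.0)
CFG = DetectionConfig()
T = np.arange(0, 1.2, 1 / RATE)


def ser(values, units=""):
    return UniformSeries(np.asarray(values, float), rate=RATE, units=units)


def mst_event(t=0.3):
    return GaitEvent(kind="MST", method="MST", detected=True, t=t,
                     cycle_percent=100 * t, mst_t=t)


def chain(position=None, velocity=None, acceleration=None, jerk=None):
    zeros = ser(np.zeros_like(T))
    return KinematicChain(position=ser(position) if position is not None else zeros,
                          velocity=ser(velocity) if velocity is not None else zeros,
                          acceleration=ser(acceleration) if acceleration is not None else zeros,
                          jerk=ser(jerk) if jerk is not None else zeros)


def brute_force_first_reach(f, thr, lo, hi, dense=100_000):
    """Oracle: dense scan of a continuous function for the first time >= thr."""
    tt = np.arange(lo, hi, 1.0 / dense)
    hits = np.nonzero(f(tt) >= thr)[0]
    return None if hits.size == 0 else tt[hits[0]]


class TestDetectMST:
    def test_toe_ahead_at_ic_fires_on_first_sample(self):
        heel = ser(np.full_like(T, 100.0))
        toe = ser(np.full_like(T, 150.0))
        ev = detect_mst(heel, toe, CYCLE)
        assert ev.detected and ev.t == pytest.approx(0.0)
        assert ev.cycle_percent == pytest.approx(0.0)

    def test_linear_crossing_matches_analytic_intersection(self):
        heel = ser(np.full_like(T, 500.0))
        toe = ser(500.0 + 2000.0 * (T - 0.30))  # crosses at t* = 0.30
        ev = detect_mst(heel, toe, CYCLE)
        assert ev.detected
        assert 0.30 <= ev.t < 0.30 + 1 / RATE

    def test_toe_never_reaching_heel_is_undetected(self):
        heel = ser(np.full_like(T, 500.0))
        toe = ser(np.full_like(T, 100.0))
        ev = detect_mst(heel, toe, CYCLE)
        assert not ev.detected and ev.failure_reason == "no-mst"


class TestPositionDetector:
    def test_flat_heel_is_undetected(self):
        ev = detect_hr_position(chain(position=np.zeros_like(T)), mst_event(),
                                3.0, CYCLE, CFG)
        assert not ev.detected and ev.failure_reason == "no-crossing"

    @pytest.mark.parametrize("thr", [3.0, 4.0, 5.0])
    def test_linear_rise_crossing_time(self, thr):
        r = 60.0  # mm/s
        t_mst = 360 / RATE  # on the grid, so the MST reference height is exact
        pos = np.maximum(T - t_mst, 0.0) * r
        ev = detect_hr_position(chain(position=pos), mst_event(t_mst), thr,
                                CYCLE, CFG)
        t_star = brute_force_first_reach(
            lambda tt: np.maximum(tt - t_mst, 0.0) * r, thr, t_mst, 0.9)
        assert ev.detected
        assert abs(ev.t - t_star) <= 1 / RATE
        assert abs(ev.t - (t_mst + thr / r)) <= 1 / RATE

    def test_nested_thresholds_give_ordered_times(self):
        pos = np.maximum(T - 0.3, 0.0) ** 2 * 400.0
        times = [detect_hr_position(chain(position=pos), mst_event(0.3), thr,
                                    CYCLE, CFG).t for thr in (3, 4, 5)]
        assert times[0] <= times[1] <= times[2]

    def test_reference_is_position_at_mst(self):
        # constant offset before MST must not matter (MST-referenced)
        base = np.maximum(T - 0.3, 0.0) * 50.0
        ev0 = detect_hr_position(chain(position=base), mst_event(0.3), 4.0, CYCLE, CFG)
        ev1 = detect_hr_position(chain(position=base + 250.0), mst_event(0.3),
                                 4.0, CYCLE, CFG)
        assert ev0.t == ev1.t


class TestVelocityDetector:
    def test_zero_velocity_is_undetected(self):
        ev = detect_hr_velocity(chain(), mst_event(), 50.0, CYCLE, CFG)
        assert not ev.detected

    @pytest.mark.parametrize("thr", [50.0, 80.0, 100.0])
    def test_constant_acceleration_crossing(self, thr):
        a = 800.0  # mm/s² from MST
        vel = np.maximum(T - 0.3, 0.0) * a
        ev = detect_hr_velocity(chain(velocity=vel), mst_event(0.3), thr, CYCLE, CFG)
        assert ev.detected
        assert abs(ev.t - (0.3 + thr / a)) <= 1 / RATE


class TestAccelerationDetector:
    def test_constant_velocity_rise_is_undetected(self):
        ev = detect_hr_acceleration(chain(), mst_event(), CYCLE, CFG)
        assert not ev.detected

    def test_smoothstep_crossing_within_one_sample_of_root(self):
        x = np.clip((T - 0.35) / 0.2, 0.0, 1.0)
        acc = 10.0 * (x ** 2 * 3 - 2 * x ** 3)  # smooth 0 -> 10 m/s²
        ev = detect_hr_acceleration(chain(acceleration=acc), mst_event(0.3),
                                    CYCLE, CFG)
        t_star = brute_force_first_reach(
            lambda tt: 10.0 * (np.clip((tt - 0.35) / 0.2, 0, 1) ** 2 * 3
                               - 2 * np.clip((tt - 0.35) / 0.2, 0, 1) ** 3),
            CFG.hm_acc_threshold_m_s2, 0.3, 0.6)
        assert ev.detected
        assert abs(ev.t - t_star) <= 1 / RATE


class TestJerkDetector:
    @staticmethod
    def bump(t, c, w, amp):
        inside = np.abs(t - c) < w
        out = np.zeros_like(t)
        out[inside] = amp * np.cos(np.pi * (t[inside] - c) / (2 * w)) ** 2
        return out

    def test_single_rise_takes_the_upward_crossing_before_t_acc(self):
        acc = np.maximum(T - 0.45, 0.0) * 40.0  # crosses 1.9 at ~0.4975
        jerk = self.bump(T, 0.47, 0.05, 40.0)
        ev = detect_hr_jerk(chain(acceleration=acc, jerk=jerk), mst_event(0.3),
                            CYCLE, CFG)
        # brute-force: last upward 15-crossing at or before the acc crossing
        t_acc = 0.45 + 1.9 / 40.0
        tt = np.arange(0.3, t_acc, 1e-5)
        jj = self.bump(tt, 0.47, 0.05, 40.0)
        ups = np.nonzero((jj[1:] >= 15.0) & (jj[:-1] < 15.0))[0]
        t_star = tt[ups[-1] + 1]
        assert ev.detected
        assert abs(ev.t - t_star) <= 1 / RATE

    def test_two_bumps_take_the_later_one(self):
        acc = np.maximum(T - 0.55, 0.0) * 40.0
        jerk = self.bump(T, 0.38, 0.03, 30.0) + self.bump(T, 0.52, 0.03, 30.0)
        ev = detect_hr_jerk(chain(acceleration=acc, jerk=jerk), mst_event(0.3),
                            CYCLE, CFG)
        assert ev.detected
        assert 0.50 < ev.t < 0.52  # rising edge of the second bump

    def test_zero_jerk_is_undetected_with_reason(self):
        acc = np.maximum(T - 0.45, 0.0) * 40.0
        ev = detect_hr_jerk(chain(acceleration=acc), mst_event(0.3), CYCLE, CFG)
        assert not ev.detected and ev.failure_reason == "no-jerk-crossing"

    def test_no_acc_crossing_blocks_jerk(self):
        ev = detect_hr_jerk(chain(), mst_event(0.3), CYCLE, CFG)
        assert not ev.detected and ev.failure_reason == "no-acc-crossing"

    def test_jerk_never_after_acceleration_crossing(self):
        acc = np.maximum(T - 0.45, 0.0) * 40.0
        jerk = self.bump(T, 0.40, 0.05, 40.0)
        ev = detect_hr_jerk(chain(acceleration=acc, jerk=jerk), mst_event(0.3),
                            CYCLE, CFG)
        t_acc = 0.45 + 1.9 / 40.0
        assert ev.detected and ev.t <= t_acc + 1e-12


class TestForcePlateZeroCrossing:
    def test_sine_crossing_at_half_period(self):
        t0, period = 0.1, 0.6
        fy = -150.0 * np.sin(2 * np.pi * (T - t0) / period)
        ev = detect_hr_fp_zc(ser(fy, "N"), mst_event(0.3), CYCLE, CFG)
        assert ev.detected
        assert ev.t == pytest.approx(t0 + period / 2, abs=1 / RATE)

    def test_all_positive_after_mst_is_undetected(self):
        fy = np.abs(np.sin(2 * np.pi * T)) + 0.1
        ev = detect_hr_fp_zc(ser(fy, "N"), mst_event(0.3), CYCLE, CFG)
        assert not ev.detected

    def test_crossing_exactly_on_grid_sample_counts(self):
        fy = (T - 0.4) * 100.0  # zero exactly at a representable instant
        ev = detect_hr_fp_zc(ser(fy, "N"), mst_event(0.3), CYCLE, CFG)
        assert ev.detected
        assert ev.t == pytest.approx(0.4, abs=1 / RATE)


class TestImuDetectors:
    def test_zero_acceleration_is_undetected(self):
        ev = detect_hr_imu_acc(chain(), mst_event(), CYCLE, CFG)
        assert not ev.detected

    def test_ramp_crossing_within_one_sample(self):
        acc = np.maximum(T - 0.35, 0.0) * 20.0  # crosses 1.0 at 0.4
        ev = detect_hr_imu_acc(chain(acceleration=acc), mst_event(0.3), CYCLE, CFG)
        assert ev.detected
        assert abs(ev.t - 0.4) <= 1 / RATE

    def test_gravity_offset_shifts_the_threshold(self):
        acc = 9.5 + np.maximum(T - 0.35, 0.0) * 20.0
        ev = detect_hr_imu_acc(chain(acceleration=acc), mst_event(0.3), CYCLE,
                               CFG, gravity_offset=9.5)
        assert ev.detected and abs(ev.t - 0.4) <= 1 / RATE

    def test_jerk_run_onset_is_last_subthreshold_sample(self):
        acc = np.maximum(T - 0.35, 0.0) * 20.0
        jerk = np.where(T >= 0.38, 30.0, 0.0)  # rises through 12.5 at 0.38
        ev = detect_hr_imu_jerk(chain(acceleration=acc, jerk=jerk),
                                mst_event(0.3), CYCLE, CFG)
        assert ev.detected
        assert 0.38 - 1.5 / RATE <= ev.t < 0.38

    def test_subthreshold_jerk_everywhere_degenerates_to_t_acc_neighbor(self):
        acc = np.maximum(T - 0.35, 0.0) * 20.0
        ev = detect_hr_imu_jerk(chain(acceleration=acc), mst_event(0.3), CYCLE, CFG)
        assert ev.detected
        assert abs(ev.t - (0.4 - 1 / RATE)) <= 1 / RATE

    def test_no_acc_crossing_is_undetected(self):
        ev = detect_hr_imu_jerk(chain(), mst_event(0.3), CYCLE, CFG)
        assert not ev.detected and ev.failure_reason == "no-acc-crossing"


class TestDetectAll:
    def test_noise_free_trial_detects_every_method(self):
        from heelrise.synthetic_gait import generate_trial
        from tests.conftest import noise_free
        trial, _ = generate_trial([noise_free() for _ in range(5)], seed=0,
                                  with_ground_truth=False)
        events = detect_all(trial)
        assert len(events) == 5 * len(METHODS)
        assert events["detected"].all()
        assert set(events["method"]) == set(METHODS)

    def test_missing_force_plate_marks_fp_rows(self):
        from heelrise.synthetic_gait import generate_trial
        from tests.conftest import noise_free
        trial, _ = generate_trial([noise_free()], seed=0, with_ground_truth=False)
        trial.channels.pop("fy_n")
        events = detect_all(trial)
        fp = events[events["method"] == "FP-ZC"]
        assert (~fp["detected"]).all()
        assert (fp["failure_reason"] == "channel-missing").all()
        others = events[events["method"] != "FP-ZC"]
        assert others["detected"].all()

    def test_empty_trial_gives_empty_table(self):
        trial = TrialRecording(trial_id="empty", channels={})
        events = detect_all(trial)
        assert len(events) == 0

    def test_time_translation_invariance(self):
        from heelrise.synthetic_gait import generate_trial
        from tests.conftest import noise_free
        trial, _ = generate_trial([noise_free()], seed=0, with_ground_truth=False)
        shifted = TrialRecording(
            trial_id=trial.trial_id,
            channels={k: UniformSeries(s.values, rate=s.rate, t0=s.t0 + 11.0,
                                       units=s.units)
                      for k, s in trial.channels.items()},
            subject=trial.subject, side=trial.side, scenario=trial.scenario)
        a = detect_all(trial)
        b = detect_all(shifted)
        det = a["detected"].to_numpy()
        assert (b["detected"].to_numpy() == det).all()
        assert np.allclose(b.loc[det, "t_s"] - a.loc[det, "t_s"], 11.0)
        assert np.allclose(b.loc[det, "cycle_percent"], a.loc[det, "cycle_percent"],
                           atol=1e-9)
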