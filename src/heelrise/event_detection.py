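"""Heel-rise (HR) detection: the full method family on one common grid.

Every detector searches strictly after the mid-stance event (MST, the
instant the swinging foot's toe marker passes the stance foot's heel
marker) and before a configurable search-window end (60 % of the gait
cycle by default).  "Exceeds" means the first sample at or above the
threshold; ties count as crossed.

Methods
-------
HM-POS3/4/5   heel marker vertical position exceeds the MST reference by
              3/4/5 mm
HM-VEL50/80/100  heel marker vertical velocity exceeds 50/80/100 mm/s
HM-ACC        heel marker vertical acceleration exceeds 1.9 m/s²
HM-JERK       last upward crossing of heel jerk through 15 m/s³ before the
              HM-ACC crossing (the onset of the rapid acceleration increase)
FP-ZC         braking-to-propulsion zero crossing of the anteroposterior
              shear force Fy
IMU-ACC       gravity-compensated shank longitudinal acceleration exceeds
              1 m/s²
IMU-JERK      last sample before the IMU-ACC crossing whose jerk is below
              12.5 m/s³ (onset of the final supra-threshold jerk run)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .config import DetectionConfig
from .cycle_segmentation import (GaitCycle, detect_initial_contacts,
                                 segment_cycles, to_cycle_percent)
from .io import EVENT_COLUMNS, TrialRecording
from .signal_core import (KinematicChain, UniformSeries, build_imu_chain,
                          build_kinematic_chain, lowpass_zero_phase)

log = logging.getLogger(__name__)

METHODS = ("HM-POS3", "HM-POS4", "HM-POS5",
           "HM-VEL50", "HM-VEL80", "HM-VEL100",
           "HM-ACC", "HM-JERK", "FP-ZC", "IMU-ACC", "IMU-JERK")


@dataclass(frozen=True)
class GaitEvent:
    """A detected (or undetectable) instant within one gait cycle."""

    kind: str  # IC | MST | HR
    method: str
    detected: bool
    t: Optional[float] = None
    cycle_percent: Optional[float] = None
    heel_above_mst_mm: Optional[float] = None
    mst_t: Optional[float] = None
    failure_reason: Optional[str] = None
    t_interp: Optional[float] = None  # FP-ZC sub-sample crossing time


def _undetected(kind: str, method: str, reason: str,
                mst_t: Optional[float] = None) -> GaitEvent:
    return GaitEvent(kind=kind, method=method, detected=False,
                     failure_reason=reason, mst_t=mst_t)


def _window(series: UniformSeries, mst_t: float, cycle: GaitCycle,
            cfg: DetectionConfig) -> tuple[int, int]:
    """Index range (start, end] for the HR search: strictly after MST up to
    ``search_end_percent`` of the stride."""
    mst_idx = series.index_at(mst_t)
    t_end = cycle.ic_start + cfg.search_end_percent / 100.0 * cycle.stride_time
    end_idx = int(np.floor((t_end - series.t0) * series.rate + 1e-9))
    end_idx = min(end_idx, len(series) - 1)
    return mst_idx, end_idx


def _first_at_or_above(values: np.ndarray, lo: int, hi: int,
                       threshold: float) -> Optional[int]:
    """First index in (lo, hi] with value >= threshold."""
    seg = values[lo + 1:hi + 1]
    hits = np.nonzero(seg >= threshold)[0]
    return int(lo + 1 + hits[0]) if hits.size else None


def detect_mst(stance_heel_ap: UniformSeries, swing_toe_ap: UniformSeries,
               cycle: GaitCycle) -> GaitEvent:
    """Mid-stance event: first sample where the swinging toe's AP position
    reaches the stance heel's (AP axis positive in the walking direction)."""
    i0 = stance_heel_ap.index_at(cycle.ic_start)
    i1 = stance_heel_ap.index_at(cycle.ic_end)
    diff = swing_toe_ap.values[i0:i1] - stance_heel_ap.values[i0:i1]
    hits = np.nonzero(diff >= 0)[0]
    if hits.size == 0:
        return _undetected("MST", "MST", "no-mst")
    t = stance_heel_ap.t0 + (i0 + int(hits[0])) / stance_heel_ap.rate
    return GaitEvent(kind="MST", method="MST", detected=True, t=t,
                     cycle_percent=to_cycle_percent(t, cycle), mst_t=t)


def _threshold_event(channel: UniformSeries, method: str, mst: GaitEvent,
                     threshold: float, cycle: GaitCycle, cfg: DetectionConfig,
                     reference: float = 0.0) -> GaitEvent:
    lo, hi = _window(channel, mst.t, cycle, cfg)
    idx = _first_at_or_above(channel.values - reference, lo, hi, threshold)
    if idx is None:
        return _undetected("HR", method, "no-crossing", mst.t)
    t = channel.t0 + idx / channel.rate
    return GaitEvent(kind="HR", method=method, detected=True, t=t,
                     cycle_percent=to_cycle_percent(t, cycle), mst_t=mst.t)


def detect_hr_position(chain: KinematicChain, mst: GaitEvent, threshold_mm: float,
                       cycle: GaitCycle, cfg: DetectionConfig) -> GaitEvent:
    """Heel height exceeds the MST reference height by ``threshold_mm``."""
    pos = chain.position
    ref = pos.values[pos.index_at(mst.t)]
    ev = _threshold_event(pos, f"HM-POS{threshold_mm:g}", mst, threshold_mm,
                          cycle, cfg, reference=ref)
    if ev.detected:
        ev = replace(ev, heel_above_mst_mm=float(
            pos.values[pos.index_at(ev.t)] - ref))
    return ev


def detect_hr_velocity(chain: KinematicChain, mst: GaitEvent, threshold_mm_s: float,
                       cycle: GaitCycle, cfg: DetectionConfig) -> GaitEvent:
    return _threshold_event(chain.velocity, f"HM-VEL{threshold_mm_s:g}", mst,
                            threshold_mm_s, cycle, cfg)


def detect_hr_acceleration(chain: KinematicChain, mst: GaitEvent, cycle: GaitCycle,
                           cfg: DetectionConfig) -> GaitEvent:
    return _threshold_event(chain.acceleration, "HM-ACC", mst,
                            cfg.hm_acc_threshold_m_s2, cycle, cfg)


def detect_hr_jerk(chain: KinematicChain, mst: GaitEvent, cycle: GaitCycle,
                   cfg: DetectionConfig) -> GaitEvent:
    """Last upward jerk crossing through the threshold at or before the
    acceleration crossing."""
    acc = chain.acceleration
    lo, hi = _window(acc, mst.t, cycle, cfg)
    t_acc_idx = _first_at_or_above(acc.values, lo, hi, cfg.hm_acc_threshold_m_s2)
    if t_acc_idx is None:
        return _undetected("HR", "HM-JERK", "no-acc-crossing", mst.t)
    jerk = chain.jerk.values
    thr = cfg.hm_jerk_threshold_m_s3
    for i in range(t_acc_idx, lo, -1):
        if jerk[i] >= thr and jerk[i - 1] < thr:
            t = chain.jerk.t0 + i / chain.jerk.rate
            return GaitEvent(kind="HR", method="HM-JERK", detected=True, t=t,
                             cycle_percent=to_cycle_percent(t, cycle), mst_t=mst.t)
    return _undetected("HR", "HM-JERK", "no-jerk-crossing", mst.t)


def detect_hr_fp_zc(fy: UniformSeries, mst: GaitEvent, cycle: GaitCycle,
                    cfg: DetectionConfig) -> GaitEvent:
    """First braking-to-propulsion (negative-to-positive) Fy crossing after
    MST.  ``fy`` must already be low-pass filtered.  The reported time is the
    linearly interpolated crossing; cycle-percent uses the grid sample."""
    lo, hi = _window(fy, mst.t, cycle, cfg)
    y = fy.values
    idx = None
    for i in range(lo + 1, hi + 1):
        if y[i - 1] < 0 <= y[i]:
            idx = i
            break
    if idx is None:
        return _undetected("HR", "FP-ZC", "no-crossing", mst.t)
    t_grid = fy.t0 + idx / fy.rate
    frac = -y[idx - 1] / (y[idx] - y[idx - 1]) if y[idx] > y[idx - 1] else 1.0
    t_interp = fy.t0 + (idx - 1 + frac) / fy.rate
    return GaitEvent(kind="HR", method="FP-ZC", detected=True, t=t_interp,
                     cycle_percent=to_cycle_percent(t_grid, cycle),
                     mst_t=mst.t, t_interp=t_interp)


def detect_hr_imu_acc(imu_chain: KinematicChain, mst: GaitEvent, cycle: GaitCycle,
                      cfg: DetectionConfig, gravity_offset: float = 0.0) -> GaitEvent:
    """Gravity-compensated longitudinal acceleration exceeds the threshold."""
    return _threshold_event(imu_chain.acceleration, "IMU-ACC", mst,
                            cfg.imu_acc_threshold_m_s2, cycle, cfg,
                            reference=gravity_offset)


def detect_hr_imu_jerk(imu_chain: KinematicChain, mst: GaitEvent, cycle: GaitCycle,
                       cfg: DetectionConfig, gravity_offset: float = 0.0) -> GaitEvent:
    """Last sample at or before the IMU-ACC crossing whose jerk is below the
    threshold — the onset of the final sustained supra-threshold jerk run."""
    acc = imu_chain.acceleration
    lo, hi = _window(acc, mst.t, cycle, cfg)
    t_acc_idx = _first_at_or_above(acc.values - gravity_offset, lo, hi,
                                   cfg.imu_acc_threshold_m_s2)
    if t_acc_idx is None:
        return _undetected("HR", "IMU-JERK", "no-acc-crossing", mst.t)
    jerk = imu_chain.jerk.values
    thr = cfg.imu_jerk_threshold_m_s3
    for i in range(t_acc_idx, lo, -1):
        if jerk[i] < thr:
            if i == t_acc_idx - 1 and np.all(jerk[lo + 1:t_acc_idx] < thr):
                log.debug("IMU-JERK degenerate: jerk sub-threshold throughout "
                          "the window; reporting the sample before the "
                          "acceleration crossing")
            t = imu_chain.jerk.t0 + i / imu_chain.jerk.rate
            return GaitEvent(kind="HR", method="IMU-JERK", detected=True, t=t,
                             cycle_percent=to_cycle_percent(t, cycle), mst_t=mst.t)
    return _undetected("HR", "IMU-JERK", "no-subthreshold-jerk", mst.t)


def estimate_gravity_offset(imu_raw: UniformSeries, cycle: GaitCycle, mst_t: float,
                            cfg: DetectionConfig) -> float:
    """Per-stride longitudinal gravity component: the mean raw acceleration
    over the flat-foot window (default 10 % of the cycle up to MST)."""
    t_start = cycle.ic_start + cfg.gravity_window_start_percent / 100.0 * cycle.stride_time
    i0 = imu_raw.index_at(t_start)
    i1 = imu_raw.index_at(mst_t)
    if i1 <= i0:
        return float(imu_raw.values[i0])
    return float(imu_raw.values[i0:i1].mean())


def _prepare_signals(trial: TrialRecording, cfg: DetectionConfig) -> dict:
    """Filter chains shared across cycles of one trial."""
    sig: dict = {}
    if trial.has("heel_z_mm"):
        sig["hm_chain"] = build_kinematic_chain(
            trial.channels["heel_z_mm"], cfg.marker_cutoff_hz,
            cfg.jerk_prefilter_cutoff_hz, cfg.filter_order)
    if trial.has("imu_acc_long_ms2"):
        sig["imu_raw"] = trial.channels["imu_acc_long_ms2"]
        sig["imu_chain"] = build_imu_chain(
            sig["imu_raw"], cfg.imu_cutoff_hz,
            cfg.jerk_prefilter_cutoff_hz, cfg.filter_order)
    if trial.has("fy_n"):
        fy = trial.channels["fy_n"]
        if cfg.fy_axis_flip:
            fy = fy.with_values(-fy.values)
        sig["fy"] = lowpass_zero_phase(fy, cfg.fy_cutoff_hz, cfg.filter_order)
    if trial.has("imu_gyro_ml_dps"):
        gyro = trial.channels["imu_gyro_ml_dps"]
        if cfg.gyro_axis_flip:
            gyro = gyro.with_values(-gyro.values)
        sig["gyro"] = lowpass_zero_phase(gyro, cfg.gyro_cutoff_hz, cfg.filter_order)
    return sig


def segment_trial(trial: TrialRecording, cfg: DetectionConfig) -> list[GaitCycle]:
    """ICs from the trial's gyro channel -> gait cycles."""
    sig = _prepare_signals(trial, cfg)
    if "gyro" not in sig:
        return []
    ics = detect_initial_contacts(sig["gyro"], cfg.peak_prominence,
                                  cfg.min_stride_time, cfg.max_peak_to_ic)
    return segment_cycles(ics, side=trial.side)


def detect_cycle(trial: TrialRecording, cycle: GaitCycle, cfg: DetectionConfig,
                 sig: Optional[dict] = None) -> list[GaitEvent]:
    """All HR methods for one gait cycle; failures are data, not exceptions."""
    if sig is None:
        sig = _prepare_signals(trial, cfg)
    events: list[GaitEvent] = []
    if trial.has("heel_ap_mm") and trial.has("toe_ap_opp_mm"):
        mst = detect_mst(trial.channels["heel_ap_mm"],
                         trial.channels["toe_ap_opp_mm"], cycle)
    else:
        mst = _undetected("MST", "MST", "channel-missing")
    if not mst.detected:
        return [_undetected("HR", m, mst.failure_reason or "no-mst")
                for m in METHODS]

    hm_chain = sig.get("hm_chain")
    for m in METHODS:
        if m.startswith("HM-") and hm_chain is None:
            events.append(_undetected("HR", m, "channel-missing", mst.t))
        elif m.startswith("HM-POS"):
            events.append(detect_hr_position(hm_chain, mst, float(m[6:]), cycle, cfg))
        elif m.startswith("HM-VEL"):
            events.append(detect_hr_velocity(hm_chain, mst, float(m[6:]), cycle, cfg))
        elif m == "HM-ACC":
            events.append(detect_hr_acceleration(hm_chain, mst, cycle, cfg))
        elif m == "HM-JERK":
            events.append(detect_hr_jerk(hm_chain, mst, cycle, cfg))
        elif m == "FP-ZC":
            if "fy" not in sig:
                events.append(_undetected("HR", m, "channel-missing", mst.t))
            else:
                events.append(detect_hr_fp_zc(sig["fy"], mst, cycle, cfg))
        elif m in ("IMU-ACC", "IMU-JERK"):
            if "imu_chain" not in sig:
                events.append(_undetected("HR", m, "channel-missing", mst.t))
                continue
            g = 0.0 if cfg.imu_precompensated else estimate_gravity_offset(
                sig["imu_raw"], cycle, mst.t, cfg)
            if m == "IMU-ACC":
                events.append(detect_hr_imu_acc(sig["imu_chain"], mst, cycle, cfg, g))
            else:
                events.append(detect_hr_imu_jerk(sig["imu_chain"], mst, cycle, cfg, g))

    # annotate every detected HR with the heel height above the MST reference
    if hm_chain is not None:
        pos = hm_chain.position
        ref = pos.values[pos.index_at(mst.t)]
        events = [replace(ev, heel_above_mst_mm=float(
            pos.values[pos.index_at(ev.t)] - ref))
            if ev.detected and ev.heel_above_mst_mm is None else ev
            for ev in events]
    return events


def detect_all(trial: TrialRecording, cfg: Optional[DetectionConfig] = None) -> pd.DataFrame:
    """Run segmentation plus every detector; one row per (cycle, method)."""
    cfg = cfg or DetectionConfig()
    rows: list[dict] = []
    if trial.channels:
        sig = _prepare_signals(trial, cfg)
        cycles = segment_trial(trial, cfg)
        for cycle in cycles:
            for ev in detect_cycle(trial, cycle, cfg, sig):
                rows.append({
                    "trial_id": trial.trial_id, "subject": trial.subject,
                    "side": trial.side, "scenario": trial.scenario,
                    "cycle_index": cycle.index, "method": ev.method,
                    "detected": ev.detected, "t_s": ev.t,
                    "cycle_percent": ev.cycle_percent,
                    "heel_above_mst_mm": ev.heel_above_mst_mm,
                    "mst_t_s": ev.mst_t, "failure_reason": ev.failure_reason,
                })
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)
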