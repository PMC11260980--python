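"""Synthetic multi-channel strides with exact ground-truth event times.

The generator emulates the signal morphology that the heel-rise detectors
operate on, with every event time known by construction:

* **Heel vertical position** — flat through early stance; from MST an
  optional slow "pre-rise" (a quintic smoothstep whose mean slope is the
  ``pre_rise_rate``) up to the RIA instant; from RIA a rapid C⁴-continuous
  9th-order smoothstep rise of ``rise_amplitude`` mm over ``rise_duration``
  s; a raised-cosine swing return to baseline at the next initial contact.
  The high continuity order keeps the jerk channel band-limited, so the
  zero-phase filter chain does not move threshold crossings.
* **AP markers** — stance heel constant, advancing by the stride length
  during swing; the contralateral toe crosses the stance heel exactly at
  ``mst_percent``.
* **Shank angular velocity (ML)** — a positive mid-swing peak followed by a
  strictly descending limb into a sharp local minimum at the next initial
  contact (the IC that segmentation must recover).
* **Fy** — a C¹ braking/propulsion double lobe with its upward zero
  crossing exactly at ``fy_zc_percent``.
* **IMU longitudinal acceleration** — ``imu_gain`` × the heel's analytic
  vertical acceleration, plus a constant gravity component.

Channels are returned *raw* (plus optional white Gaussian noise); filtering
is the detection pipeline's job.  Ground truth is computed on the
noise-free continuous model *through the method's own filter chain*,
evaluated on a dense grid (100 kHz) with sub-sample interpolated
crossings — an oracle independent of the sample-resolution detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal as _sps

from .config import DetectionConfig
from .io import TrialRecording
from .signal_core import InvalidParameterError, UniformSeries

# ---------------------------------------------------------------------------
# smoothstep polynomials (0 -> 1 on [0, 1], flat outside)

def smoothstep5(x: np.ndarray) -> np.ndarray:
    """C² quintic smoothstep 6x⁵-15x⁴+10x³."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 3 * (10.0 + x * (-15.0 + 6.0 * x))


def smoothstep5_d2(x: np.ndarray) -> np.ndarray:
    inside = (x > 0.0) & (x < 1.0)
    x = np.clip(x, 0.0, 1.0)
    return np.where(inside, 60.0 * x * (1.0 - x) * (1.0 - 2.0 * x), 0.0)


def smoothstep9(x: np.ndarray) -> np.ndarray:
    """C⁴ 9th-order smoothstep 70x⁹-315x⁸+540x⁷-420x⁶+126x⁵."""
    x = np.clip(x, 0.0, 1.0)
    return x ** 5 * (126.0 + x * (-420.0 + x * (540.0 + x * (-315.0 + 70.0 * x))))


def smoothstep9_d2(x: np.ndarray) -> np.ndarray:
    inside = (x > 0.0) & (x < 1.0)
    x = np.clip(x, 0.0, 1.0)
    return np.where(inside,
                    2520.0 * x ** 3 * (1.0 - x) ** 3 * (1.0 - 2.0 * x), 0.0)


def smoothstep9_inverse(y: float) -> float:
    """x with smoothstep9(x) = y, by bisection (used for closed-form checks)."""
    if not 0.0 <= y <= 1.0:
        raise InvalidParameterError("smoothstep inverse needs y in [0, 1]")
    lo, hi = 0.0, 1.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if smoothstep9(np.asarray(mid)) < y:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrideModelParams:
    """Parameters of one continuous model stride.

    ``pre_rise_rate`` is the mean slope (mm/s) of the slow heel elevation
    between MST and RIA; 0 selects the abrupt strategy.  Noise SDs apply to
    the raw sampled channels; the ground truth is always noise-free.
    """

    stride_time: float = 1.05  # s
    sample_rate: float = 1125.0  # Hz
    stride_length: float = 1.45  # m
    mst_percent: float = 26.0
    ria_percent: float = 36.5
    pre_rise_rate: float = 0.0  # mm/s (0 = abrupt strategy)
    rise_amplitude: float = 80.0  # mm
    rise_duration: float = 0.25  # s
    fy_zc_percent: float = 34.0
    fy_amplitude: float = 150.0  # N
    imu_gain: float = 0.6
    gravity_offset_m_s2: float = 9.55
    midswing_peak_percent: float = 76.0
    gyro_peak_dps: float = 300.0
    gyro_dip_dps: float = 400.0
    stance_end_percent: float = 62.0
    noise_sd_pos: float = 0.3  # mm
    noise_sd_imu: float = 0.3  # m/s²
    noise_sd_fy: float = 2.0  # N
    noise_sd_gyro: float = 5.0  # deg/s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mst_percent < self.ria_percent < 100.0:
            raise InvalidParameterError("need 0 < mst_percent < ria_percent < 100")
        if self.rise_amplitude <= 0 or self.rise_duration <= 0:
            raise InvalidParameterError("rise amplitude and duration must be > 0")
        if min(self.noise_sd_pos, self.noise_sd_imu, self.noise_sd_fy,
               self.noise_sd_gyro) < 0:
            raise InvalidParameterError("noise SDs must be >= 0")
        if not 0.0 < self.imu_gain <= 1.0:
            raise InvalidParameterError("imu_gain must lie in (0, 1]")
        if self.ria_percent / 100.0 + self.rise_duration / self.stride_time >= 0.97:
            raise InvalidParameterError("rise must finish before the next IC")

    @property
    def pre_rise_amplitude_mm(self) -> float:
        window = (self.ria_percent - self.mst_percent) / 100.0 * self.stride_time
        return self.pre_rise_rate * window


@dataclass(frozen=True)
class StrideGroundTruth:
    """Exact event times for one stride on the noise-free continuous model."""

    stride_index: int
    ic_start: float
    ic_end: float
    mst_t: float
    ria_t: float
    crossings: dict[str, Optional[float]] = field(default_factory=dict)


class TrialModel:
    """Continuous multi-stride model; evaluates any channel at arbitrary t.

    ``strides`` always contains a warm-up stride first and a (truncated)
    virtual tail stride last, so filtering and segmentation of the sampled
    trial see realistic context around every real stride.
    """

    TAIL_FRACTION = 0.35

    def __init__(self, stride_params: list[StrideModelParams]):
        if not stride_params:
            raise InvalidParameterError("need at least one stride")
        warmup = replace(stride_params[0], pre_rise_rate=0.0)
        tail = stride_params[-1]
        self.strides: list[StrideModelParams] = [warmup, *stride_params, tail]
        durations = [p.stride_time for p in self.strides]
        self.bounds = np.concatenate([[0.0], np.cumsum(durations)])
        self.n_real = len(stride_params)
        # trial ends part-way into the virtual tail stride
        self.t_end = self.bounds[-2] + self.TAIL_FRACTION * tail.stride_time
        # initial contacts: every real-stride boundary
        self.ic_times = self.bounds[1:self.n_real + 2].copy()
        # cumulative AP position of the (stance) heel at each stride start, mm
        ap = np.concatenate([[0.0], np.cumsum(
            [p.stride_length * 1000.0 for p in self.strides])])
        self.ap_start = ap

    # -- per-channel evaluation -------------------------------------------

    def _per_stride(self, t: np.ndarray, fn) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        idx = np.clip(np.searchsorted(self.bounds, t, side="right") - 1,
                      0, len(self.strides) - 1)
        for k, p in enumerate(self.strides):
            m = idx == k
            if m.any():
                u = (t[m] - self.bounds[k]) / p.stride_time
                out[m] = fn(p, u, k)
        return out

    # the slow pre-rise starts shortly *after* MST (first fifth of the
    # MST->RIA window), so the filtered heel height is still flat at the
    # MST reference instant
    PRE_RISE_DELAY = 0.2

    @classmethod
    def _pre_rise_onset(cls, um: float, ur: float) -> float:
        return um + cls.PRE_RISE_DELAY * (ur - um)

    @classmethod
    def _heel_z_stride(cls, p: StrideModelParams, u: np.ndarray) -> np.ndarray:
        um, ur = p.mst_percent / 100.0, p.ria_percent / 100.0
        ud = p.rise_duration / p.stride_time
        ue = ur + ud
        u0 = cls._pre_rise_onset(um, ur)
        pre = p.pre_rise_amplitude_mm * smoothstep5((u - u0) / (ur - u0))
        rise = p.rise_amplitude * smoothstep9((u - ur) / ud)
        z = pre + rise
        high = u > ue
        if high.any():
            height = p.pre_rise_amplitude_mm + p.rise_amplitude
            z_sw = height * 0.5 * (1.0 + np.cos(np.pi * (u[high] - ue) / (1.0 - ue)))
            z = np.where(high, 0.0, z)
            z[high] = z_sw
        return z

    @classmethod
    def _heel_z_acc_stride(cls, p: StrideModelParams, u: np.ndarray) -> np.ndarray:
        """Analytic second derivative of the heel height, mm/s²."""
        um, ur = p.mst_percent / 100.0, p.ria_percent / 100.0
        ud = p.rise_duration / p.stride_time
        ue = ur + ud
        u0 = cls._pre_rise_onset(um, ur)
        w_pre = (ur - u0) * p.stride_time
        acc = (p.pre_rise_amplitude_mm * smoothstep5_d2((u - u0) / (ur - u0))
               / w_pre ** 2
               + p.rise_amplitude * smoothstep9_d2((u - ur) / ud)
               / (ud * p.stride_time) ** 2)
        high = u > ue
        if high.any():
            height = p.pre_rise_amplitude_mm + p.rise_amplitude
            om = np.pi / ((1.0 - ue) * p.stride_time)
            acc = np.where(high, 0.0, acc)
            acc[high] = -height * 0.5 * om ** 2 * np.cos(
                np.pi * (u[high] - ue) / (1.0 - ue))
        return acc

    def heel_z(self, t) -> np.ndarray:
        return self._per_stride(t, lambda p, u, k: self._heel_z_stride(p, u))

    def heel_z_acc(self, t) -> np.ndarray:
        return self._per_stride(t, lambda p, u, k: self._heel_z_acc_stride(p, u))

    def heel_ap(self, t) -> np.ndarray:
        def fn(p, u, k):
            u_sw0 = p.stance_end_percent / 100.0
            L = p.stride_length * 1000.0
            return self.ap_start[k] + L * smoothstep5((u - u_sw0) / (0.98 - u_sw0))
        return self._per_stride(t, fn)

    def toe_ap_opp(self, t) -> np.ndarray:
        # contralateral toe: stationary during its own stance, advancing
        # linearly during its swing and crossing the stance heel at MST
        def fn(p, u, k):
            um = p.mst_percent / 100.0
            L = p.stride_length * 1000.0
            u_swing = np.clip(u, um - 0.14, um + 0.24)
            return self.ap_start[k] + 3.5 * L * (u_swing - um)
        return self._per_stride(t, fn)

    def fy(self, t) -> np.ndarray:
        def fn(p, u, k):
            uzc = p.fy_zc_percent / 100.0
            use = p.stance_end_percent / 100.0
            y = np.zeros_like(u)
            brake = (u >= 0) & (u < uzc)
            y[brake] = -p.fy_amplitude * np.sin(np.pi * u[brake] / uzc)
            prop = (u >= uzc) & (u <= use)
            # slope-matched propulsion lobe (C¹ at the zero crossing)
            amp = p.fy_amplitude * (use - uzc) / uzc
            y[prop] = amp * np.sin(np.pi * (u[prop] - uzc) / (use - uzc))
            return y
        return self._per_stride(t, fn)

    def imu_acc(self, t, include_gravity: bool = True) -> np.ndarray:
        t = np.asarray(t, float)
        out = np.zeros_like(t)
        idx = np.clip(np.searchsorted(self.bounds, t, side="right") - 1,
                      0, len(self.strides) - 1)
        for k, p in enumerate(self.strides):
            m = idx == k
            if m.any():
                u = (t[m] - self.bounds[k]) / p.stride_time
                acc = p.imu_gain * self._heel_z_acc_stride(p, u) / 1000.0
                if include_gravity:
                    acc = acc + p.gravity_offset_m_s2
                out[m] = acc
        return out

    def gyro_ml(self, t) -> np.ndarray:
        t = np.asarray(t, float)
        # mid-swing peaks: one per stride except the virtual tail
        out = np.zeros_like(t)
        idx = np.clip(np.searchsorted(self.bounds, t, side="right") - 1,
                      0, len(self.strides) - 1)
        wp = 0.09
        for k, p in enumerate(self.strides[:-1]):
            m = idx == k
            if m.any():
                u = (t[m] - self.bounds[k]) / p.stride_time
                up = p.midswing_peak_percent / 100.0
                inside = np.abs(u - up) < wp
                bump = np.zeros_like(u)
                bump[inside] = p.gyro_peak_dps * np.cos(
                    np.pi * (u[inside] - up) / (2.0 * wp)) ** 2
                out[m] += bump
        # IC dips: sharp symmetric local minimum at every initial contact
        for j, tb in enumerate(self.ic_times):
            p = self.strides[min(j + 1, len(self.strides) - 1)]
            wd = 0.06 * p.stride_time
            m = np.abs(t - tb) < wd
            if m.any():
                out[m] -= p.gyro_dip_dps * np.cos(
                    np.pi * (t[m] - tb) / (2.0 * wd)) ** 2
        return out


# ---------------------------------------------------------------------------
# sampling

def _sample_trial(model: TrialModel, rate: float, rng: np.random.Generator,
                  noise: StrideModelParams, trial_id: str, subject: str,
                  side: str, scenario: str) -> TrialRecording:
    n = int(np.floor(model.t_end * rate)) + 1
    t = np.arange(n) / rate

    def ser(vals, units):
        return UniformSeries(vals, rate=rate, t0=0.0, units=units)

    channels = {
        "heel_z_mm": ser(model.heel_z(t)
                         + rng.normal(0.0, noise.noise_sd_pos, n), "mm"),
        "heel_ap_mm": ser(model.heel_ap(t)
                          + rng.normal(0.0, noise.noise_sd_pos, n), "mm"),
        "toe_ap_opp_mm": ser(model.toe_ap_opp(t)
                             + rng.normal(0.0, noise.noise_sd_pos, n), "mm"),
        "imu_acc_long_ms2": ser(model.imu_acc(t)
                                + rng.normal(0.0, noise.noise_sd_imu, n), "m/s^2"),
        "imu_gyro_ml_dps": ser(model.gyro_ml(t)
                               + rng.normal(0.0, noise.noise_sd_gyro, n), "deg/s"),
        "fy_n": ser(model.fy(t) + rng.normal(0.0, noise.noise_sd_fy, n), "N"),
    }
    return TrialRecording(trial_id=trial_id, channels=channels, subject=subject,
                          side=side, scenario=scenario,
                          provenance={c: rate for c in channels})


# ---------------------------------------------------------------------------
# ground truth: dense filtered continuous model, interpolated crossings

def _filtfilt_dense(y: np.ndarray, cutoff: float, rate: float, order: int = 2
                    ) -> np.ndarray:
    b, a = _sps.butter(order, cutoff, btype="low", fs=rate)
    return _sps.filtfilt(b, a, y, padtype="odd", padlen=3 * (order + 1))


def _first_reach(t: np.ndarray, y: np.ndarray, thr: float, lo: float,
                 hi: float) -> Optional[float]:
    """Interpolated first time in (lo, hi] with y >= thr."""
    m = (t > lo) & (t <= hi)
    idx = np.nonzero(m)[0]
    hits = np.nonzero(y[idx] >= thr)[0]
    if hits.size == 0:
        return None
    i = idx[hits[0]]
    if i == 0 or y[i - 1] >= thr or y[i] == y[i - 1]:
        return float(t[i])
    frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def _last_upward(t: np.ndarray, y: np.ndarray, thr: float, lo: float,
                 hi: float) -> Optional[float]:
    """Interpolated last upward crossing of thr in (lo, hi]."""
    m = (t > lo) & (t <= hi)
    idx = np.nonzero(m)[0]
    if idx.size < 2:
        return None
    yy = y[idx]
    up = np.nonzero((yy[1:] >= thr) & (yy[:-1] < thr))[0]
    if up.size == 0:
        return None
    i = idx[up[-1] + 1]
    frac = (thr - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def compute_ground_truth(model: TrialModel, stride_index: int,
                         cfg: Optional[DetectionConfig] = None,
                         dense_rate: float = 100_000.0) -> StrideGroundTruth:
    """Event times for one real stride of the model, via the dense oracle.

    ``stride_index`` counts real strides (0-based, warm-up excluded).
    """
    cfg = cfg or DetectionConfig()
    k = stride_index + 1  # account for the warm-up stride
    p = model.strides[k]
    ic0, ic1 = model.bounds[k], model.bounds[k + 1]
    T = p.stride_time
    t_lo = max(ic0 - 0.35, 0.0)
    t_hi = min(ic1 + 0.25, model.t_end)
    t = np.arange(t_lo, t_hi, 1.0 / dense_rate)
    dt = 1.0 / dense_rate

    mst_t = ic0 + p.mst_percent / 100.0 * T
    ria_t = ic0 + p.ria_percent / 100.0 * T
    search_hi = ic0 + cfg.search_end_percent / 100.0 * T

    # heel-marker chain through the method's filter cascade
    pos = _filtfilt_dense(model.heel_z(t), cfg.marker_cutoff_hz, dense_rate,
                          cfg.filter_order)
    vel = np.gradient(pos, dt)
    acc = np.gradient(vel, dt) / 1000.0
    jerk = np.gradient(_filtfilt_dense(acc, cfg.jerk_prefilter_cutoff_hz,
                                       dense_rate, cfg.filter_order), dt)
    ref = float(np.interp(mst_t, t, pos))

    cross: dict[str, Optional[float]] = {}
    for thr in cfg.pos_thresholds_mm:
        cross[f"HM-POS{thr:g}"] = _first_reach(t, pos - ref, thr, mst_t, search_hi)
    for thr in cfg.vel_thresholds_mm_s:
        cross[f"HM-VEL{thr:g}"] = _first_reach(t, vel, thr, mst_t, search_hi)
    t_acc = _first_reach(t, acc, cfg.hm_acc_threshold_m_s2, mst_t, search_hi)
    cross["HM-ACC"] = t_acc
    cross["HM-JERK"] = (None if t_acc is None else
                        _last_upward(t, jerk, cfg.hm_jerk_threshold_m_s3,
                                     mst_t, t_acc))

    # force plate
    fy = _filtfilt_dense(model.fy(t), cfg.fy_cutoff_hz, dense_rate,
                         cfg.filter_order)
    cross["FP-ZC"] = _first_reach(t, fy, 0.0, mst_t, search_hi)

    # IMU chain (gravity-compensated exactly: the oracle knows the offset)
    imu = _filtfilt_dense(model.imu_acc(t, include_gravity=False),
                          cfg.imu_cutoff_hz, dense_rate, cfg.filter_order)
    imu_jerk = np.gradient(_filtfilt_dense(imu, cfg.jerk_prefilter_cutoff_hz,
                                           dense_rate, cfg.filter_order), dt)
    t_acc_imu = _first_reach(t, imu, cfg.imu_acc_threshold_m_s2, mst_t, search_hi)
    cross["IMU-ACC"] = t_acc_imu
    cross["IMU-JERK"] = (None if t_acc_imu is None else
                         _last_upward(t, imu_jerk, cfg.imu_jerk_threshold_m_s3,
                                      mst_t, t_acc_imu))

    return StrideGroundTruth(stride_index=stride_index, ic_start=float(ic0),
                             ic_end=float(ic1), mst_t=mst_t, ria_t=ria_t,
                             crossings=cross)


# ---------------------------------------------------------------------------
# public generation API

def generate_trial(stride_params: list[StrideModelParams], seed: int = 0,
                   trial_id: str = "trial", subject: str = "S01",
                   side: str = "right", scenario: str = "shod_normal",
                   cfg: Optional[DetectionConfig] = None,
                   with_ground_truth: bool = True,
                   with_crossings: bool = True,
                   ) -> tuple[TrialRecording, list[StrideGroundTruth]]:
    """Sample a multi-stride trial and (optionally) its ground truth."""
    model = TrialModel(stride_params)
    rng = np.random.default_rng(seed)
    trial = _sample_trial(model, stride_params[0].sample_rate, rng,
                          stride_params[0], trial_id, subject, side, scenario)
    truth: list[StrideGroundTruth] = []
    if with_ground_truth:
        for i, p in enumerate(stride_params):
            if with_crossings:
                truth.append(compute_ground_truth(model, i, cfg))
            else:
                ic0 = model.bounds[i + 1]
                truth.append(StrideGroundTruth(
                    stride_index=i, ic_start=float(ic0),
                    ic_end=float(model.bounds[i + 2]),
                    mst_t=ic0 + p.mst_percent / 100.0 * p.stride_time,
                    ria_t=ic0 + p.ria_percent / 100.0 * p.stride_time))
    return trial, truth


def generate_stride(p: StrideModelParams, **kwargs
                    ) -> tuple[TrialRecording, Optional[StrideGroundTruth]]:
    """One-stride convenience wrapper around :func:`generate_trial`."""
    trial, truth = generate_trial([p], seed=p.seed, **kwargs)
    return trial, truth[0] if truth else None


# scenario regimes: stride time (s), stride length (m) and RIA (% of cycle)
# for fast/normal/slow walking, shod and barefoot
SCENARIOS: dict[str, dict[str, float]] = {
    "shod_fast": {"stride_time": 0.95, "stride_length": 1.71, "ria_percent": 35.0},
    "shod_normal": {"stride_time": 1.05, "stride_length": 1.45, "ria_percent": 36.5},
    "shod_slow": {"stride_time": 1.17, "stride_length": 1.31, "ria_percent": 38.5},
    "barefoot_fast": {"stride_time": 0.92, "stride_length": 1.64, "ria_percent": 33.5},
    "barefoot_normal": {"stride_time": 1.02, "stride_length": 1.41, "ria_percent": 35.0},
    "barefoot_slow": {"stride_time": 1.14, "stride_length": 1.27, "ria_percent": 37.0},
}

TRUTH_COLUMNS = ["trial_id", "subject", "side", "scenario", "cycle_index",
                 "ic_start_s", "ic_end_s", "mst_t_s", "ria_t_s"]


def generate_cohort(n_subjects: int = 15, strides_per_leg: int = 10,
                    scenario_grid: Optional[list[str]] = None,
                    strategy_mix: float = 0.5, seed: int = 0,
                    pre_rise_scale: float = 1.0,
                    base_pre_rise_rate: float = 25.0,
                    noise: bool = True,
                    with_crossings: bool = False,
                    cfg: Optional[DetectionConfig] = None,
                    ) -> tuple[list[TrialRecording], pd.DataFrame]:
    """A reproducible synthetic cohort: one trial per (subject, leg, scenario).

    Subject-level parameters (stride time factor, MST/RIA offsets, heel-rise
    strategy) are drawn once per subject; per-stride jitter adds within-leg
    variability.  A fraction ``strategy_mix`` of subjects are "pre-risers"
    whose heel creeps upward between MST and RIA at about
    ``base_pre_rise_rate * pre_rise_scale`` mm/s.

    Returns the trial list and a ground-truth table (one row per stride;
    per-detector crossing columns when ``with_crossings``).
    """
    if n_subjects < 1 or strides_per_leg < 1:
        raise InvalidParameterError("need at least one subject and stride")
    grid = scenario_grid or ["shod_normal"]
    unknown = [s for s in grid if s not in SCENARIOS]
    if unknown:
        raise InvalidParameterError(f"unknown scenarios {unknown}; "
                                    f"choose from {sorted(SCENARIOS)}")
    rng = np.random.default_rng(seed)
    n_pre = int(round(strategy_mix * n_subjects))

    trials: list[TrialRecording] = []
    rows: list[dict] = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        is_preriser = si < n_pre
        f_time = rng.normal(1.0, 0.04)
        mst_off = rng.normal(0.0, 0.7)
        ria_off = rng.normal(0.0, 0.7)
        amp = float(np.clip(rng.normal(80.0, 8.0), 50.0, 110.0))
        rate_subj = (float(np.clip(rng.normal(base_pre_rise_rate, 5.0), 5.0, 60.0))
                     * pre_rise_scale if is_preriser else 0.0)
        for scenario in grid:
            sc = SCENARIOS[scenario]
            for side in ("left", "right"):
                leg_off = rng.normal(0.0, 0.3)
                params: list[StrideModelParams] = []
                for _ in range(strides_per_leg):
                    T = float(np.clip(sc["stride_time"] * f_time
                                      + rng.normal(0.0, 0.02), 0.7, 1.6))
                    mst = float(np.clip(26.0 + mst_off + leg_off
                                        + rng.normal(0.0, 0.5), 20.0, 32.0))
                    ria = float(np.clip(sc["ria_percent"] + ria_off + leg_off
                                        + rng.normal(0.0, 0.5), mst + 4.0, 48.0))
                    params.append(StrideModelParams(
                        stride_time=T, stride_length=sc["stride_length"],
                        mst_percent=mst, ria_percent=ria,
                        pre_rise_rate=rate_subj, rise_amplitude=amp,
                        rise_duration=0.24 * T,
                        noise_sd_pos=0.3 if noise else 0.0,
                        noise_sd_imu=0.3 if noise else 0.0,
                        noise_sd_fy=2.0 if noise else 0.0,
                        noise_sd_gyro=5.0 if noise else 0.0,
                    ))
                trial_id = f"{subject}_{side}_{scenario}"
                trial_seed = int(rng.integers(0, 2 ** 31 - 1))
                trial, truth = generate_trial(
                    params, seed=trial_seed, trial_id=trial_id, subject=subject,
                    side=side, scenario=scenario, cfg=cfg,
                    with_crossings=with_crossings)
                trials.append(trial)
                for gt in truth:
                    row = {"trial_id": trial_id, "subject": subject,
                           "side": side, "scenario": scenario,
                           "cycle_index": gt.stride_index,
                           "ic_start_s": gt.ic_start, "ic_end_s": gt.ic_end,
                           "mst_t_s": gt.mst_t, "ria_t_s": gt.ria_t}
                    for method, tx in gt.crossings.items():
                        row[method] = tx
                    rows.append(row)
    truth_df = pd.DataFrame(rows)
    return trials, truth_df
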