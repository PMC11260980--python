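"""Detection configuration: every threshold, cutoff and window in one place.

Defaults are the published values of the method family: position thresholds
{3, 4, 5} mm and velocity thresholds {50, 80, 100} mm/s relative to the
mid-stance (MST) reference, heel-marker acceleration 1.9 m/s² and jerk
15 m/s³, IMU longitudinal acceleration 1 m/s² and jerk 12.5 m/s³, 10 Hz
marker/force cutoffs, 6 Hz IMU cutoff, and a 1125 Hz common grid.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

from .signal_core import InvalidParameterError


@dataclass(frozen=True)
class DetectionConfig:
    # HR thresholds
    pos_thresholds_mm: tuple[float, ...] = (3.0, 4.0, 5.0)
    vel_thresholds_mm_s: tuple[float, ...] = (50.0, 80.0, 100.0)
    hm_acc_threshold_m_s2: float = 1.9
    hm_jerk_threshold_m_s3: float = 15.0
    imu_acc_threshold_m_s2: float = 1.0
    imu_jerk_threshold_m_s3: float = 12.5
    # filtering
    marker_cutoff_hz: float = 10.0
    fy_cutoff_hz: float = 10.0
    imu_cutoff_hz: float = 6.0
    gyro_cutoff_hz: float = 6.0
    jerk_prefilter_cutoff_hz: float = 10.0
    filter_order: int = 2
    # grid & windows
    common_rate_hz: float = 1125.0
    search_end_percent: float = 60.0
    # initial-contact detection
    peak_prominence: float = 100.0  # deg/s
    min_stride_time: float = 0.6  # s
    max_peak_to_ic: float = 0.4  # s
    # IMU gravity compensation: window start (% of cycle); end is MST
    gravity_window_start_percent: float = 10.0
    # axis conventions
    gyro_axis_flip: bool = False
    fy_axis_flip: bool = False
    imu_precompensated: bool = False

    def __post_init__(self) -> None:
        thresholds = (*self.pos_thresholds_mm, *self.vel_thresholds_mm_s,
                      self.hm_acc_threshold_m_s2, self.hm_jerk_threshold_m_s3,
                      self.imu_acc_threshold_m_s2, self.imu_jerk_threshold_m_s3)
        if any(t <= 0 for t in thresholds):
            raise InvalidParameterError("all detection thresholds must be > 0")
        if not 0 < self.search_end_percent <= 100:
            raise InvalidParameterError("search_end_percent must lie in (0, 100]")
        if self.common_rate_hz <= 0:
            raise InvalidParameterError("common_rate_hz must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pos_thresholds_mm"] = list(self.pos_thresholds_mm)
        d["vel_thresholds_mm_s"] = list(self.vel_thresholds_mm_s)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("pos_thresholds_mm", "vel_thresholds_mm_s"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)
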