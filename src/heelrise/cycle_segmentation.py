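"""Gait-cycle segmentation from shank angular velocity.

Initial contacts (IC) delimit strides.  They are found as the first strict
local minimum following the distinctive mid-swing peak of the mediolateral
shank angular-velocity signal — the standard single-shank-gyro rule.  Event
times are then expressed as 0–100 % of the stride, and basic stride
parameters (time, length, velocity) are derived from the heel marker's
anteroposterior displacement between consecutive ipsilateral ICs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sps

from .signal_core import InsufficientDataError, InvalidParameterError, UniformSeries

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GaitCycle:
    """One stride delimited by consecutive ipsilateral initial contacts."""

    ic_start: float
    ic_end: float
    side: str = "right"
    index: int = 0

    def __post_init__(self) -> None:
        if not self.ic_end > self.ic_start:
            raise InvalidParameterError("ic_end must be after ic_start")

    @property
    def stride_time(self) -> float:
        return self.ic_end - self.ic_start


@dataclass(frozen=True)
class StrideParameters:
    stride_time: float  # s
    stride_length: float  # m
    stride_velocity: float  # m/s


def detect_initial_contacts(gyro_ml: UniformSeries, peak_prominence: float = 100.0,
                            min_stride_time: float = 0.6,
                            max_peak_to_ic: float = 0.4) -> list[float]:
    """IC times from a low-pass-filtered mediolateral shank angular velocity.

    For each accepted mid-swing peak (prominence >= ``peak_prominence`` deg/s,
    separated by at least ``min_stride_time`` s) the IC is the first strict
    sample-wise local minimum within ``max_peak_to_ic`` s after the peak.
    Returns an empty list (with a logged warning) when no peak is found.
    """
    y = gyro_ml.values
    if len(y) < 3:
        return []
    distance = max(int(round(min_stride_time * gyro_ml.rate)), 1)
    peaks, _ = _sps.find_peaks(y, prominence=peak_prominence, distance=distance)
    if peaks.size == 0:
        log.warning("no mid-swing peak found; returning no initial contacts")
        return []
    horizon = int(round(max_peak_to_ic * gyro_ml.rate))
    ics: list[float] = []
    for p in peaks:
        stop = min(p + horizon, len(y) - 1)
        for i in range(p + 1, stop):
            if y[i] < y[i - 1] and y[i] < y[i + 1]:
                ics.append(gyro_ml.t0 + i / gyro_ml.rate)
                break
    return sorted(ics)


def segment_cycles(ic_times: list[float], side: str = "right") -> list[GaitCycle]:
    """n ICs -> n-1 half-open cycles [ic_i, ic_{i+1})."""
    if any(b <= a for a, b in zip(ic_times, ic_times[1:])):
        raise InvalidParameterError("initial-contact times must be sorted ascending")
    return [GaitCycle(ic_start=a, ic_end=b, side=side, index=i)
            for i, (a, b) in enumerate(zip(ic_times, ic_times[1:]))]


def to_cycle_percent(t: float, cycle: GaitCycle) -> float:
    """Time normalized to 0–100 % of the stride."""
    if not cycle.ic_start - 1e-9 <= t <= cycle.ic_end + 1e-9:
        raise InvalidParameterError(
            f"t={t} outside cycle [{cycle.ic_start}, {cycle.ic_end}]")
    return 100.0 * (t - cycle.ic_start) / cycle.stride_time


def compute_stride_parameters(cycle: GaitCycle, heel_ap: UniformSeries) -> StrideParameters:
    """Stride time, length and velocity from heel AP displacement (mm -> m)."""
    span_lo = heel_ap.t0
    span_hi = heel_ap.t0 + heel_ap.duration
    if cycle.ic_start < span_lo - 1e-9 or cycle.ic_end > span_hi + 1e-9:
        raise InsufficientDataError("heel AP series does not span the cycle")
    length_m = abs(heel_ap.value_at(cycle.ic_end) - heel_ap.value_at(cycle.ic_start)) / 1000.0
    t = cycle.stride_time
    return StrideParameters(stride_time=t, stride_length=length_m,
                            stride_velocity=length_m / t)
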