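"""Uniformly sampled series, zero-phase filtering and differentiation.

All heel-rise detection in this package happens on a common uniform time
grid.  :class:`UniformSeries` is the single in-memory representation of one
channel; the operations here implement the preprocessing chain used by every
detector: a 2nd-order zero-phase (forward-backward) Butterworth low-pass,
central-difference differentiation up to jerk, and linear resampling onto a
common rate.

Unit conventions are fixed so the detection thresholds can be stated
literally: heel position in mm, velocity in mm/s, acceleration in m/s²
(the mm/s² -> m/s² factor of 1000 is applied exactly once, when the
acceleration channel is built) and jerk in m/s³.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as _sps


class InsufficientDataError(ValueError):
    """Series too short for the requested operation."""


class InvalidParameterError(ValueError):
    """Parameter outside its admissible range."""


_UNIT_PER_S = {
    "mm": "mm/s",
    "mm/s": "mm/s^2",
    "mm/s^2": "mm/s^3",
    "m/s^2": "m/s^3",
    "m/s": "m/s^2",
    "deg/s": "deg/s^2",
    "N": "N/s",
}


@dataclass(frozen=True)
class UniformSeries:
    """One uniformly sampled channel.

    Sample ``k`` has time ``t0 + k / rate`` exactly.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise InvalidParameterError("UniformSeries values must be 1-D")
        if not self.rate > 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def duration(self) -> float:
        """Time spanned from the first to the last sample."""
        return (len(self) - 1) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def index_at(self, t: float) -> int:
        """Nearest sample index for time ``t`` (clipped to the grid)."""
        k = int(round((t - self.t0) * self.rate))
        return min(max(k, 0), len(self) - 1)

    def value_at(self, t) -> np.ndarray | float:
        """Linearly interpolated value(s) at time(s) ``t`` (no extrapolation)."""
        t_arr = np.asarray(t, dtype=float)
        lo, hi = self.t0, self.t0 + self.duration
        if np.any(t_arr < lo - 1e-9) or np.any(t_arr > hi + 1e-9):
            raise InvalidParameterError("value_at outside the sampled span")
        out = np.interp(t_arr, self.times(), self.values)
        return float(out) if np.isscalar(t) else out

    def with_values(self, values: np.ndarray, units: Optional[str] = None) -> "UniformSeries":
        return replace(self, values=np.asarray(values, float),
                       units=self.units if units is None else units)


def lowpass_zero_phase(s: UniformSeries, cutoff_hz: float, order: int = 2) -> UniformSeries:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Forward-backward application cancels the phase response and squares the
    magnitude response, so the single-pass -3 dB cutoff becomes a -6 dB
    point (amplitude ratio 0.5) of the combined filter.  Edges are handled
    with odd (reflect-and-negate) padding of length ``3 * (order + 1)``,
    scipy's default for ``filtfilt``.
    """
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    if not 0 < cutoff_hz < s.rate / 2:
        raise InvalidParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={s.rate / 2} Hz)")
    padlen = 3 * (order + 1)
    if len(s) <= padlen:
        raise InsufficientDataError(
            f"series of length {len(s)} too short for edge padding ({padlen})")
    b, a = _sps.butter(order, cutoff_hz, btype="low", fs=s.rate)
    return s.with_values(_sps.filtfilt(b, a, s.values, padtype="odd", padlen=padlen))


def differentiate(s: UniformSeries) -> UniformSeries:
    """First time derivative: central differences, one-sided at the ends."""
    if len(s) < 3:
        raise InsufficientDataError("differentiate needs at least 3 samples")
    dv = np.gradient(s.values, s.dt)
    return s.with_values(dv, units=_UNIT_PER_S.get(s.units, f"{s.units}/s"))


def resample_linear(s: UniformSeries, target_rate_hz: float) -> UniformSeries:
    """Resample onto a new uniform grid from ``t0`` to the last sample time.

    Values are linearly interpolated; the new grid never extends beyond the
    original span, so no extrapolation occurs.
    """
    if not target_rate_hz > 0:
        raise InvalidParameterError("target rate must be > 0")
    if np.isclose(target_rate_hz, s.rate):
        return s
    n_new = int(np.floor(s.duration * target_rate_hz + 1e-9)) + 1
    t_new = s.t0 + np.arange(n_new) / target_rate_hz
    return UniformSeries(np.interp(t_new, s.times(), s.values),
                         rate=target_rate_hz, t0=s.t0, units=s.units)


@dataclass(frozen=True)
class KinematicChain:
    """Position, velocity, acceleration and jerk on one shared grid.

    ``position``/``velocity`` are ``None`` for the IMU chain, which starts
    from a measured acceleration.  Units: mm, mm/s, m/s², m/s³.
    """

    acceleration: UniformSeries
    jerk: UniformSeries
    position: Optional[UniformSeries] = None
    velocity: Optional[UniformSeries] = None

    def __post_init__(self) -> None:
        ref = self.acceleration
        for ch in (self.jerk, self.position, self.velocity):
            if ch is None:
                continue
            if len(ch) != len(ref) or not np.isclose(ch.rate, ref.rate) \
                    or not np.isclose(ch.t0, ref.t0):
                raise InvalidParameterError("chain channels must share the grid")


def build_kinematic_chain(heel_z: UniformSeries, marker_cutoff_hz: float = 10.0,
                          jerk_prefilter_cutoff_hz: float = 10.0,
                          filter_order: int = 2) -> KinematicChain:
    """Heel-marker chain: filter, then differentiate up to jerk.

    position  = low-pass(heel_z, 10 Hz)                      [mm]
    velocity  = d/dt position                                [mm/s]
    accel     = (d/dt velocity) / 1000                       [m/s²]
    jerk      = d/dt low-pass(accel, 10 Hz)                  [m/s³]

    The acceleration channel used for thresholding is *not* refiltered; the
    second 10 Hz pass applies only on the way to jerk.
    """
    pos = lowpass_zero_phase(heel_z, marker_cutoff_hz, filter_order)
    vel = differentiate(pos)
    acc_mm = differentiate(vel)
    acc = acc_mm.with_values(acc_mm.values / 1000.0, units="m/s^2")
    acc_refilt = lowpass_zero_phase(acc, jerk_prefilter_cutoff_hz, filter_order)
    jerk = differentiate(acc_refilt)
    return KinematicChain(position=pos, velocity=vel, acceleration=acc, jerk=jerk)


def build_imu_chain(acc_long: UniformSeries, imu_cutoff_hz: float = 6.0,
                    jerk_prefilter_cutoff_hz: float = 10.0,
                    filter_order: int = 2) -> KinematicChain:
    """Shank-IMU chain from (gravity-compensated) longitudinal acceleration.

    The acceleration is low-passed at 6 Hz; jerk mirrors the marker rule
    (a second 10 Hz pass before differentiation).
    """
    acc = lowpass_zero_phase(acc_long, imu_cutoff_hz, filter_order)
    acc_refilt = lowpass_zero_phase(acc, jerk_prefilter_cutoff_hz, filter_order)
    jerk = differentiate(acc_refilt)
    return KinematicChain(acceleration=acc, jerk=jerk)
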