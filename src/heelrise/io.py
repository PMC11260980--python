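"""File formats and run configuration.

A walking trial travels as a plain CSV with a ``time_s`` column plus any
subset of the channel schema below.  Channels recorded at different native
rates coexist in one file: slower channels leave NaN in the rows where they
have no sample, and each channel's native rate is inferred from its own
non-NaN time stamps.  On ingestion every channel is validated for uniform
sampling (1e-6 s jitter tolerance) and linearly resampled onto the common
grid (force-plate rate, 1125 Hz by default).

Channel schema (column name -> unit):

    heel_z_mm         heel marker vertical position, mm
    heel_ap_mm        heel marker anteroposterior position (ipsilateral), mm
    toe_ap_opp_mm     toe marker AP position of the *opposite* (swinging) foot, mm
    imu_acc_long_ms2  shank-IMU longitudinal acceleration, m/s²
    imu_gyro_ml_dps   shank-IMU mediolateral angular velocity, deg/s
    fy_n              force-plate anteroposterior shear force, N
                      (negative = braking, positive = propulsion)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .config import DetectionConfig
from .signal_core import InvalidParameterError, UniformSeries, resample_linear

CHANNEL_UNITS = {
    "heel_z_mm": "mm",
    "heel_ap_mm": "mm",
    "toe_ap_opp_mm": "mm",
    "imu_acc_long_ms2": "m/s^2",
    "imu_gyro_ml_dps": "deg/s",
    "fy_n": "N",
}

EVENT_COLUMNS = ["trial_id", "subject", "side", "scenario", "cycle_index",
                 "method", "detected", "t_s", "cycle_percent",
                 "heel_above_mst_mm", "mst_t_s", "failure_reason"]

_FLOAT_FMT = "%.9g"


class FormatError(ValueError):
    """Malformed trial or event file."""


@dataclass
class TrialRecording:
    """Synchronized, co-sampled channel bundle for one walking pass."""

    trial_id: str
    channels: dict[str, UniformSeries]
    subject: str = "S01"
    side: str = "right"
    scenario: str = "shod_normal"
    provenance: dict[str, float] = field(default_factory=dict)  # original rates

    def __post_init__(self) -> None:
        series = list(self.channels.values())
        if series:
            ref = series[0]
            for s in series[1:]:
                if len(s) != len(ref) or not np.isclose(s.rate, ref.rate) \
                        or not np.isclose(s.t0, ref.t0):
                    raise InvalidParameterError(
                        "trial channels must share one grid after ingestion")

    @property
    def rate(self) -> float:
        return next(iter(self.channels.values())).rate

    def has(self, name: str) -> bool:
        return name in self.channels


def _infer_uniform(t: np.ndarray, jitter_tol: float = 1e-6) -> float:
    """Sampling rate of a time vector, enforcing uniformity."""
    if t.size < 2:
        raise FormatError("channel has fewer than 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError("time stamps are not strictly increasing")
    if np.max(np.abs(dt - dt.mean())) > jitter_tol:
        raise FormatError(f"non-uniform sampling (jitter above {jitter_tol} s)")
    return 1.0 / dt.mean()


def read_trial_csv(path: str | Path, common_rate_hz: float = 1125.0,
                   trial_id: Optional[str] = None, subject: str = "S01",
                   side: str = "right", scenario: str = "shod_normal") -> TrialRecording:
    """Parse a trial CSV and resample every channel to the common rate."""
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path.name}: missing required column 'time_s'")
    unknown = [c for c in df.columns if c not in CHANNEL_UNITS and c != "time_s"]
    if unknown:
        raise FormatError(f"{path.name}: unknown channel columns {unknown} "
                          f"(expected subset of {sorted(CHANNEL_UNITS)})")
    t_all = df["time_s"].to_numpy(float)
    if np.any(np.diff(t_all) <= 0):
        raise FormatError(f"{path.name}: column 'time_s' is not strictly increasing")
    channels: dict[str, UniformSeries] = {}
    provenance: dict[str, float] = {}
    for name in df.columns:
        if name == "time_s":
            continue
        mask = df[name].notna().to_numpy()
        if not mask.any():
            continue
        t = t_all[mask]
        try:
            rate = _infer_uniform(t)
        except FormatError as e:
            raise FormatError(f"{path.name}: column '{name}': {e}") from e
        s = UniformSeries(df.loc[mask, name].to_numpy(float), rate=rate,
                          t0=float(t[0]), units=CHANNEL_UNITS[name])
        provenance[name] = rate
        channels[name] = resample_linear(s, common_rate_hz)
    # trim all channels to the shared span so the grids coincide
    if channels:
        t0 = max(s.t0 for s in channels.values())
        t_end = min(s.t0 + s.duration for s in channels.values())
        n = int(np.floor((t_end - t0) * common_rate_hz + 1e-9)) + 1
        for name, s in channels.items():
            k0 = int(round((t0 - s.t0) * common_rate_hz))
            channels[name] = UniformSeries(s.values[k0:k0 + n], rate=common_rate_hz,
                                           t0=t0, units=s.units)
    return TrialRecording(trial_id=trial_id or path.stem, channels=channels,
                          subject=subject, side=side, scenario=scenario,
                          provenance=provenance)


def write_trial_csv(trial: TrialRecording, path: str | Path) -> None:
    """Serialize a common-rate trial; round-trips losslessly to 1e-9."""
    path = Path(path)
    if not trial.channels:
        raise InvalidParameterError("cannot write a trial without channels")
    ref = next(iter(trial.channels.values()))
    data = {"time_s": ref.times()}
    for name in CHANNEL_UNITS:
        if name in trial.channels:
            data[name] = trial.channels[name].values
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    """Event table -> CSV in deterministic (trial, cycle, method) order."""
    df = events.reindex(columns=EVENT_COLUMNS)
    if len(df):
        df = df.sort_values(["trial_id", "cycle_index", "method"],
                            kind="mergesort").reset_index(drop=True)
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"event file missing columns {sorted(missing)}")
    return df


def write_report(report: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Write a summary table as CSV plus an aligned plain-text rendering."""
    path = Path(path)
    report.to_csv(path, index=False, float_format="%.4g")
    txt = path.with_suffix(".txt")
    with open(txt, "w") as fh:
        if title:
            fh.write(title + "\n" + "=" * len(title) + "\n")
        fh.write(report.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        fh.write("\n")


@dataclass
class RunConfig:
    """Detection config plus run-level settings; YAML round-trippable."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    seed: int = 0
    log_level: str = "INFO"
    input_dir: str = ""
    output_dir: str = ""
    scenario_labels: list[str] = field(default_factory=list)

    def to_yaml(self, path: str | Path) -> None:
        doc = {"detection": self.detection.to_dict(), "seed": self.seed,
               "log_level": self.log_level, "input_dir": self.input_dir,
               "output_dir": self.output_dir,
               "scenario_labels": list(self.scenario_labels)}
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        det = DetectionConfig.from_dict(doc.get("detection", {}))
        return cls(detection=det, seed=int(doc.get("seed", 0)),
                   log_level=str(doc.get("log_level", "INFO")),
                   input_dir=str(doc.get("input_dir", "")),
                   output_dir=str(doc.get("output_dir", "")),
                   scenario_labels=list(doc.get("scenario_labels", [])))
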