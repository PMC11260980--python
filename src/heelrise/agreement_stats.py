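"""Agreement and variability statistics for paired event detections.

The evaluation protocol compares each detector against a reference method
(e.g. visually identified heel rise) on paired per-stride event times:

* true-error metrics — mean error, sample SD, mean absolute error, with the
  sign convention ``method - reference`` (negative = method detects earlier);
* Bland-Altman 95 % limits of agreement (mean difference ± 1.96 SD);
* two-way mixed-effects intraclass correlation coefficients in all four
  McGraw-&-Wong forms — absolute agreement / consistency, single / average
  rating — with 95 % confidence intervals from the F-distribution bounds;
* Cohen's d between two methods' detection-point samples;
* the leg-wise variability decomposition: "SD of leg means" (between
  individuals) and "mean leg-specific SD" (within-session), where a leg is
  one (subject, side) unit.

Undetected events are handled by pairwise deletion with exclusion counts;
nothing is imputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _st

from .signal_core import InsufficientDataError, InvalidParameterError

log = logging.getLogger(__name__)


class UndefinedEffectError(ValueError):
    """Effect size undefined (zero pooled variance)."""


@dataclass(frozen=True)
class PairedDetections:
    """Paired event times (ms) for one method against the reference.

    Pairs where either side is undetected (NaN) are excluded and counted.
    """

    reference_ms: np.ndarray
    method_ms: np.ndarray
    strata: Optional[pd.DataFrame] = None  # subject / leg / scenario labels
    n_excluded: int = 0

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_ms, float)
        met = np.asarray(self.method_ms, float)
        if ref.shape != met.shape:
            raise InvalidParameterError("paired sequences must have equal length")
        valid = np.isfinite(ref) & np.isfinite(met)
        object.__setattr__(self, "reference_ms", ref[valid])
        object.__setattr__(self, "method_ms", met[valid])
        object.__setattr__(self, "n_excluded",
                           self.n_excluded + int((~valid).sum()))
        if self.strata is not None:
            object.__setattr__(self, "strata",
                               self.strata.loc[valid].reset_index(drop=True))

    @property
    def n_pairs(self) -> int:
        return self.reference_ms.size

    @property
    def differences(self) -> np.ndarray:
        return self.method_ms - self.reference_ms


@dataclass(frozen=True)
class AgreementReport:
    method: str
    reference: str
    n_pairs: int
    n_excluded: int
    mean_error_ms: float
    sd_error_ms: float
    mae_ms: float
    loa_low_ms: float
    loa_high_ms: float
    icc_abs_single: tuple[float, float, float]
    icc_abs_avg: tuple[float, float, float]
    icc_cons_single: tuple[float, float, float]
    icc_cons_avg: tuple[float, float, float]


def error_metrics(p: PairedDetections) -> tuple[float, float, float]:
    """(mean error, sample SD, MAE) of method - reference, in ms."""
    if p.n_pairs < 2:
        raise InsufficientDataError("need at least 2 valid pairs")
    d = p.differences
    return float(d.mean()), float(d.std(ddof=1)), float(np.abs(d).mean())


def bland_altman(p: PairedDetections) -> tuple[float, float, float]:
    """(mean difference, lower LoA, upper LoA); LoA = mean ± 1.96 SD."""
    if p.n_pairs < 2:
        raise InsufficientDataError("need at least 2 valid pairs")
    d = p.differences
    m, s = float(d.mean()), float(d.std(ddof=1))
    return m, m - 1.96 * s, m + 1.96 * s


def anova_mean_squares(ratings: np.ndarray) -> tuple[float, float, float]:
    """(MS_rows, MS_cols, MS_error) of the two-way crossed ANOVA
    decomposition (rows = targets/strides, columns = raters/methods)."""
    x = np.asarray(ratings, float)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1, keepdims=True)
    col_means = x.mean(axis=0, keepdims=True)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    # residual computed directly (not by subtraction) so perfect-agreement
    # matrices give an exact zero
    ss_err = np.sum((x - row_means - col_means + grand) ** 2)
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_two_way(ratings: np.ndarray, form: str = "absolute",
                unit: str = "single", alpha: float = 0.05,
                ) -> tuple[float, float, float]:
    """Two-way mixed-effects ICC with a 95 % confidence interval.

    ``form`` is ``"absolute"`` (agreement) or ``"consistency"``; ``unit`` is
    ``"single"`` or ``"average"``.  Rows with missing cells are dropped.
    When every value is identical the ICC is defined as 1 with a degenerate
    interval.
    """
    x = np.asarray(ratings, float)
    if x.ndim != 2:
        raise InvalidParameterError("ratings must be an n x k matrix")
    keep = np.all(np.isfinite(x), axis=1)
    if not keep.all():
        log.info("icc_two_way: dropping %d rows with missing cells",
                 int((~keep).sum()))
        x = x[keep]
    n, k = x.shape
    if n < 5 or k < 2:
        raise InsufficientDataError("ICC needs at least 5 targets and 2 raters")
    if form not in ("absolute", "consistency") or unit not in ("single", "average"):
        raise InvalidParameterError("form: absolute|consistency; unit: single|average")
    if np.allclose(x, x.flat[0]):
        log.info("icc_two_way: degenerate (constant) ratings; ICC := 1")
        return 1.0, 1.0, 1.0
    msr, msc, mse = anova_mean_squares(x)

    if form == "consistency":
        if mse == 0:
            log.info("icc_two_way: zero residual variance; consistency := 1")
            return 1.0, 1.0, 1.0
        if unit == "single":
            icc = (msr - mse) / (msr + (k - 1) * mse)
        else:
            icc = (msr - mse) / msr if msr > 0 else 0.0
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / _st.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * _st.f.ppf(1 - alpha / 2, df2, df1)
        lo_s = (fl - 1) / (fl + k - 1)
        hi_s = (fu - 1) / (fu + k - 1)
        lo, hi = (lo_s, hi_s) if unit == "single" else (
            _spearman_brown(lo_s, k), _spearman_brown(hi_s, k))
    else:
        denom_s = msr + (k - 1) * mse + k * (msc - mse) / n
        icc_s = (msr - mse) / denom_s if denom_s != 0 else 0.0
        icc = icc_s if unit == "single" else (
            (msr - mse) / (msr + (msc - mse) / n)
            if (msr + (msc - mse) / n) != 0 else 0.0)
        # Satterthwaite df for the absolute-agreement interval
        a = k * icc_s / (n * (1 - icc_s)) if icc_s < 1 else math.inf
        b = 1 + k * icc_s * (n - 1) / (n * (1 - icc_s)) if icc_s < 1 else math.inf
        if math.isinf(a):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = ((a * msc) ** 2 / (k - 1)
                   + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            v = num / den if den > 0 else 1.0
            f1 = _st.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = _st.f.ppf(1 - alpha / 2, v, n - 1)
            lo_s = n * (msr - f1 * mse) / (
                f1 * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi_s = n * (f2 * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f2 * msr)
            lo, hi = (lo_s, hi_s) if unit == "single" else (
                _spearman_brown(lo_s, k), _spearman_brown(hi_s, k))
    lo, hi = min(lo, icc), max(hi, icc)
    return float(icc), float(lo), float(hi)


def _spearman_brown(r: float, k: int) -> float:
    if r >= 1.0:
        return 1.0
    return k * r / (1 + (k - 1) * r)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled SD."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs at least 2 values")
    na, nb = a.size, b.size
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                       / (na + nb - 2))
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0
        raise UndefinedEffectError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / pooled)


def agreement_report(p: PairedDetections, method: str = "method",
                     reference: str = "reference") -> AgreementReport:
    """Full Table-3-style agreement summary for one method vs the reference."""
    me, sd, mae = error_metrics(p)
    _, lo, hi = bland_altman(p)
    mat = np.column_stack([p.reference_ms, p.method_ms])
    return AgreementReport(
        method=method, reference=reference, n_pairs=p.n_pairs,
        n_excluded=p.n_excluded, mean_error_ms=me, sd_error_ms=sd, mae_ms=mae,
        loa_low_ms=lo, loa_high_ms=hi,
        icc_abs_single=icc_two_way(mat, "absolute", "single"),
        icc_abs_avg=icc_two_way(mat, "absolute", "average"),
        icc_cons_single=icc_two_way(mat, "consistency", "single"),
        icc_cons_avg=icc_two_way(mat, "consistency", "average"))


def agreement_table(reports: list[AgreementReport]) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append({
            "method": r.method, "reference": r.reference, "n_pairs": r.n_pairs,
            "n_excluded": r.n_excluded, "mean_error_ms": r.mean_error_ms,
            "sd_error_ms": r.sd_error_ms, "loa_low_ms": r.loa_low_ms,
            "loa_high_ms": r.loa_high_ms, "mae_ms": r.mae_ms,
            "icc_abs_single": r.icc_abs_single[0],
            "icc_abs_single_ci_low": r.icc_abs_single[1],
            "icc_abs_single_ci_high": r.icc_abs_single[2],
            "icc_abs_avg": r.icc_abs_avg[0],
            "icc_cons_single": r.icc_cons_single[0],
            "icc_cons_avg": r.icc_cons_avg[0],
        })
    return pd.DataFrame(rows)


def pair_events(events: pd.DataFrame, method: str, reference: str,
                value: str = "t_s") -> PairedDetections:
    """Build paired detections (in ms) for two methods from an event table."""
    key = ["trial_id", "cycle_index"]
    a = events[events["method"] == reference].set_index(key)
    b = events[events["method"] == method].set_index(key)
    joined = a[[value, "detected", "subject", "side", "scenario"]].join(
        b[[value, "detected"]], how="inner", lsuffix="_ref", rsuffix="_met")
    ref = np.where(joined["detected_ref"].astype(bool),
                   joined[f"{value}_ref"], np.nan) * 1000.0
    met = np.where(joined["detected_met"].astype(bool),
                   joined[f"{value}_met"], np.nan) * 1000.0
    strata = joined[["subject", "side", "scenario"]].reset_index(drop=True)
    return PairedDetections(reference_ms=ref, method_ms=met, strata=strata)


def variability_summary(events: pd.DataFrame,
                        values: tuple[str, ...] = ("cycle_percent",
                                                   "heel_above_mst_mm"),
                        ) -> pd.DataFrame:
    """Leg-wise variability per (method, scenario).

    For each quantity: the reported mean is the mean of per-leg means, the
    "SD of leg means" is the sample SD across legs (between-individual
    variability) and the "mean leg-specific SD" is the mean of within-leg
    sample SDs (within-session variability).  Legs with a single stride
    contribute a mean but no within-leg SD.
    """
    det = events[events["detected"].astype(bool)].copy()
    rows = []
    for (method, scenario), grp in det.groupby(["method", "scenario"],
                                               sort=True):
        row: dict = {"method": method, "scenario": scenario,
                     "n_strides": len(grp), "n_legs":
                     grp.groupby(["subject", "side"]).ngroups}
        for val in values:
            legs = grp.groupby(["subject", "side"])[val]
            leg_means = legs.mean()
            leg_sds = legs.std(ddof=1).dropna()
            if len(leg_sds) < legs.ngroups:
                log.info("variability_summary: %d leg(s) with < 2 strides "
                         "contribute no within-leg SD",
                         legs.ngroups - len(leg_sds))
            row[f"mean_{val}"] = float(leg_means.mean())
            row[f"sd_of_leg_means_{val}"] = (
                float(leg_means.std(ddof=1)) if len(leg_means) > 1 else np.nan)
            row[f"mean_leg_specific_sd_{val}"] = (
                float(leg_sds.mean()) if len(leg_sds) else np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
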