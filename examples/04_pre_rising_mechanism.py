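"""The pre-rising confound: why jerk-based detection is robust.

Doubling the cohort's pre-rise rate (the slow heel creep between mid-stance
and the rapid-rise instant) drags position- and velocity-threshold
detections tens of milliseconds earlier, while the jerk-based detector
stays anchored to RIA.
"""

import pandas as pd

from heelrise import detect_all, generate_cohort


def mean_delta_ms(pre_rise_scale):
    trials, truth = generate_cohort(n_subjects=8, strides_per_leg=4,
                                    scenario_grid=["shod_normal"],
                                    strategy_mix=0.5, seed=11,
                                    pre_rise_scale=pre_rise_scale)
    events = pd.concat([detect_all(t) for t in trials], ignore_index=True)
    key = ["trial_id", "cycle_index"]
    merged = events.merge(truth[key + ["ria_t_s"]], on=key)
    det = merged[merged["detected"]].copy()
    det["delta_ms"] = (det["t_s"] - det["ria_t_s"]) * 1000.0
    return det.groupby("method")["delta_ms"].mean()


base = mean_delta_ms(1.0)
doubled = mean_delta_ms(2.0)
out = pd.DataFrame({"baseline_ms": base, "doubled_pre_rise_ms": doubled,
                    "shift_ms": (doubled - base).abs()}).round(1)
print("Mean detection time relative to RIA (ms), before/after doubling the "
      "pre-rise rate:\n")
print(out.loc[["HM-POS3", "HM-POS4", "HM-POS5", "HM-VEL50", "HM-VEL80",
               "HM-JERK", "IMU-JERK", "HM-ACC", "IMU-ACC"]].to_string())
ratio = out.loc["HM-POS4", "shift_ms"] / max(out.loc["HM-JERK", "shift_ms"], 1e-9)
print(f"\nHM-POS4 shifts {ratio:.0f}x more than HM-JERK: the position "
      "threshold reacts to the pre-rise itself, the jerk threshold only to "
      "the rapid-acceleration onset it was designed to find.")
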