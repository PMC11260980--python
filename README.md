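# heelrise

Heel rise (HR, "heel-off") marks the transition from mid-stance to terminal
stance. Unlike initial contact or toe-off it is a *gradual* event — the heel
often creeps upward slowly before its rapid rise toward forefoot-rocker
motion — so different detection rules can disagree by tens of milliseconds
on the same stride. `heelrise` implements a family of HR detectors for the
three instrument classes used in gait laboratories, on one shared
preprocessing and gait-cycle segmentation chain, together with the agreement
statistics needed to compare them and a synthetic stride generator that
provides exact ground truth for validation.

It is written for movement scientists and biomechanics engineers who need a
reproducible, testable HR definition for gait-phase separation.

## The detectors

All signals are resampled to a common grid (force-plate rate, 1125 Hz by
default). Heel-marker vertical position and the anteroposterior shear force
Fy are low-pass filtered with a 2nd-order zero-phase (forward–backward)
Butterworth at 10 Hz; shank-IMU longitudinal acceleration at 6 Hz. Vertical
velocity v(t), acceleration a(t) and jerk j(t) are the first/second/third
time derivatives of the filtered heel height z(t) (central differences),
with one extra 10 Hz pass on a(t) before differentiating to jerk. Gait
cycles are delimited by initial contacts (IC), detected as the first strict
local minimum after the prominent mid-swing peak of the mediolateral shank
angular velocity.

Each cycle's reference instant is the mid-stance event **MST** — the first
sample where the swinging foot's toe marker passes the stance foot's heel
marker in the walking direction. Searching strictly after MST (up to 60 %
of the cycle):

| method | rule |
|---|---|
| HM-POS3/4/5 | z(t) − z(MST) ≥ 3 / 4 / 5 mm |
| HM-VEL50/80/100 | v(t) ≥ 50 / 80 / 100 mm/s |
| HM-ACC | a(t) ≥ 1.9 m/s² |
| HM-JERK | last upward crossing of j(t) through 15 m/s³ before the HM-ACC instant |
| FP-ZC | braking→propulsion zero crossing of Fy |
| IMU-ACC | gravity-compensated shank longitudinal acceleration ≥ 1 m/s² |
| IMU-JERK | last sub-12.5 m/s³ jerk sample before the IMU-ACC instant |

The jerk rules target the **RIA** (rapid increase in acceleration) — the
kinematic onset of the true heel rise — and are robust to "pre-rising",
the slow sub-threshold heel elevation between MST and RIA that some
individuals show and that drags position/velocity thresholds early.

Agreement between methods is quantified with the standard protocol: error
statistics (mean ± SD, MAE, method − reference in ms), Bland–Altman 95 %
limits of agreement (mean ± 1.96 SD), and two-way mixed-effects intraclass
correlation coefficients (absolute agreement and consistency, single and
average rating, with 95 % F-distribution confidence intervals), plus
leg-wise variability summaries ("SD of leg means" between individuals,
"mean leg-specific SD" within a leg).

## Worked example

```python
from heelrise import StrideModelParams, generate_stride

p = StrideModelParams(pre_rise_rate=0.0, noise_sd_pos=0, noise_sd_imu=0,
                      noise_sd_fy=0, noise_sd_gyro=0)
trial, gt = generate_stride(p)       # six channels + exact event times
```

Running `python examples/01_simulate_stride.py` prints, for the abrupt
strategy (no pre-rise, normal shod speed):

```
abrupt stride (stride time 1.05 s)
  MST (toe passes heel)  at  26.0 % of the cycle
  RIA (rapid rise onset) at  36.5 %
  HM-POS3    fires at  41.9 %
  HM-VEL50   fires at  39.6 %
  HM-ACC     fires at  38.3 %
  HM-JERK    fires at  34.6 %
  FP-ZC      fires at  34.0 %
  IMU-ACC    fires at  36.6 %
  IMU-JERK   fires at  32.9 %
```

HM-JERK and IMU-JERK fire within ~2 % of the RIA instant; position and
velocity thresholds fire 3–6 % of the cycle later, because the heel must
physically clear the threshold. `examples/04_pre_rising_mechanism.py` shows
the flip side: doubling the cohort's pre-rise rate moves HM-POS4 by ~36 ms
while HM-JERK moves by ~1 ms.

The other examples cover the full pipeline on noisy trials
(`02_detect_heel_rise.py`) and the agreement/variability statistics
(`03_agreement_statistics.py`).

## Command line

```bash
heelrise simulate --out data/ --seed 1 --n-subjects 10   # synthetic cohort
heelrise detect   --in data/ --out events.csv            # full pipeline
heelrise evaluate --events events.csv --truth data/ground_truth.csv --out eval/
heelrise report   --events events.csv --out tables/      # variability tables
```

Trials are plain CSV (`time_s` plus any subset of the documented channel
columns; channels may carry different native rates and are resampled on
ingestion). All outputs are deterministic given inputs, config and seed.

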