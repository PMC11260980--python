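# Methods

## Signal model and preprocessing

Every channel is a uniformly sampled series; all detection happens after
linear resampling to a common grid (default 1125 Hz, the force-plate rate —
marker and IMU channels arrive at lower native rates and are upsampled).
Filtering is a 2nd-order Butterworth applied forward and backward
(`scipy.signal.filtfilt`, odd padding of length 3·(order+1)): the phase
response cancels and the magnitude response squares, so the nominal cutoff
becomes an amplitude-ratio-0.5 point. Cutoffs: 10 Hz for heel markers and
Fy, 6 Hz for IMU acceleration and for the gyro channel used in
segmentation. Derivatives use central differences with one-sided endpoints;
the kinematic chain is fixed to mm, mm/s, m/s², m/s³, with the single
mm→m factor applied when the acceleration channel is built. The heel
acceleration (and, by symmetry, the IMU acceleration) receives one extra
10 Hz pass before differentiation to jerk; the acceleration used for
thresholding is the once-filtered one.

## Detection rules

Initial contacts are the first strict sample-wise local minimum within
0.4 s after each accepted mid-swing peak of the mediolateral shank angular
velocity (peak prominence ≥ 100 deg/s, minimum separation 0.6 s; an
axis-flip flag accommodates opposite sensor mountings). MST is the first
sample where the contralateral toe's AP position reaches the stance heel's;
the filtered heel height at that sample is the per-cycle reference. All HR
searches run strictly after MST and close at 60 % of the cycle —
comfortably past every detector's operating range (~33–43 %) and before
swing. "Exceeds" means the first sample at or above the threshold (ties
count as crossed). The two "last time before" jerk rules are
operationalized as the boundary of the final supra-threshold run ending at
the acceleration crossing: the marker rule reports the upward-crossing
sample, the IMU rule the last sub-threshold sample; the one-sample
difference between the two readings is intentional and documented here.
FP-ZC additionally records the linearly interpolated crossing time
(the force signal's fidelity supports sub-sample timing); cycle-percent
bookkeeping uses the grid sample. IMU gravity compensation subtracts the
mean raw longitudinal acceleration over a flat-foot window (10 % of the
cycle up to MST) per stride; a config flag accepts pre-compensated input.

Failed preconditions (no MST, missing channel, threshold never reached)
produce undetected rows with a categorical reason — failures are data,
never exceptions.

## Synthetic stride model

The generator emulates the morphology the detectors key on, with every
event time known on the continuous model:

* Heel height: zero through early stance; an optional **pre-rise** — a
  quintic smoothstep whose amplitude is `pre_rise_rate` × the MST→RIA
  window, starting 20 % into that window (the pre-rise begins just after
  MST) — then, from RIA, a 9th-order (C⁴-continuous) smoothstep adding
  `rise_amplitude` (default 80 mm) over `rise_duration` (default 0.24 ×
  stride time); a raised-cosine swing hump returns to baseline at the next
  IC. The C⁴ joint keeps the jerk channel band-limited so the 10 Hz
  zero-phase filter does not displace threshold crossings; a C² joint would
  put a jerk discontinuity of hundreds of m/s³ at RIA and make any
  continuous-time oracle disagree with the sampled pipeline by many
  samples.
* AP markers: stance heel constant, advancing by the stride length during
  swing; the contralateral toe holds during its own stance and advances
  linearly during its swing, crossing the stance heel exactly at
  `mst_percent`.
* Shank gyro: a 300 deg/s mid-swing peak at 76 % of the cycle descending
  strictly into a deep, sharp, symmetric IC minimum (400 deg/s deep, 6 % of
  the stride in half-width). The dip is deliberately pronounced: its
  sharpness, together with the 6 Hz segmentation filter, makes the
  first-strict-minimum rule an unbiased IC estimator whose scatter stays
  below ~0.6 samples at gyro noise up to 10 % of the peak amplitude.
  Real IC transients are often shallower; segmentation accuracy on real
  data will degrade accordingly.
* Fy: a C¹ two-lobe braking/propulsion curve with its upward zero crossing
  exactly at `fy_zc_percent` (default 34 %).
* IMU longitudinal acceleration: `imu_gain` (default 0.6) × the analytic
  heel acceleration plus a constant gravity component (default 9.55 m/s²,
  a slightly tilted shank axis); the generator can also emit compensated
  output. The gain reflects that the shank is less affected by heel rise
  than the heel marker, consistent with the lower IMU thresholds.

Default condition regimes (stride time / length and RIA percent per speed
and footwear) follow normal gait: shod 0.95/1.05/1.17 s, 1.71/1.45/1.31 m,
RIA 35/36.5/38.5 %; barefoot slightly faster strides with RIA 2 % earlier.
MST defaults to 26 % of the cycle. Channel noise defaults: 0.3 mm markers,
0.3 m/s² IMU, 2 N force, 5 deg/s gyro — optical-capture-grade marker noise
and consumer-IMU-grade inertial noise. Cohort generation draws
subject-level offsets (stride-time factor SD 4 %, MST/RIA offsets SD 0.7 %,
rise amplitude SD 8 mm) plus per-stride jitter (SD 0.5 %), with a
configurable fraction of "pre-risers" at 25 ± 5 mm/s.

### Ground truth

Ground truth is computed on the noise-free continuous model **through the
method's own filter chain**: channels are evaluated analytically on a dense
100 kHz grid, filtered with the same zero-phase Butterworth design,
differentiated numerically at that resolution, and crossings located by
linear interpolation — an oracle that shares no code path, grid or crossing
logic with the sample-resolution detectors. Filtering belongs in the oracle
because the detectors are *defined* on filtered signals: the 10 Hz filter
attenuates the ~4 Hz rise by ~2 %, which alone shifts raw-model crossings
by several milliseconds. The raw (unfiltered) closed forms — e.g. the
9th-order smoothstep inverse for position thresholds — are kept as a
separate check of the model/scan machinery at 1e−5 s.

## What the synthetic tests do and do not show

Passing tests demonstrate that the detectors implement their definitions
exactly (one-sample agreement with the continuous oracle), that the
detector orderings and the pre-rising mechanism follow from those
definitions, and that the statistics match their ANOVA/closed-form
oracles. They do not validate the detectors against recorded human gait:
the model has no soft-tissue artifact, marker occlusion, kinetic
consistency between Fy and the kinematics, or pathological patterns, and
its noise is white and Gaussian. Quantities like the mean detection cycle
points reported by the examples are properties of the model's default
regimes, not measurements.

## Numerical choices

* Threshold semantics: first sample ≥ threshold; sample-resolution
  reporting (except FP-ZC's interpolated time, see above).
* Detector/oracle comparisons allow 1.02 sample periods: one sample of
  quantization plus ≤ 2 % of a sample for the difference between the
  1125 Hz and 100 kHz bilinear approximations of the same analog filter.
* ICC follows the McGraw & Wong two-way mixed-effects mean-squares forms;
  residual sums of squares are computed directly (not by subtraction) so
  perfect agreement yields exactly 1; degenerate (constant) matrices define
  ICC = 1 with a collapsed interval; confidence level fixed at 95 %, sample
  SDs use n−1, the Bland–Altman multiplier is exactly 1.96.
* Cohen's d is (mean_a − mean_b)/pooled SD; zero pooled SD with unequal
  means is an error, with equal means it is 0.
* Undetected events: pairwise deletion with exclusion counts; no
  imputation.
* Determinism: one `numpy` Generator seeded per trial/cohort; CSV writers
  use fixed float formats and a fixed (trial, cycle, method) row order.

## Problem sizes

The validation suite uses desk-scale problems chosen to exercise the full
parameter grid: 216 noise-free strides (6 scenarios × 2 strategies × 3
morphological variants × 6 rise durations) for oracle equivalence, 1000
random strides for ordering invariants, a 20-subject × 2-leg × 3-speed ×
5-stride noisy cohort (600 strides per condition) for the pre-rising
mechanism, and 500 strides at gyro noise swept from 0 to 30 deg/s for
IC recovery.

## Known limitations

Stride-length estimation uses heel-marker AP displacement between
ipsilateral ICs — adequate for the generator's geometry, simplistic for
real marker sets. The search-window end (60 %) and the IC-search horizon
(0.4 s) are tuned for healthy-speed walking; very slow or pathological
gait may need different windows, and no speed adaptation of the thresholds
is implemented. Left/right feet are carried as separate trials ("leg" =
subject × side); bilateral event interleaving is out of scope. C3D or
vendor formats are not read; the CSV schema is the interchange format.
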