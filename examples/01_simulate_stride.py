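"""Generate one synthetic stride and inspect its ground-truth event times.

The stride model produces the six channels the detectors consume (heel
vertical/AP markers, contralateral toe AP, shank gyro, shank longitudinal
acceleration, anteroposterior shear force) plus the exact instant every
detector should fire on the noise-free model.
"""

from heelrise import StrideModelParams, generate_stride

# an "abrupt" heel-rise strategy (no pre-rise) at normal shod walking speed
abrupt = StrideModelParams(pre_rise_rate=0.0, noise_sd_pos=0, noise_sd_imu=0,
                           noise_sd_fy=0, noise_sd_gyro=0)
# a "pre-riser": the heel creeps up ~2.8 mm between mid-stance and the
# rapid-rise instant (RIA)
preriser = StrideModelParams(pre_rise_rate=25.0, noise_sd_pos=0,
                             noise_sd_imu=0, noise_sd_fy=0, noise_sd_gyro=0)

for label, params in [("abrupt", abrupt), ("pre-riser", preriser)]:
    trial, gt = generate_stride(params)
    T = gt.ic_end - gt.ic_start
    pct = lambda t: 100.0 * (t - gt.ic_start) / T
    print(f"\n{label} stride (stride time {T:.2f} s)")
    print(f"  MST (toe passes heel)  at {pct(gt.mst_t):5.1f} % of the cycle")
    print(f"  RIA (rapid rise onset) at {pct(gt.ria_t):5.1f} %")
    for method, t in gt.crossings.items():
        mark = "-" if t is None else f"{pct(t):5.1f} %"
        print(f"  {method:10s} fires at {mark}")

print("""
Reading the numbers: position/velocity thresholds fire well after RIA for
the abrupt strategy but drift earlier for the pre-riser, while the
jerk-based detectors stay anchored near RIA — the core robustness
difference between the method families.""")
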