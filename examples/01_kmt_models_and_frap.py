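"""Selective-detachment model: calibration and simulated photobleaching.

Calibrates the nucleation rate so the steady state carries ~227 KMTs (the
metaphase median per half spindle), then bleaches a 1 um box 2.5 um from
the chromosomes and reports the recovery half-time and its fast/slow
decomposition.
"""

from dataclasses import replace

import numpy as np

from spindlekit import (
    SimParams,
    calibrate_nucleation_rate,
    frap_half_time,
    frap_two_component_fit,
    simulate_frap,
)

params = SimParams.published("selective_detachment", R=200.0)
cal = calibrate_nucleation_rate(params, target_kmt_count=227.0, tol=0.05, seed=0)
print(f"calibrated nucleation rate R = {cal.R:.1f} MTs/s "
      f"(steady-state KMT mean {cal.kmt_mean:.1f})")

params = replace(params, R=cal.R)
curves = [simulate_frap(params, seed) for seed in range(8)]
t = curves[0].times
S = np.mean([c.S for c in curves], axis=0)

half = frap_half_time(t, S)
fit = frap_two_component_fit(t, S)
print(f"recovery half-time: {half:.1f} s")
print(f"fast exponential component: tau = {fit.tau_fast:.1f} s  (SMT turnover by catastrophe)")
print(f"slow linear component: {fit.ramp_duration:.1f} s ramp  (KMT minus-end depolymerisation)")
# The fast time constant tracks 1/kappa-scale SMT turnover; the ~20 s ramp
# is the time KMT minus-ends need to sweep the bleached marks out of the box.
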