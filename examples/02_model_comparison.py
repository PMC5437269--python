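"""Compare the three KMT-formation models at their published parameters.

Reports the time for a de-novo spindle to reach its steady-state KMT
count and the shape of the steady-state KMT length distribution — the
two observables that separate the models.
"""

from dataclasses import replace

import numpy as np

from spindlekit import (
    SimParams,
    calibrate_nucleation_rate,
    extract_distributions,
    run_model,
    steady_state_time_from_counts,
)

for model in ("flux", "stochastic_detachment", "selective_detachment"):
    params = SimParams.published(model, R=100.0)
    cal = calibrate_nucleation_rate(params, 227.0, tol=0.05, seed=1,
                                    burn_in=600.0 if model == "flux" else 120.0,
                                    n_snapshots=8, sample_dt=15.0)
    params = replace(params, R=cal.R)
    t_end = 900.0 if model == "flux" else 300.0
    curves = [run_model(params, t_end, seed=s, sample_dt=2.0, record_snapshots=False).n_kmt
              for s in range(4)]
    times = np.arange(0.0, t_end + 1e-9, 2.0)
    settle = steady_state_time_from_counts(times, np.mean(curves, axis=0))

    traj = run_model(params, t_end, seed=99, sample_dt=30.0)
    kmt = extract_distributions(traj, burn_in=t_end / 3)["kmt_length"]
    body = kmt.mean[:9]
    shape = "decaying" if body[0] > 2 * body[-1] else "flat"
    print(f"{model:24s} R={cal.R:7.1f}/s  settle={settle:6.1f} s  "
          f"KMT length histogram (0-4.5 um): {np.round(body, 1)} -> {shape}")
# Only minus-end detachment lets the spindle assemble in under a minute;
# only *selective* detachment (KMTs alone switching) keeps the KMT length
# distribution flat, as observed by electron tomography.
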