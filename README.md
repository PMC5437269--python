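# spindlekit

Stochastic models and 3D-reconstruction analyses of kinetochore-microtubule
(KMT) organisation in the *C. elegans* mitotic spindle.

*C. elegans* chromosomes are holocentric: instead of a point kinetochore,
microtubule attachment sites line the whole pole-facing chromosome surface.
Electron tomography of these spindles shows that most KMTs do not reach the
centrosome, that KMT lengths are nearly uniform while spindle (SMT) and
astral (AMT) microtubule lengths decay exponentially, and that the
photobleaching mark of spindle tubulin barely moves. `spindlekit` packages
the quantitative machinery behind those observations for people who model
spindle assembly or analyse filament reconstructions:

* **1D stochastic models of KMT formation and turnover.** Microtubules
  nucleate at Poisson rate $R$ with minus-ends within 3 µm of the
  centrosome, grow at $v_g$, are destroyed by catastrophe at rate $\kappa$
  while their plus-end is free, and become KMTs on reaching the chromosomes
  at distance $L$.  Free growth has the steady-state length law
  $\psi(\ell) = A\,e^{-\ell/(v_g/\kappa)}$.  Three variants remove
  microtubules in different ways — **flux** (plus-ends shrink at $v_d$ after
  attachment), **stochastic detachment** (every minus-end switches at rate
  $r$ to shrinking at $v_d$) and **selective detachment** (only KMT
  minus-ends switch).  The models are realised exactly by an event-driven
  scheme (exponential clocks for nucleation, catastrophe and switching;
  analytically scheduled boundary events), with nucleation-rate calibration
  against a target KMT count and simulated FRAP,
  $S(t) = [M(t) - B(t)]/M(t)$, for a bleached box of spindle material.
* **Geometric and statistical analysis of 3D microtubule traces** —
  KMT/SMT/AMT classification (kinetochore-zone rule, then an 18.4°
  centre-of-mass cone), endpoint-distance CDFs, axial crossing densities,
  filtered length distributions, the radial distribution function of
  attachment sites on the metaphase plate, per-chromosome attachment
  statistics and a z-endpoint density check for section stitching.
* **Interaction-network connectivity** — a graph whose edges are
  microtubule pairs within an interaction distance $a$ and chord angle
  $\beta$, and shortest-path counts of how many interactions a KMT needs to
  reach a centrosome-connected microtubule.
* **Dynamic-imaging estimators** — EB-comet velocimetry by spatio-temporal
  correlation of wavelet-resynthesised radial fields, and FRAP-profile
  analysis (chromatin-peak alignment, quadratic trough fits, drift velocity
  and recovery half-time).
* **Synthetic data generators** for all of the above, with ground-truth
  labels, standing in for the unreleased tomograms and movies.

## Worked example

```python
from dataclasses import replace
import numpy as np
from spindlekit import (SimParams, calibrate_nucleation_rate, simulate_frap,
                        frap_half_time, frap_two_component_fit)

params = SimParams.published("selective_detachment", R=200.0)
cal = calibrate_nucleation_rate(params, target_kmt_count=227.0, tol=0.05, seed=0)
params = replace(params, R=cal.R)
curves = [simulate_frap(params, seed) for seed in range(8)]
S = np.mean([c.S for c in curves], axis=0)
fit = frap_two_component_fit(curves[0].times, S)
print(cal.R, cal.kmt_mean)
print(frap_half_time(curves[0].times, S), fit.tau_fast, fit.ramp_duration)
```

prints (seed 0, eight bleach replicates)

```
200.0 222.9
8.2  4.8  18.0
```

i.e. a nucleation rate of ~200 microtubules/s sustains a ~223-KMT steady
state; the bleached box recovers with half-time ≈ 8 s, decomposing into a
fast ≈ 4.8 s exponential part (SMT turnover by catastrophe) and a slower
≈ 18 s linear ramp (KMT minus-ends sweeping the bleached marks out of the
box).  The `examples/` directory holds one short script per capability
(model comparison, reconstruction statistics, network connectivity, comet
velocimetry, FRAP profile analysis), and the `spindlekit` command-line
driver (`synth`, `simulate`, `calibrate`, `frap-sim`, `structure`,
`network`, `dynamics`) writes the same analyses as CSV/JSON artifacts with
a reproducibility manifest.

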