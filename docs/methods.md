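# Methods

This note documents the models and estimators implemented in `spindlekit`,
the defaults chosen where the underlying study left a quantity open, and
what the synthetic data do and do not establish about real reconstructions.

## 1. Stochastic models of KMT formation

The half spindle is the interval $[0, L]$ along the pole-to-chromosome
axis, with the mother centriole at 0 and the metaphase plate at
$L$ (default 6.5 µm).  Microtubules nucleate as zero-length segments at
Poisson rate $R$, with minus-end positions drawn from a nucleation profile
supported on $[0, 3]$ µm; plus-ends grow at $v_g$ (0.4 µm/s).  While the
plus-end is free, catastrophe at rate $\kappa$ (0.25 s⁻¹) removes the
microtubule instantly (depolymerisation is not tracked; this is the
standard simplification for $v_\text{shrink} \gg v_g$).  A plus-end
reaching $L$ attaches: the microtubule becomes a KMT and is immune to
catastrophe.  The variants:

| model | after attachment | minus-end dynamics | $v_d$ | $r$ |
|---|---|---|---|---|
| flux | plus-end shrinks at $v_d$, minus-end static and detached | none | 0.02 µm/s | ∞ (deterministic switch) |
| stochastic detachment | plus-end stalls against the plate | *every* minus-end switches at rate $r$ to shrinking at $v_d$ | 0.45 µm/s | 0.2 s⁻¹ |
| selective detachment | plus-end stalls; *only KMT* minus-ends switch at rate $r$ | shrink at $v_d$ after the switch | 0.17 µm/s | 0.5 s⁻¹ |

Zero-length microtubules are removed.  In the stochastic model a minus-end
may start shrinking before attachment; with $v_d > v_g$ such an SMT dies
when its minus-end overtakes the plus-end.  The flux model's $v_d$ is
printed both as 0.02 (parameter table) and 0.03 µm/s (measured flux bound)
in the source study; the table value is the default here and the text
value is available by override — only the table value is compatible with
the reported multi-minute relaxation of a de-novo flux spindle (the KMT
count converges completely at $\max_x (L-x)/v_d \approx 341$ s for
0.02 µm/s, versus 233 s for 0.03 µm/s).

**Exact event-driven scheme.**  All stochastic events (nucleation,
catastrophe, minus-end switching) have exponential waiting times and are
drawn exactly; between events every end moves at constant velocity, so the
deterministic boundary events (arrival at $L$, length reaching zero) are
scheduled analytically on the same priority queue.  Stale events are
discarded by comparing the stored per-microtubule event times at pop time.
This hybrid is an exact realisation of the continuous-time process; a
brute-force fixed-step integrator (Δt = 10⁻³ s) serves as an independent
oracle in the test suite at rates where at most a handful of microtubules
coexist.

**Nucleation profile.**  The study used its measured SMT minus-end
distribution (not released) truncated at 3 µm.  The default here is a
truncated exponential on $[0, 3]$ µm with scale 1 µm; a histogram-backed
profile can be supplied instead.  The simulated observables reported in
this package are only weakly sensitive to the profile's scale (FRAP
half-time varies by ≈ 2 s between scale 1.0 and a near-pole point source).

**Calibration.**  $E[n_\text{KMT}]$ is proportional to $R$ (independent
nucleation), so `calibrate_nucleation_rate` iterates
$R \leftarrow R \cdot \text{target}/\hat m(R)$ with $\hat m$ the steady
mean over snapshots taken every 30 s after a model-dependent burn-in
(600 s flux, 150 s otherwise); it converges in two or three evaluations to
the default 5 % relative tolerance.

**Steady-state time.**  The study states no criterion; the package defines
the settling time as the first sample time from which every forward 60-s
window mean of the KMT count stays within 5 % of the long-run mean
(estimated from the final half of the trajectory).  Forward windows are
used because trailing windows lag the ramp by most of a window length and
would misclassify the detachment models, which assemble in tens of
seconds.  Two caveats are documented deliberately: (i) single-trajectory
KMT fluctuations are Poisson-like ($\sqrt{227}/227 \approx 6.6\,\%$),
larger than the 5 % band, so the criterion is applied to seed-averaged
count curves; (ii) for the flux model the last few percent of the ramp are
shallow, so the 5 % criterion fires at ≈ 4.3 min even though the count
converges completely only at ≈ 5.7 min — the windowed statistic therefore
*understates* the printed "more than five minutes" relaxation, and no
windowed tolerance above the Monte-Carlo noise floor reproduces it.  The
acceptance script reports the honestly computed windowed value.

**Simulated FRAP.**  At bleach time every piece of microtubule inside a
box (default 1 µm wide, centred 2.5 µm plate-side of the chromosomes) is
marked.  Marks sit at fixed spatial coordinates: they vanish as shrinking
ends pass over them or whole microtubules are destroyed.  The read-out is
$S(t) = [M(t) - B(t)]/M(t)$ with $M$ the total and $B$ the still-bleached
microtubule mass inside the box; $S(0) = 0$ and $S \to 1$.  An empty box
at bleach time raises an error.  The recovery decomposes into a fast
saturating exponential (SMT turnover by catastrophe, plus growth of
unbleached plus-ends into the box) and a slower, delayed linear ramp (KMT
minus-ends sweeping the marks towards the plate);
`frap_two_component_fit` fits the sum
$A(1-e^{-t/\tau}) + B\,\mathrm{clip}((t-t_0)/T, 0, 1)$ to $S(t)$ and, at
the published selective-detachment parameters, returns $\tau \approx
4.5$ s and $T \approx 19$ s, matching the reported ≈ 5 s exponential and
≈ 20 s linear contributions.  A per-current-class decomposition is also
exposed (`FrapResult.smt_unbleached` etc.) but conflates the timescales,
because a bleached SMT that attaches transfers its mark to the KMT ledger.

**A genuine discrepancy.**  The measured metaphase recovery half-time is
21.4 s (95 % CI 19.7–23.2).  The simulated selective-detachment recovery
is structurally faster: every mark is erased within
$1/r + \text{box top}/v_d \approx 28.5$ s, and a curve that is the sum of
a ≈ 5 s exponential and a ≈ 20 s ramp reaches half of its plateau at
8–15 s for any mixture weight.  The simulated half-time here is ≈ 8 s.
The model reproduces the *timescales* of the measured recovery, not its
half-time; the corresponding acceptance check is left failing rather than
redefining the read-out.

## 2. Reconstruction analyses

Coordinates are nm; times s; all histogram bins are half-open $[lo, hi)$.

* **Classification.**  A trace with either endpoint inside the
  ribosome-free ("kinetochore") zone — a slab of configurable thickness
  (default 500 nm) pole-side of the chromosome rectangles — is a KMT; this
  rule precedes the cone rule.  Remaining traces are SMTs when their
  length-weighted centre of mass lies inside the cone with half-angle
  18.4° opening from the mother centriole towards the chromosomes
  (the printed "opening angle" is read as the axis-to-surface half-angle),
  otherwise AMTs.  Every trace receives exactly one label.
* **Endpoint CDFs.**  The pole-facing end is the end with the smaller
  axial coordinate (trace polarity is not annotated; polarity comes from
  the comet imaging).  Distances are 3D distances to the mother centriole.
* **Length distributions.**  Traces with an endpoint closer than 250 nm to
  the reconstruction volume boundary, or shorter than 100 nm, are removed
  before binning; the two filters commute and their tallies are reported.
* **Attachment RDF.**  KMT chromosome-facing ends are projected on the
  plate plane; annulus pair counts are normalised by the mean over
  ensembles of the same number of points placed uniformly in the same
  chromosome rectangles (default 10,000 ensembles; tests use a few
  hundred, which already gives per-bin reference errors ≪ the signal).
  The same machinery computes in-slice neighbour densities from
  plane-crossing points restricted to the cone, with a uniform-disk
  reference.
* **Network.**  Pair distance = exact minimum over all segment pairs
  (Lumelsky clamping, vectorised); pair angle = acute angle between the
  end-to-end chords, insensitive to local distortions.  Candidate pairs
  come from a k-d tree over points resampled along each trace at spacing
  $\delta$ and query radius $a_{\max} + \delta$, which provably cannot
  miss a qualifying pair; exactness is re-verified against all-pairs
  enumeration in the tests.  Centrosome connection = minimum
  point-to-trace distance to the centriole ≤ $d$ (default 2 µm).  Hop
  counts use unit edge weights (Dijkstra ≡ BFS, both tested): 0 means the
  KMT itself is connected, a KMT–SMT₁–SMT₂(connected) chain counts 2.
  AMTs participate as intermediates by default (`include_classes` filters
  them out).
* **z-endpoint density.**  Bins alternate between section interiors
  (central 50 % of each section) and boundaries (25 % of each adjacent
  section); counts are normalised by bin width.  Smooth curves indicate
  good stitching.

## 3. Dynamic-imaging estimators

* **Comet velocimetry.**  Detected (or ground-truth) spot positions are
  converted to polar coordinates about the centrosome.  Per azimuthal
  sector (default 24), each spot contributes a Mexican-hat wavelet along
  the radius (σ = 0.5 px; the orthogonal ×4 widening is represented by the
  sector width, so circumferential motion remains permissible).  Radial
  profiles of frame pairs separated by the requested lag (default 0.6 s;
  the *realised* lag on the frame grid is what divides the displacement)
  are cross-correlated, summed over sectors and pairs, and the mean peak
  is located by a Gaussian fit for sub-grid precision.  Positive velocity
  = outward.  On synthetic movies the estimator is unbiased within ≈ 2 %
  over 0.2–0.8 µm/s.
* **FRAP profiles.**  Per time point: Gaussian-plus-offset fit of the
  chromatin peak, a rough trough location, then a *refit* of the peak with
  the trough interval masked (the dip otherwise biases the alignment);
  the trough position is the vertex of a quadratic fitted to the
  baseline-normalised profile within ±1 µm (the sloping chromatin flank
  otherwise displaces the vertex).  Marks shallower than a 3 % dip, or
  jumping more than 600 nm between frames, are treated as unresolved and
  excluded from the drift fit.  Drift velocity is the linear-fit slope of
  trough-to-peak distance (positive toward the chromosomes); recovery is
  the intensity at the trough centre divided by the intensity at the
  position mirrored across the peak, and the half-time is the first
  crossing of the midpoint between initial and plateau recovery.

## 4. Synthetic data

The generators emulate the *statistical structure* the analyses assume,
with ground truth attached.

* **Half spindle** (default 8331 traces, 227 KMTs, metaphase): 12
  chromosome rectangles on a ring in the plate plane (areas 0.35–2.1 µm²,
  total ≈ 11.8 µm², giving ≈ 19 attachments/µm² and 6–50 per chromosome
  roughly proportional to area); KMT attachment points by dart throwing
  with a global 127 nm hard core; KMT lengths uniform on [0, 6.5] µm along
  straight chords towards the pole; SMT/AMT minus-ends with radial density
  $\propto r^2 e^{-r/1.5\,\mu m}$ truncated at 3 µm (an exponentially
  decaying nucleation density per unit volume — this reproduces the
  observed ≈ 46 % of SMT ends within 2 µm in 3D, which a 1D exponential on
  the distance cannot); SMT growth directions inside the cone (4° margin),
  AMT directions outside it; SMT lengths exponential (mean 1.6 µm) with a
  20 % uniform tail on [2, 6] µm — the tail law is an acknowledged choice,
  configurable; AMT lengths exponential, clipped 100 nm inside the volume
  bounds (clipped traces are exactly the ones the boundary filter later
  removes); polylines are straight chords with 20 nm Gaussian jitter on
  interior vertices (curvature is not analysed downstream); end-morphology
  labels drawn per end to match the printed open/closed tallies with 30 %
  undetermined.
* **Comet movies**: Poisson births in an annular region, radial motion at
  the region's preset speed (0.27/0.34/0.49/0.73 µm/s for inner-astral /
  spindle / chromosomes / outer-astral), exponential lifetimes, Gaussian
  PSF rendering on a noisy background, one frame per 250 ms.
* **FRAP series**: Gaussian chromatin peak, multiplicative Gaussian trough
  drifting at the configured velocity (default 0.03 µm/s toward the
  chromosomes) whose depth recovers as a weighted fast-exponential plus
  linear ramp.

**What passing tests do and do not show.**  The generators place traces
independently, so they contain no inter-microtubule clustering — real
spindles show a ≈ 55 nm neighbour-distance peak.  Consequently network
*reachability* on synthetic spindles saturates near one third of KMTs at
the published thresholds, and the tests assert the threshold monotonicity,
the oracle equivalences and the hop statistics of the *connected* KMTs
(median ≤ 2 interactions), not the in-vivo connected fraction.  Similarly,
KMT lengths in the selective model are flat only up to $L - 3$ µm (longer
KMTs require nucleation very close to the pole), so uniformity is tested
on that range.

## 5. Problem sizes and numerics

Tests and the acceptance script use desk-scale sizes chosen as the
package's own defaults: 10 bleach replicates for FRAP curves, 10 seeds for
relaxation times, ≥ 10⁴ pooled length samples (snapshots every 30 s are
effectively independent at a 4 s SMT lifetime), 200-trace random sets for
the exact-geometry oracles and a 1500-trace spindle for the network
example.  Stochastic assertions use α = 0.01 tests or tolerances of 5–15 %
set from the Monte-Carlo error at those sizes.  Degenerate inputs raise
typed errors (`PackingError`, `FrapEmptyBoxError`, `NotConvergedError`,
`EstimationError`, `TraceFormatError`) rather than returning sentinel
values; undefined ratios (0/0 plane counts, sub-3-chromosome correlations)
are reported as NaN/None.
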