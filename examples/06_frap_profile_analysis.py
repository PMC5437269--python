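"""Bleach-mark drift and recovery from axial intensity profiles.

Generates a synthetic FRAP profile series (chromatin peak plus a
drifting, recovering trough) and analyses it the way measured profiles
are: Gaussian alignment on the chromatin peak, quadratic trough fits,
and mirrored-position normalisation for the recovery.
"""

from spindlekit import SynthFrapConfig, frap_profile_analysis, generate_frap_series

cfg = SynthFrapConfig(drift_velocity=0.03, noise_sd=0.005, seed=11)
series = generate_frap_series(cfg)
res = frap_profile_analysis(series)

print(f"bleach-mark velocity: {res.velocity:+.3f} +- {res.velocity_stderr:.3f} um/s "
      f"toward the chromosomes (planted {cfg.drift_velocity:+.3f})")
print(f"recovery half-time: {res.half_time:.1f} s")
# A small positive drift means the mark creeps toward the chromosomes —
# the signature of slow poleward flux — and rules out plus-end growth at
# the kinetochore, which would move the mark the other way at ~0.4 um/s.
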