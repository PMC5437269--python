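"""Stochastic half-spindle models: invariants, limits and oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats

from spindlekit.simulate import (
    Engine,
    FrapEmptyBoxError,
    SimParams,
    SimTrajectory,
    TruncatedExponentialProfile,
    calibrate_nucleation_rate,
    extract_distributions,
    frap_half_time,
    run_model,
    simulate_frap,
    time_to_steady_state,
)

CAPTURE_OFF = dict(L=math.inf, R=100.0)


def test_zero_nucleation_gives_empty_spindle():
    traj = run_model(SimParams(model_kind="flux", R=0.0), t_end=200.0, seed=0)
    assert np.all(traj.n_smt == 0) and np.all(traj.n_kmt == 0)
    assert time_to_steady_state(traj) == 0.0


def test_flux_model_rejects_finite_switching_rate():
    with pytest.raises(ValueError):
        SimParams(model_kind="flux", r=0.5)


@pytest.mark.parametrize("model", ["flux", "stochastic_detachment", "selective_detachment"])
def test_positions_stay_ordered_within_halfspindle(model):
    params = SimParams.published(model, R=60.0)
    traj = run_model(params, t_end=240.0, seed=5, sample_dt=10.0)
    for snap in traj.snapshots:
        assert np.all(snap["minus"] >= -1e-9)
        assert np.all(snap["plus"] - snap["minus"] >= -1e-9)
        assert np.all(snap["plus"] <= params.L + 1e-9)
        # snapshot counts match the recorded population sizes
    assert np.array_equal(traj.n_kmt, [s["is_kmt"].sum() for s in traj.snapshots])


def test_seed_reproducibility_is_exact():
    params = SimParams.published("selective_detachment", R=80.0)
    t1 = run_model(params, 150.0, seed=9, sample_dt=15.0)
    t2 = run_model(params, 150.0, seed=9, sample_dt=15.0)
    assert np.array_equal(t1.n_kmt, t2.n_kmt) and np.array_equal(t1.n_smt, t2.n_smt)
    for a, b in zip(t1.snapshots, t2.snapshots):
        assert np.array_equal(a["minus"], b["minus"]) and np.array_equal(a["plus"], b["plus"])


def _pooled_smt_lengths(params, seed, burn=60.0, n_snap=25, dt=30.0):
    traj = run_model(params, burn + n_snap * dt, seed, sample_dt=dt)
    lengths = [
        s["plus"][~s["is_kmt"]] - s["minus"][~s["is_kmt"]]
        for s in traj.snapshots
        if s["t"] >= burn
    ]
    return np.concatenate(lengths)


def test_capture_disabled_smt_lengths_are_exponential():
    """With L -> inf the growth/catastrophe process has the closed-form
    steady state ~ exp(-l / (v_g/kappa)), mean 1.6 um."""
    params = SimParams(model_kind="selective_detachment", **CAPTURE_OFF)
    lengths = _pooled_smt_lengths(params, seed=21)
    assert len(lengths) >= 10_000
    mean = lengths.mean()
    assert mean == pytest.approx(1.6, rel=0.05)  # Monte-Carlo tolerance
    # chi-square goodness of fit against the exponential law at alpha=0.01
    edges = np.arange(0.0, 8.0, 0.5)
    obs, _ = np.histogram(lengths, bins=edges)
    scale = mean
    cdf = 1.0 - np.exp(-edges / scale)
    p = np.diff(cdf)
    p = np.append(p, 1.0 - cdf[-1])
    obs = np.append(obs, len(lengths) - obs.sum())
    keep = p * len(lengths) >= 5
    chi2 = ((obs[keep] - p[keep] * len(lengths)) ** 2 / (p[keep] * len(lengths))).sum()
    dof = keep.sum() - 2  # one fitted parameter
    assert chi2 < stats.chi2.ppf(0.99, dof)


def test_catastrophe_rate_recovered_from_length_distribution():
    params = SimParams(model_kind="selective_detachment", **CAPTURE_OFF)
    lengths = _pooled_smt_lengths(params, seed=22)
    kappa_hat = params.v_g / lengths.mean()
    assert kappa_hat == pytest.approx(0.25, rel=0.10)


def test_calibration_trivial_and_proportional():
    params = SimParams.published("selective_detachment")
    assert calibrate_nucleation_rate(params, 0.0).R == 0.0
    cal1 = calibrate_nucleation_rate(params, 60.0, tol=0.05, seed=3, burn_in=100.0, n_snapshots=12)
    cal2 = calibrate_nucleation_rate(params, 120.0, tol=0.05, seed=4, burn_in=100.0, n_snapshots=12)
    # independent nucleation: doubling the target ~ doubles R
    assert cal2.R / cal1.R == pytest.approx(2.0, rel=0.15)
    assert cal1.kmt_mean == pytest.approx(60.0, rel=0.05)


def test_extract_distributions_single_snapshot_delta():
    snap = {"t": 30.0, "minus": np.array([0.0]), "plus": np.array([2.0]),
            "is_kmt": np.array([True]), "ids": np.array([0])}
    traj = SimTrajectory(
        params=SimParams.published("selective_detachment"),
        times=np.array([30.0]), n_smt=np.array([0]), n_kmt=np.array([1]), snapshots=[snap],
    )
    d = extract_distributions(traj, burn_in=0.0, bin_width=0.5)
    k = d["kmt_length"]
    hit = np.nonzero(k.mean)[0]
    assert len(hit) == 1 and k.edges[hit[0]] == pytest.approx(2.0)
    with pytest.raises(ValueError):
        extract_distributions(traj, burn_in=100.0)


def test_frap_no_bleach_means_full_signal():
    params = SimParams.published("selective_detachment", R=150.0)
    res = simulate_frap(params, seed=2, equilibrate=80.0, duration=20.0, bleach_depth=0.0)
    assert np.allclose(res.S, 1.0)


def test_frap_invariants_and_empty_box():
    params = SimParams.published("selective_detachment", R=150.0)
    res = simulate_frap(params, seed=3, equilibrate=80.0, duration=40.0)
    assert res.S[0] == 0.0
    assert np.all((res.S >= 0) & (res.S <= 1.0 + 1e-12))
    assert np.all(np.diff(res.B) <= 1e-9)  # bleached mass never increases
    assert np.all(res.M >= res.B - 1e-9)
    with pytest.raises(FrapEmptyBoxError):
        simulate_frap(SimParams.published("selective_detachment", R=50.0), seed=1, equilibrate=0.0)


def test_frap_half_time_closed_form():
    t = np.linspace(0, 60, 601)
    S = 1.0 - np.exp(-t / 10.0)
    assert frap_half_time(t, S, plateau_tail=1.0) == pytest.approx(10 * np.log(2) / 0.998, rel=0.02)


def test_flux_without_shrinkage_grows_linearly():
    """v_d = 0 makes KMTs immortal: their number increases linearly and
    never reaches a plateau."""
    params = SimParams(model_kind="flux", v_d=0.0, R=30.0)
    traj = run_model(params, 600.0, seed=8, sample_dt=10.0, record_snapshots=False)
    t, n = traj.times, traj.n_kmt
    sel = t >= 60.0  # past the initial growth delay
    fit = stats.linregress(t[sel], n[sel])
    assert fit.slope > 0
    assert fit.rvalue**2 > 0.98
    # no plateau: the last quarter keeps growing at the same rate
    late = stats.linregress(t[t >= 450], n[t >= 450])
    assert late.slope == pytest.approx(fit.slope, rel=0.25)


def _small_system_brute_force(params, t_end, seed, dt=1e-3):
    """Fixed-small-timestep reference simulation (independent oracle)."""
    rng = np.random.default_rng(seed)
    mts = []  # dicts: minus, plus, state
    t = 0.0
    n_steps = int(round(t_end / dt))
    kmt_time = 0.0
    smt_len_sum = 0.0
    smt_len_n = 0
    for k in range(n_steps):
        t = k * dt
        if rng.random() < params.R * dt:
            x0 = float(params.nucleation_profile.sample(rng, 1)[0])
            mts.append({"m": x0, "p": x0, "s": "grow"})
        out = []
        for mt in mts:
            if mt["s"] == "grow":
                if rng.random() < params.kappa * dt:
                    continue
                mt["p"] += params.v_g * dt
                if mt["p"] >= params.L:
                    mt["p"] = params.L
                    mt["s"] = "kmt"
            elif mt["s"] == "kmt":
                if rng.random() < params.r * dt:
                    mt["s"] = "shrink"
            else:
                mt["m"] += params.v_d * dt
                if mt["m"] >= mt["p"]:
                    continue
            out.append(mt)
        mts = out
        kmt_time += dt * sum(1 for m in mts if m["s"] != "grow")
        for m in mts:
            if m["s"] == "grow":
                smt_len_sum += m["p"] - m["m"]
                smt_len_n += 1
    return kmt_time / t_end, smt_len_sum / max(smt_len_n, 1)


def test_small_system_matches_fixed_timestep_oracle():
    """At rates where <=3 MTs coexist, the event-driven scheme and a
    brute-force dt=1e-3 integrator agree on time-averaged statistics."""
    params = SimParams(
        model_kind="selective_detachment", R=0.2, kappa=0.3, r=0.5, v_d=0.4, L=3.5,
        nucleation_profile=TruncatedExponentialProfile(scale=0.5, hi=1.0),
    )
    t_end = 2000.0
    mean_kmt_bf, mean_smtlen_bf = _small_system_brute_force(params, t_end, seed=12)

    traj = run_model(params, t_end, seed=13, sample_dt=1.0)
    mean_kmt = traj.n_kmt.mean()
    smt_lens = np.concatenate(
        [s["plus"][~s["is_kmt"]] - s["minus"][~s["is_kmt"]] for s in traj.snapshots]
    )
    assert max(traj.n_kmt + traj.n_smt) <= 6  # genuinely a small system
    assert mean_kmt == pytest.approx(mean_kmt_bf, abs=3 * 0.05 + 0.15 * mean_kmt_bf)
    assert smt_lens.mean() == pytest.approx(mean_smtlen_bf, rel=0.15)


def test_nucleation_profile_validation():
    with pytest.raises(ValueError):
        SimParams(model_kind="flux", nucleation_profile=TruncatedExponentialProfile(hi=5.0))
    with pytest.raises(ValueError):
        SimParams(model_kind="flux", L=2.0)  # plate inside the nucleation zone
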