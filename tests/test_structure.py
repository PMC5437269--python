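"""Structural analyses of reconstructions: classification, CDFs, filters,
plate statistics and QC binning."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from spindlekit.structure import (
    attachment_rdf,
    chromosome_attachment_stats,
    classify,
    density_along_axis,
    disk_sampler,
    end_distance_cdf,
    length_distribution,
    trace_crosses_plane,
    z_endpoint_bins,
    z_endpoint_density,
)
from spindlekit.synthetic import SynthSpindleConfig, default_chromosome_rects, generate_reconstruction
from spindlekit.traces import ChromosomeRect, MicrotubuleTrace, SpindleReconstruction


def _recon(traces, **kw):
    kw.setdefault("chromosome_rects", [ChromosomeRect((0.0, 0.0), 2000.0, 2000.0)])
    kw.setdefault("volume_bounds", [[-3000, -9000, -9000], [8000, 9000, 9000]])
    return SpindleReconstruction(traces=traces, **kw)


def _line(tid, a, b, n=5):
    t = np.linspace(0, 1, n)[:, None]
    return MicrotubuleTrace(id=tid, points=np.asarray(a) + t * (np.asarray(b) - np.asarray(a)))


# --- classification --------------------------------------------------------


def test_kinetochore_zone_rule_precedes_cone_rule():
    rec0 = _recon([])
    u, v = rec0.basis_uv  # in-plane basis of the reconstruction frame
    axis = np.array([1.0, 0.0, 0.0])
    # ends in the zone but centre of mass far off-axis: still a KMT
    kmt = _line(0, 6400.0 * axis + 1500.0 * u, 3000.0 * axis + 5000.0 * u)
    smt = _line(1, [200.0, 50.0, 0.0], [4000.0, 100.0, 0.0])  # axial, stops short of zone
    amt = _line(2, [500.0, 0.0, 0.0], [700.0, 6000.0, 0.0])  # orthogonal, far from axis
    rec = _recon([kmt, smt, amt], chromosome_rects=[ChromosomeRect((1500.0, 0.0), 2000.0, 2000.0)])
    labels = classify(rec)
    assert labels == {0: "KMT", 1: "SMT", 2: "AMT"}


def test_classification_is_a_partition(small_spindle):
    recon, _ = small_spindle
    labels = classify(recon)
    assert set(labels) == {t.id for t in recon.traces}
    assert set(labels.values()) <= {"KMT", "SMT", "AMT"}


def test_classifier_recovers_ground_truth(default_spindle):
    recon, truth, labels = default_spindle
    agree = np.mean([labels[i] == truth[i] for i in truth])
    assert agree >= 0.99


def test_degenerate_axis_rejected():
    with pytest.raises(ValueError):
        SpindleReconstruction(traces=[], axis=np.zeros(3))


# --- endpoint CDFs ---------------------------------------------------------


def test_cdf_jump_when_all_ends_at_centriole():
    traces = [_line(i, [0.0, 0, 0], [4000.0, 100.0 * i, 0]) for i in range(5)]
    rec = _recon(traces)
    labels = {i: "SMT" for i in range(5)}
    cdf = end_distance_cdf(rec, labels, "SMT", radius=1.0)
    assert cdf.fraction_within == 1.0
    assert cdf.cdf(0.0) == 1.0
    with pytest.raises(ValueError):
        end_distance_cdf(rec, labels, "KMT")


def test_axial_kmt_fraction_matches_uniform_law_analytically():
    """Straight near-axial KMTs with uniform [0, 6.5] um lengths: the
    fraction of pole-facing ends within 2 um is 2/6.5."""
    rng = np.random.default_rng(0)
    traces = []
    for i in range(400):
        length = rng.uniform(0, 6500.0)
        u, v = rng.uniform(-300, 300, 2)
        plus = np.array([6500.0, u, v])
        minus = plus - plus / np.linalg.norm(plus) * length
        traces.append(_line(i, minus, plus))
    rec = _recon(traces)
    labels = {i: "KMT" for i in range(400)}
    frac = end_distance_cdf(rec, labels, "KMT", radius=2000.0).fraction_within
    assert frac == pytest.approx(2 / 6.5, abs=0.04)


def test_synthetic_defaults_reproduce_measured_end_fractions(default_spindle):
    recon, truth, _ = default_spindle
    kmt = end_distance_cdf(recon, truth, "KMT", radius=2000.0).fraction_within
    smt = end_distance_cdf(recon, truth, "SMT", radius=2000.0).fraction_within
    assert kmt == pytest.approx(0.22, abs=0.05)
    assert smt == pytest.approx(0.46, abs=0.06)


# --- axial density ---------------------------------------------------------


def test_single_spanning_trace_crosses_every_plane():
    tr = _line(0, [0.0, 0, 0], [6500.0, 0, 0])
    rec = _recon([tr])
    prof = density_along_axis(rec, {0: "SMT"}, n_planes=7)
    assert np.all(prof.counts["SMT"] == 1)
    with pytest.raises(ValueError):
        density_along_axis(rec, {0: "SMT"}, n_planes=0)


def test_plane_crossings_equal_sign_change_oracle(small_spindle):
    recon, truth = small_spindle
    prof = density_along_axis(recon, truth, n_planes=6)
    for j, p in enumerate(prof.positions):
        for cls in ("KMT", "SMT", "AMT"):
            want = 0
            for tr in recon.traces:
                if truth[tr.id] != cls:
                    continue
                x = recon.axial_coord(tr.points)
                crosses = any(
                    min(x[i], x[i + 1]) <= p < max(x[i], x[i + 1]) for i in range(len(x) - 1)
                )
                want += crosses
            assert prof.counts[cls][j] == want


def test_kmt_smt_ratio_rises_towards_plate(default_spindle):
    recon, truth, _ = default_spindle
    prof = density_along_axis(recon, truth, n_planes=8)
    r = prof.ratio_kmt_smt[np.isfinite(prof.ratio_kmt_smt)]
    assert r[-1] > r[0]
    assert r[-3:].mean() > r[:3].mean()


# --- length distributions --------------------------------------------------


def test_short_and_boundary_traces_are_filtered():
    bounds = [[0.0, 0, 0], [10000.0, 10000, 10000]]
    inside = _line(0, [3000.0, 3000, 3000], [6000.0, 3000, 3000])
    short = MicrotubuleTrace(id=1, points=np.array([[3000.0, 4000, 3000], [3090.0, 4000, 3000]]))
    near1 = _line(2, [100.0, 3000, 3000], [4000.0, 3000, 3000])  # endpoint <250nm from x=0
    near2 = _line(3, [5000.0, 9900, 5000], [5000.0, 6000, 5000])
    inside2 = _line(4, [2000.0, 5000, 5000], [2000.0, 8000, 5000])
    rec = _recon([inside, short, near1, near2, inside2], volume_bounds=bounds)
    labels = {i: "SMT" for i in range(5)}
    res = length_distribution(rec, labels)
    assert res.n_excluded_boundary == 2 and res.n_excluded_short == 1
    assert len(res.lengths["SMT"]) == 2
    assert res.histograms["SMT"].sum() == 2
    # filters are idempotent: re-filtering the survivors removes nothing
    rec2 = _recon([inside, inside2], volume_bounds=bounds)
    res2 = length_distribution(rec2, {0: "SMT", 4: "SMT"})
    assert res2.n_excluded_boundary == 0 and res2.n_excluded_short == 0


def test_class_length_laws_survive_filters(default_spindle):
    """AMT lengths stay exponential and KMT lengths flat after filtering."""
    recon, truth, _ = default_spindle
    res = length_distribution(recon, truth)
    amt = res.lengths["AMT"] / 1000.0
    # log-linear decay fit over the histogram body: straight line with
    # slope -1/mean (the boundary filter nibbles only at the far tail)
    edges = np.arange(0.2, 4.2, 0.4)
    counts, _ = np.histogram(amt, bins=edges)
    fit = stats.linregress(0.5 * (edges[:-1] + edges[1:]), np.log(counts))
    assert fit.rvalue**2 > 0.98
    # decay rate consistent with the surviving sample's own mean (the
    # boundary filter steepens the tail, shape stays exponential)
    assert -fit.slope == pytest.approx(1 / amt.mean(), rel=0.2)
    assert fit.slope < 0
    kmt = res.lengths["KMT"] / 1000.0
    ks_u = stats.kstest(kmt / kmt.max(), "uniform")
    assert ks_u.pvalue > 0.01


# --- attachment RDF --------------------------------------------------------


def test_rdf_of_uniform_points_is_flat(default_spindle):
    recon, truth, _ = default_spindle
    rng = np.random.default_rng(1)
    sampler = disk_sampler(2000.0)
    pts = sampler(rng, 200)
    rdf = attachment_rdf(
        recon, truth, points=pts, reference_sampler=sampler, n_random=300, seed=2,
        bin_width=100.0, max_distance=2500.0,
    )
    g = rdf.g[np.isfinite(rdf.g) & (rdf.reference_mean > 20)]
    assert np.abs(g - 1.0).mean() < 0.1


def test_rdf_square_lattice_peaks_at_spacing(default_spindle):
    recon, truth, _ = default_spindle
    s = 300.0
    xx, yy = np.meshgrid(np.arange(10) * s, np.arange(10) * s)
    pts = np.stack([xx.ravel(), yy.ravel()], axis=1)

    def square_sampler(rng, n):  # reference matches the lattice's domain
        return rng.uniform(0.0, 9 * s, (n, 2))

    rdf = attachment_rdf(
        recon, truth, points=pts, reference_sampler=square_sampler, n_random=100, seed=3,
        bin_width=50.0, max_distance=800.0,
    )
    # brute-force oracle: annulus pair counts equal the raw pair-distance histogram
    assert np.array_equal(rdf.pair_counts, np.histogram(pdist(pts), bins=rdf.edges)[0])
    # dominant normalized peak at the lattice constant
    assert abs(rdf.peak_distance(100.0, 700.0) - s) <= 50.0


def test_rdf_detects_hard_core_spacing():
    rects = [
        ChromosomeRect(r.center_uv, r.width * 0.84, r.height * 0.84)
        for r in default_chromosome_rects()
    ]
    cfg = SynthSpindleConfig(
        n_mts_total=250, n_kmts=227, chromosome_rects=rects, seed=3, smt_fraction_of_nonkmt=0.5
    )
    rec = generate_reconstruction(cfg)
    truth = {t.id: t.mt_class for t in rec.traces}
    rdf = attachment_rdf(rec, truth, n_random=300, seed=0)
    assert np.all(rdf.g[rdf.centers < 110] < 0.2)  # excluded core
    peak = rdf.peak_distance(60.0, 400.0)
    assert 120.0 <= peak <= 220.0  # contact peak just above the 127 nm core
    with pytest.raises(ValueError):
        attachment_rdf(rec, truth, points=np.zeros((1, 2)))


# --- chromosome statistics -------------------------------------------------


def test_attachment_stats_degenerate_and_collinear_cases():
    rects = [ChromosomeRect((0.0, 0.0), 1000.0, 1000.0),
             ChromosomeRect((3000.0, 0.0), 2000.0, 1000.0),
             ChromosomeRect((-3000.0, 0.0), 3000.0, 1000.0)]
    rec = _recon([], chromosome_rects=rects)
    empty = chromosome_attachment_stats(rec, {})
    assert np.all(empty.counts == 0) and empty.pearson_r is None

    # counts (2, 4, 6) against areas (1, 2, 3): perfectly collinear
    u_vec, _ = rec.basis_uv
    axis = np.array([1.0, 0.0, 0.0])
    traces = []
    tid = 0
    for rect, n in zip(rects, (2, 4, 6)):
        for k in range(n):
            u = rect.center_uv[0] + (k - n / 2) * 100.0
            traces.append(_line(tid, 1000.0 * axis + u * u_vec, 6500.0 * axis + u * u_vec))
            tid += 1
    rec2 = _recon(traces, chromosome_rects=rects)
    res = chromosome_attachment_stats(rec2, {t.id: "KMT" for t in traces})
    assert list(res.counts) == [2, 4, 6]
    assert res.pearson_r == pytest.approx(1.0)


def test_default_spindle_attachment_statistics(default_spindle):
    recon, truth, _ = default_spindle
    res = chromosome_attachment_stats(recon, truth)
    assert res.counts.sum() == 227
    assert np.all((res.counts >= 6) & (res.counts <= 50))
    assert np.all((res.density_per_um2 > 10) & (res.density_per_um2 < 30))
    assert res.pearson_r > 0.9
    morph = res.end_morphology["chromosome"]
    open_frac = morph["open"] / (morph["open"] + morph["closed"])
    assert open_frac == pytest.approx(0.71, abs=0.10)


# --- z endpoint density ----------------------------------------------------


def test_z_bins_and_manual_binning_oracle():
    zb = np.array([0.0, 300.0, 600.0, 900.0])
    edges, kinds = z_endpoint_bins(zb)
    assert kinds == ["section", "boundary", "section", "boundary", "section"]
    assert np.allclose(edges, [75, 225, 375, 525, 675, 825])

    # 10 endpoints = 5 two-point traces placed by hand
    zs = [100, 200, 290, 310, 400, 500, 590, 610, 700, 800]
    traces = [
        MicrotubuleTrace(id=i, points=np.array([[0.0, 0, zs[2 * i]], [500.0, 0, zs[2 * i + 1]]]))
        for i in range(5)
    ]
    rec = _recon(traces)
    rec.section_boundaries_z = zb
    res = z_endpoint_density(rec)
    assert list(res.counts) == [2, 2, 2, 2, 2]
    assert np.allclose(res.density, res.counts / np.diff(edges))


def test_z_density_flat_for_uniform_and_peaked_for_planted():
    rng = np.random.default_rng(4)
    zb = np.linspace(0.0, 3000.0, 11)
    uni = [
        MicrotubuleTrace(id=i, points=np.array([[0.0, 0, a], [500.0, 0, b]]))
        for i, (a, b) in enumerate(rng.uniform(80, 2920, (400, 2)))
    ]
    rec = _recon(uni)
    rec.section_boundaries_z = zb
    res = z_endpoint_density(rec)
    assert res.density.std() / res.density.mean() < 0.25

    planted = [
        MicrotubuleTrace(id=i, points=np.array([[0.0, 0, 600.0 + rng.normal(0, 10)], [500.0, 0, 1500.0]]))
        for i in range(50)
    ]
    rec2 = _recon(planted)
    rec2.section_boundaries_z = zb
    res2 = z_endpoint_density(rec2)
    # the boundary bin at z=600 has by far the highest density
    b600 = [i for i, (lo, hi) in enumerate(zip(res2.bin_edges[:-1], res2.bin_edges[1:]))
            if lo < 600 < hi][0]
    assert res2.bin_kind[b600] == "boundary"
    assert res2.density[b600] == res2.density.max()
    rec2.section_boundaries_z = None
    with pytest.raises(ValueError):
        z_endpoint_density(rec2)


def test_trace_crosses_plane_half_open_convention():
    x = np.array([0.0, 1.0, 2.0])
    assert trace_crosses_plane(x, 0.0)       # touches lower edge: counted
    assert not trace_crosses_plane(x, 2.0)   # upper edge: excluded
    assert trace_crosses_plane(x, 1.0)
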