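"""Homogeneity metrics, Carr index and series-comparison tests
(pure functions on synthetic snapshots; no DEM runs)."""

import numpy as np
import pytest

from blendsim.blending import (
    BlenderSpec,
    Formulation,
    SamplingBin,
    Snapshot,
    build_blender,
    carr_index,
    compare_series,
    content_uniformity,
    default_bins,
    sample_bins,
    t_index_series,
)


# ----- Carr index ------------------------------------------------------------

def test_carr_index_values():
    assert carr_index(0.25, 0.25) == 0.0
    assert carr_index(0.20, 0.25) == pytest.approx(20.0)
    assert carr_index(0.8 * 1.3, 1.3) == pytest.approx(20.0)


def test_carr_index_rejects_bulk_above_tap():
    with pytest.raises(ValueError):
        carr_index(0.3, 0.25)
    with pytest.raises(ValueError):
        carr_index(0.0, 0.25)


# ----- formulation -----------------------------------------------------------

def test_formulation_validates():
    with pytest.raises(ValueError, match="sum"):
        Formulation(("a", "b"), (0.5, 0.4), "a")
    with pytest.raises(ValueError, match="API"):
        Formulation(("a", "b"), (0.5, 0.5), "c")
    f = Formulation(("api", "filler"), (0.06935, 0.93065), "api")
    assert f.api_fraction == pytest.approx(0.06935)


# ----- content uniformity ----------------------------------------------------

def test_cu_identical_bins_zero():
    assert content_uniformity([100.0] * 8) == 0.0


def test_cu_hand_value():
    # contents (90, 110): mean 100, sample SD sqrt(200)
    assert content_uniformity([90.0, 110.0]) == pytest.approx(
        100 * np.sqrt(200) / 100)


def test_cu_scale_invariant():
    c = np.array([92.0, 101.0, 97.0, 108.0, 95.0])
    assert content_uniformity(c) == pytest.approx(content_uniformity(3.7 * c))


def test_cu_needs_two_bins():
    with pytest.raises(ValueError):
        content_uniformity([100.0])


def test_cu_zero_mean_is_nan():
    assert np.isnan(content_uniformity([0.0, 0.0, 0.0]))


# ----- sampling bins ---------------------------------------------------------

def synthetic_snapshot(n_api, n_total, rng=None, spread=0.05):
    """Uniform cloud in a unit cube; the first ``n_api`` particles are API."""
    rng = rng or np.random.default_rng(0)
    pos = rng.uniform(0, 1, (n_total, 3))
    mat = np.zeros(n_total, dtype=int)
    mat[n_api:] = 1
    mass = np.full(n_total, 1.0)
    return Snapshot(time=0.0, pos=pos, radius=np.full(n_total, spread),
                    material_id=mat, mass=mass)


FORM = Formulation(("api", "excipient"), (0.25, 0.75), "api")


def test_perfectly_proportioned_bin_reads_100():
    # 1 API among 4 equal-mass particles inside the bin = nominal 25%
    snap = Snapshot(0.0, np.zeros((4, 3)), np.full(4, 0.1),
                    np.array([0, 1, 1, 1]), np.ones(4))
    bins = [SamplingBin(center=(0, 0, 0), radius=1.0, height=2.0)]
    m = sample_bins(snap, bins, FORM, min_bins=1)
    assert m.bin_contents[0] == pytest.approx(100.0)


def test_bin_without_api_reads_zero():
    snap = Snapshot(0.0, np.zeros((3, 3)), np.full(3, 0.1),
                    np.array([1, 1, 1]), np.ones(3))
    bins = [SamplingBin(center=(0, 0, 0), radius=1.0, height=2.0)]
    m = sample_bins(snap, bins, FORM, min_bins=1)
    assert m.bin_contents[0] == 0.0


def test_empty_bins_excluded_with_warning():
    snap = synthetic_snapshot(50, 200)
    bins = list(default_bins(snap, 8))
    bins.append(SamplingBin(center=(50.0, 50.0, 50.0), radius=0.1, height=0.1))
    with pytest.warns(UserWarning, match="empty"):
        m = sample_bins(snap, bins, FORM)
    assert m.n_bins == 8


def test_cu_matches_binomial_sampling_floor():
    """Random uniform placement: CU across bins approaches the binomial
    sampling SD for the per-bin API count."""
    rng = np.random.default_rng(42)
    reps, api_frac, n = 40, 0.25, 4000
    cus = []
    for _ in range(reps):
        snap = synthetic_snapshot(int(api_frac * n), n, rng)
        # shuffle so API positions are exchangeable with the rest
        perm = rng.permutation(n)
        snap.material_id = snap.material_id[perm]
        m = sample_bins(snap, default_bins(snap, 8), FORM)
        cus.append(m.cu)
    # expected per-bin API count ~ Binomial(n_bin, p): RSD of content
    # = sqrt((1-p)/(n_bin p)); bins hold roughly n * bin_vol each
    snap = synthetic_snapshot(int(api_frac * n), n, rng)
    b = default_bins(snap, 8)[0]
    n_bin = n * (np.pi * b.radius**2 * b.height)
    expect = 100 * np.sqrt((1 - api_frac) / (n_bin * api_frac))
    assert np.mean(cus) == pytest.approx(expect, rel=0.25)


def test_metrics_invariant_under_rigid_rotation():
    rng = np.random.default_rng(3)
    snap = synthetic_snapshot(100, 400, rng)
    bins = default_bins(snap, 8)
    m0 = sample_bins(snap, bins, FORM)
    # rotate everything 90 degrees about z
    R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    snap_r = Snapshot(0.0, snap.pos @ R.T, snap.radius, snap.material_id,
                      snap.mass)
    bins_r = [SamplingBin(tuple(R @ np.array(b.center)), b.radius, b.height,
                          tuple(R @ np.array(b.axis))) for b in bins]
    m1 = sample_bins(snap_r, bins_r, FORM)
    assert m1.cu == pytest.approx(m0.cu, abs=1e-9)
    assert np.allclose(sorted(m1.bin_contents), sorted(m0.bin_contents))


# ----- T-index ---------------------------------------------------------------

def make_series(mixed: bool, steps=8, seed=0):
    """Grid cloud; 'mixed' interleaves the API on the lattice (almost no
    sampling noise), otherwise the API segregates at the top."""
    rng = np.random.default_rng(seed)
    g = np.mgrid[0:12, 0:12, 0:12].reshape(3, -1).T / 12.0
    n = len(g)
    snaps = []
    for k in range(steps + 1):
        pos = g + rng.uniform(0, 1e-3, g.shape)
        mat = np.ones(n, dtype=int)
        if mixed:
            mat[::4] = 0                   # every 4th lattice site is API
        else:
            order = np.argsort(pos[:, 2], kind="stable")
            mat[order[3 * n // 4:]] = 0    # API concentrated at the top
        snaps.append(Snapshot(float(k), pos, np.full(n, 0.02), mat,
                              np.ones(n)))
    return snaps


def test_premixed_state_meets_specs_at_first_t_index():
    series = t_index_series(make_series(mixed=True), FORM)
    assert series.attrs["t_spec"] == 1
    assert bool(series.iloc[0]["meets_spec"])


def test_segregated_static_state_never_meets_specs():
    series = t_index_series(make_series(mixed=False), FORM)
    assert series.attrs["t_spec"] is None
    assert not series["meets_spec"].any()


def test_t_index_interval_defaults_to_sevenths():
    series = t_index_series(make_series(mixed=True), FORM)
    assert list(series["t_index"]) == list(range(1, 8))


# ----- regression comparison -------------------------------------------------

def test_identical_series_perfect_fit():
    x = np.array([94.0, 95.0, 96.0, 96.5, 97.0])
    res = compare_series(x, x)
    assert res["slope"] == pytest.approx(1.0)
    assert res["intercept"] == pytest.approx(0.0, abs=1e-12)
    assert res["rsquared"] == pytest.approx(1.0)
    assert res["S"] == pytest.approx(0.0, abs=1e-12)


def test_affine_series_recovers_coefficients():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    res = compare_series(x, 2 * x + 1)
    assert res["slope"] == pytest.approx(2.0)
    assert res["intercept"] == pytest.approx(1.0)
    assert res["rsquared"] == pytest.approx(1.0)


def test_noisy_series_rsquared_matches_expectation():
    """R^2 under known Gaussian noise matches var_signal/(var_signal+sd^2)."""
    rng = np.random.default_rng(11)
    reps = 200
    x = np.linspace(90, 100, 12)
    sd = 1.0
    r2s = [compare_series(x, x + rng.normal(0, sd, len(x)))["rsquared"]
           for _ in range(reps)]
    var_x = np.var(x)
    expect = var_x / (var_x + sd**2)
    assert np.mean(r2s) == pytest.approx(expect, abs=0.05)


def test_compare_series_guards():
    with pytest.raises(ValueError, match="length"):
        compare_series([1, 2, 3], [1, 2])
    with pytest.raises(ValueError, match="3 paired"):
        compare_series([1, 2], [1, 2])
    with pytest.raises(ValueError, match="variance"):
        compare_series([1.0, 1.0, 1.0], [1, 2, 3])
    # drop_first discards the high-variability initial points
    x = np.array([50.0, 94, 95, 96, 97])
    y = np.array([99.0, 94, 95, 96, 97])
    assert compare_series(x, y, drop_first=1)["rsquared"] == pytest.approx(1.0)


# ----- blender geometry ------------------------------------------------------

@pytest.mark.parametrize("spec", [
    BlenderSpec(kind="v", nominal_volume_l=3.0, rpm=24.0),
    BlenderSpec(kind="double_cone", nominal_volume_l=10.0, rpm=24.0),
])
def test_blender_mesh_volume_within_five_percent(spec):
    wall = build_blender(spec)
    assert wall.is_watertight
    assert wall.volume * 1e3 == pytest.approx(spec.nominal_volume_l, rel=0.05)


def test_blender_wall_speed_matches_rigid_rotation():
    wall = build_blender(BlenderSpec(kind="v", nominal_volume_l=3.0, rpm=24.0))
    omega = 24 * 2 * np.pi / 60
    p = np.array([[0.05, 0.02, 0.08]])
    v = wall.kin.surface_velocity(p)
    expect = np.cross([0, omega, 0], p[0])
    assert np.allclose(v[0], expect)


def test_unknown_blender_kind_rejected():
    with pytest.raises(ValueError):
        build_blender(BlenderSpec(kind="cube", nominal_volume_l=1.0))
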