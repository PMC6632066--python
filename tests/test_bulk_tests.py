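"""Bulk-test estimators, flow-energy integral and calibration logic."""

import numpy as np
import pytest

from blendsim.bulk_tests import (
    BfeTrace,
    CalibrationTarget,
    RheometerRig,
    bfe_energy,
    calibrate,
    heap_angle,
    simulate_static_aor,
    surface_angle,
)
from blendsim.fixtures import desk_material

RIG = RheometerRig()


# ----- flow-energy integral --------------------------------------------------

def test_bfe_zero_trace():
    n = 10
    trace = BfeTrace(np.linspace(0, 1, n), np.zeros(n), np.zeros(n),
                     np.linspace(0, 0.03, n))
    assert bfe_energy(trace, RIG) == 0.0


def test_bfe_constant_trace_closed_form():
    n, H, T, F = 50, 0.03, 2e-4, 0.5
    trace = BfeTrace(np.linspace(0, 1, n), np.full(n, T), np.full(n, F),
                     np.linspace(0, H, n))
    tan_a = np.tan(np.deg2rad(5.0))
    expect = (T / (RIG.blade_radius * tan_a) + F) * H
    assert bfe_energy(trace, RIG) == pytest.approx(expect, rel=1e-12)


def test_bfe_linear_ramp_matches_exact_integral():
    n, H = 400, 0.03
    h = np.linspace(0, H, n)
    trace = BfeTrace(np.linspace(0, 1, n), 1e-3 * h / H, 2.0 * h / H, h)
    tan_a = np.tan(np.deg2rad(5.0))
    # integral of (T(h)/(R tan a) + F(h)) dh for linear ramps = peak/2 * H
    expect = (1e-3 / (RIG.blade_radius * tan_a) + 2.0) * H / 2
    assert bfe_energy(trace, RIG) == pytest.approx(expect, rel=1e-6)


def test_bfe_linear_in_trace_scaling():
    n = 60
    rng = np.random.default_rng(0)
    trace = BfeTrace(np.linspace(0, 1, n), rng.uniform(0, 1e-3, n),
                     rng.uniform(0, 1, n), np.sort(rng.uniform(0, 0.03, n)))
    scaled = BfeTrace(trace.time, 3.0 * trace.torque, 3.0 * trace.force,
                      trace.depth)
    assert bfe_energy(scaled, RIG) == pytest.approx(3 * bfe_energy(trace, RIG))


def test_bfe_rejects_zero_helix_angle():
    import dataclasses

    trace = BfeTrace(np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))
    flat = dataclasses.replace(RIG, helix_angle_deg=0.0)
    with pytest.raises(ValueError):
        bfe_energy(trace, flat)


def test_trace_lengths_validated():
    with pytest.raises(ValueError):
        BfeTrace(np.zeros(3), np.zeros(2), np.zeros(3), np.zeros(3))


# ----- heap-angle estimator --------------------------------------------------

def ideal_cone_cloud(angle_deg, n=4000, seed=0):
    """Uniform random points inside a cone of the given surface angle."""
    rng = np.random.default_rng(seed)
    R = 1.0
    h = R * np.tan(np.deg2rad(angle_deg))
    pts = []
    while len(pts) < n:
        x, y = rng.uniform(-R, R, 2)
        z = rng.uniform(0, h)
        r = np.hypot(x, y)
        if r < R * (1 - z / h):
            pts.append([x, y, z])
    return np.asarray(pts)


@pytest.mark.parametrize("angle", [15.0, 30.0, 45.0])
def test_heap_angle_recovers_ideal_cone(angle):
    pts = ideal_cone_cloud(angle)
    got = heap_angle(pts, np.zeros(len(pts)))
    assert got == pytest.approx(angle, abs=1.5)


def test_heap_angle_rotation_invariant():
    pts = ideal_cone_cloud(30.0, seed=5)
    a0 = heap_angle(pts, np.zeros(len(pts)))
    th = np.deg2rad(90)
    R = np.array([[np.cos(th), -np.sin(th), 0],
                  [np.sin(th), np.cos(th), 0], [0, 0, 1]])
    a1 = heap_angle(pts @ R.T, np.zeros(len(pts)))
    assert a1 == pytest.approx(a0, abs=0.5)


def test_heap_angle_flat_layer_near_zero():
    rng = np.random.default_rng(2)
    pts = np.column_stack([rng.uniform(-1, 1, 2000), rng.uniform(-1, 1, 2000),
                           rng.uniform(0, 0.01, 2000)])
    assert heap_angle(pts, np.zeros(2000)) < 3.0


# ----- surface-angle estimator -----------------------------------------------

def test_surface_angle_recovers_tilted_bed():
    rng = np.random.default_rng(1)
    x = rng.uniform(-1, 1, 3000)
    slope = np.tan(np.deg2rad(25.0))
    z = slope * x + rng.uniform(-0.02, 0.0, 3000)
    pos = np.column_stack([x, rng.uniform(-0.1, 0.1, 3000), z])
    angle, r2 = surface_angle(pos, np.zeros(3000))
    assert angle == pytest.approx(25.0, abs=1.5)
    assert r2 > 0.99


# ----- static repose simulation ---------------------------------------------

@pytest.fixture(scope="module")
def frictional_angle():
    return simulate_static_aor(desk_material(mu_s=0.5, mu_r=0.25),
                               budget=150, seed=5, max_time=2.0)


def test_static_aor_deterministic_by_seed(frictional_angle):
    again = simulate_static_aor(desk_material(mu_s=0.5, mu_r=0.25),
                                budget=150, seed=5, max_time=2.0)
    assert again == pytest.approx(frictional_angle, abs=1e-9)


def test_static_aor_frictionless_collapses(frictional_angle):
    flat = simulate_static_aor(
        desk_material(mu_s=0.0, mu_r=0.0, restitution=0.9),
        budget=150, seed=5, max_time=2.0)
    # a flat spread-out disk reads ~5-10 deg on the moment estimator
    assert flat < 12.0
    assert frictional_angle > flat + 8.0


def test_static_aor_increases_with_rolling_friction(frictional_angle):
    low = simulate_static_aor(desk_material(mu_s=0.5, mu_r=0.02),
                              budget=150, seed=5, max_time=2.0)
    assert frictional_angle > low


# ----- calibration loop ------------------------------------------------------

def test_calibration_target_validation():
    with pytest.raises(ValueError, match="no tests"):
        calibrate(desk_material(), CalibrationTarget(), particle_budget=50)
    with pytest.raises(ValueError, match="tolerance"):
        calibrate(desk_material(),
                  CalibrationTarget(static_angle_deg=30.0, tolerance=0.0),
                  particle_budget=50)


def test_calibration_zero_iterations_when_target_met():
    mat = desk_material(mu_s=0.5, mu_r=0.25)
    angle = simulate_static_aor(mat, budget=150, seed=9, max_time=2.0)
    res = calibrate(mat, CalibrationTarget(static_angle_deg=angle),
                    budget_iterations=4, particle_budget=150, seed=9)
    assert res.converged
    assert len(res.iterations) == 1       # only the initial evaluation
    assert res.iterations.iloc[0]["worst_bias"] == pytest.approx(0.0, abs=1e-9)


@pytest.fixture(scope="module")
def impossible_calibration():
    mat = desk_material(mu_s=0.4, mu_r=0.2)
    return calibrate(mat, CalibrationTarget(static_angle_deg=89.0),
                     budget_iterations=2, particle_budget=120, seed=4)


def test_calibration_impossible_target_flags_nonconvergence(
        impossible_calibration):
    assert not impossible_calibration.converged
    assert impossible_calibration.worst_bias > 0.10


def test_calibration_audit_trail_monotone_on_accepts(impossible_calibration):
    accepted = impossible_calibration.iterations[
        impossible_calibration.iterations["accepted"]]
    worst = accepted["worst_bias"].to_numpy()
    assert np.all(np.diff(worst) <= 1e-12)
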