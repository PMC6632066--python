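"""Contact-law unit tests: Hertz, damping, tangential, rolling, JKR."""

import numpy as np
import pytest

from blendsim.dem import contacts as C


# ----- equivalent properties -------------------------------------------------

def test_identical_spheres_halve_radius_and_mass():
    p = C.equivalent_props(1e6, 0.25, 1e-3, 1e-5, 1e6, 0.25, 1e-3, 1e-5)
    assert p.r_star == pytest.approx(0.5e-3)
    assert p.m_star == pytest.approx(0.5e-5)


def test_wall_limit_keeps_particle_radius_and_mass():
    p = C.equivalent_props(1e6, 0.25, 1e-3, 1e-5)
    assert p.r_star == pytest.approx(1e-3)
    assert p.m_star == pytest.approx(1e-5)


def test_equivalent_modulus_hand_calculation():
    # G = 1e7 Pa, nu = 0.25 both sides -> E = 2G(1+nu) = 2.5e7
    E = 2 * 1e7 * 1.25
    p = C.equivalent_props(E, 0.25, 1e-3, 1e-5, E, 0.25, 1e-3, 1e-5)
    expect = 1.0 / (2 * (1 - 0.25**2) / E)
    assert p.e_star == pytest.approx(expect)


def test_equivalent_props_rejects_nonpositive():
    with pytest.raises(ValueError):
        C.equivalent_props(-1e6, 0.25, 1e-3, 1e-5)


# ----- Hertz normal force ----------------------------------------------------

def test_hertz_zero_at_zero_overlap():
    assert C.hertz_normal_force(0.0, 1e7, 1e-3) == 0.0
    assert C.hertz_normal_force(-1e-6, 1e7, 1e-3) == 0.0


def test_hertz_power_law():
    f1 = C.hertz_normal_force(1e-6, 1e7, 1e-3)
    f2 = C.hertz_normal_force(2e-6, 1e7, 1e-3)
    assert f2 / f1 == pytest.approx(2**1.5)


def test_hertz_hand_value():
    e_star, r_star, dn = 1e7, 0.5e-3, 1e-6
    expect = (4 / 3) * e_star * np.sqrt(r_star) * dn**1.5
    assert C.hertz_normal_force(dn, e_star, r_star) == pytest.approx(expect)


def test_hertz_strictly_increasing():
    dn = np.linspace(0, 1e-4, 50)
    f = C.hertz_normal_force(dn, 1e7, 1e-3)
    assert np.all(np.diff(f) > 0)


# ----- damping ---------------------------------------------------------------

def test_beta_zero_for_elastic():
    assert C.damping_beta(1.0) == 0.0


def test_beta_monotone_decreasing_in_e():
    es = np.linspace(0.1, 1.0, 10)
    betas = C.damping_beta(es)
    assert np.all(np.diff(betas) < 1e-12)
    assert np.all(betas >= 0)
    assert np.all(betas < 1)


def test_damping_opposes_relative_velocity():
    v = np.array([[0.0, 0.0, -1.0]])
    f = C.normal_damping_force(0.3, 1e4, 1e-5, v)
    assert f[0] @ v[0] < 0


def test_no_damping_at_zero_velocity_or_beta():
    z = np.zeros((1, 3))
    assert np.allclose(C.normal_damping_force(0.3, 1e4, 1e-5, z), 0)
    v = np.array([[1.0, 0, 0]])
    assert np.allclose(C.normal_damping_force(0.0, 1e4, 1e-5, v), 0)


# ----- tangential force ------------------------------------------------------

def test_tangential_zero_without_history_or_slip():
    f, d = C.tangential_force(1e4, np.zeros((1, 3)), 0.3, 1e-5,
                              np.zeros((1, 3)), 0.5, 1.0)
    assert np.allclose(f, 0)


def test_coulomb_cap_saturates_and_rescales_spring():
    big = np.array([[1.0, 0.0, 0.0]])       # huge accumulated displacement
    f, d = C.tangential_force(1e4, big, 0.0, 1e-5, np.zeros((1, 3)), 0.5, 2.0)
    assert np.linalg.norm(f[0]) == pytest.approx(0.5 * 2.0)
    # rescaled spring reproduces exactly the capped force
    f2, _ = C.tangential_force(1e4, d, 0.0, 1e-5, np.zeros((1, 3)), 0.5, 2.0)
    assert np.allclose(f, f2)


# ----- rolling torque --------------------------------------------------------

def test_rolling_zero_cases():
    assert np.allclose(C.rolling_torque(0.3, 1.0, 1e-3, np.zeros((1, 3))), 0)
    w = np.array([[0.0, 0.0, 10.0]])
    assert np.allclose(C.rolling_torque(0.0, 1.0, 1e-3, w), 0)


def test_rolling_magnitude_and_direction():
    w = np.array([[0.0, 0.0, 10.0]])
    t = C.rolling_torque(0.3, 2.0, 1e-3, w)
    assert np.linalg.norm(t[0]) == pytest.approx(0.3 * 2.0 * 1e-3)
    assert t[0] @ w[0] < 0


def test_spinning_sphere_decay_rate_matches_analytic():
    """Angular velocity under constant rolling torque decays linearly at
    rate mu_r Fn Rp / I."""
    mu_r, fn, rp = 0.3, 2.0, 1e-3
    inertia = 4e-6
    w = np.array([[0.0, 0.0, 50.0]])
    dt = 1e-6
    steps = 200
    for _ in range(steps):
        t = C.rolling_torque(mu_r, fn, rp, w)
        w = w + t / inertia * dt
    expect = 50.0 - mu_r * fn * rp / inertia * steps * dt
    assert w[0, 2] == pytest.approx(expect, rel=1e-9)


# ----- JKR -------------------------------------------------------------------

GAMMA, E_STAR, R_STAR = 0.02, 1.33e5, 1.5e-3


def test_jkr_zero_at_zero_radius():
    assert C.jkr_normal_force(0.0, GAMMA, E_STAR, R_STAR) == 0.0


def test_jkr_reduces_to_hertz_without_adhesion():
    dn = 2e-5
    a = np.sqrt(R_STAR * dn)
    assert C.jkr_normal_force(a, 0.0, E_STAR, R_STAR) == pytest.approx(
        C.hertz_normal_force(dn, E_STAR, R_STAR))


def test_jkr_pulloff_matches_grid_minimum():
    a = np.linspace(1e-9, 5e-3, 200_000)
    f_min = C.jkr_normal_force(a, GAMMA, E_STAR, R_STAR).min()
    assert -f_min == pytest.approx(C.jkr_pulloff_force(GAMMA, R_STAR),
                                   rel=1e-3)
    assert C.jkr_pulloff_force(GAMMA, R_STAR) == pytest.approx(
        3 * np.pi * GAMMA * R_STAR)


@pytest.mark.parametrize("dn", [3e-5, 1e-6, 0.0, -1e-6])
def test_jkr_radius_inversion_roundtrip(dn):
    a = C.jkr_contact_radius(dn, GAMMA, E_STAR, R_STAR)[0]
    assert C.jkr_overlap(a, GAMMA, E_STAR, R_STAR) == pytest.approx(
        dn, abs=1e-12)


def test_jkr_detaches_below_fold():
    _, dn_c = C.jkr_detachment(GAMMA, E_STAR, R_STAR)
    assert dn_c < 0
    a = C.jkr_contact_radius(dn_c * 1.5, GAMMA, E_STAR, R_STAR)
    assert a[0] == 0.0


# ----- Rayleigh time step ----------------------------------------------------

def test_rayleigh_linear_in_radius():
    dt1 = C.rayleigh_timestep(1e-3, 1500, 1e7, 0.25)
    dt2 = C.rayleigh_timestep(0.5e-3, 1500, 1e7, 0.25)
    assert dt1 == pytest.approx(2 * dt2)


def test_rayleigh_hand_value_reference_material():
    # St-Mg at 100x scale: D50 = 5.52 um -> r = 2.76e-4 m
    r, rho, g, nu = 2.76e-4, 1110.0, 1e7, 0.30
    expect = 0.25 * np.pi * r * np.sqrt(rho / g) / (0.1631 * nu + 0.8766)
    assert C.rayleigh_timestep(r, rho, g, nu, 0.25) == pytest.approx(expect)


def test_rayleigh_rejects_zero_fraction():
    with pytest.raises(ValueError):
        C.rayleigh_timestep(1e-3, 1500, 1e7, 0.25, fraction=0.0)
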