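"""Soft-sphere contact force laws: Hertz-Mindlin (no slip) and JKR.

Normal elastic force follows Hertz theory,

    F_n = (4/3) E* sqrt(R*) dn^(3/2),

with equivalent modulus 1/E* = (1-nu_a^2)/E_a + (1-nu_b^2)/E_b and
equivalent radius 1/R* = 1/R_a + 1/R_b.  Tangential force is the Mindlin
no-slip spring F_t = -S_t dt with stiffness S_t = 8 G* sqrt(R* dn),
capped by the Coulomb limit mu_s |F_n|.  Both directions carry viscous
damping -2 sqrt(5/6) beta sqrt(S m*) v_rel with the damping ratio
beta = -ln e / sqrt(ln^2 e + pi^2) tied to the restitution coefficient.
Rolling resistance applies the constant-directional torque
-mu_r |F_n| R_p omega_hat.

Cohesion uses the Johnson-Kendall-Roberts model expressed through the
contact radius a,

    F_JKR = -4 sqrt(pi gamma E*) a^(3/2) + (4 E* / 3 R*) a^3,

whose minimum over a is the pull-off force -3 pi gamma R*; the
overlap/contact-radius relation dn = a^2/R* - sqrt(4 pi gamma a / E*)
is inverted by Newton iteration.  All functions are vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DerivedContactProps",
    "equivalent_props",
    "damping_beta",
    "hertz_normal_force",
    "normal_stiffness",
    "tangential_stiffness",
    "normal_damping_force",
    "tangential_force",
    "rolling_torque",
    "jkr_normal_force",
    "jkr_contact_radius",
    "jkr_pulloff_force",
    "jkr_detachment",
    "rayleigh_timestep",
]


@dataclass(frozen=True)
class DerivedContactProps:
    """Equivalent properties of one contacting pair."""

    e_star: float   # equivalent Young's modulus, Pa
    g_star: float   # equivalent shear modulus, Pa
    r_star: float   # equivalent radius, m
    m_star: float   # equivalent mass, kg
    beta: float     # damping ratio, dimensionless


def equivalent_props(
    youngs_a: float, poisson_a: float, radius_a: float, mass_a: float,
    youngs_b: float | None = None, poisson_b: float | None = None,
    radius_b: float | None = None, mass_b: float | None = None,
    restitution: float = 1.0,
    shear_a: float | None = None, shear_b: float | None = None,
) -> DerivedContactProps:
    """Equivalent E*, G*, R*, m* for a pair; ``b`` fields None mean a wall.

    A wall is treated as an infinite-mass, infinite-radius body: R* and
    m* reduce to the particle's own radius and mass.  Shear moduli
    default to E / (2(1+nu)).
    """
    if min(youngs_a, radius_a, mass_a) <= 0:
        raise ValueError("particle properties must be positive")
    if shear_a is None:
        shear_a = youngs_a / (2.0 * (1.0 + poisson_a))
    if youngs_b is None:
        # wall defaults to the same elastic constants as side a unless given
        youngs_b, poisson_b, shear_b = youngs_a, poisson_a, shear_a
        inv_r = 1.0 / radius_a
        inv_m = 1.0 / mass_a
    else:
        if radius_b is None or mass_b is None:
            inv_r = 1.0 / radius_a
            inv_m = 1.0 / mass_a
        else:
            if min(radius_b, mass_b) <= 0:
                raise ValueError("pair properties must be positive")
            inv_r = 1.0 / radius_a + 1.0 / radius_b
            inv_m = 1.0 / mass_a + 1.0 / mass_b
        if shear_b is None:
            shear_b = youngs_b / (2.0 * (1.0 + poisson_b))
    inv_e = (1.0 - poisson_a**2) / youngs_a + (1.0 - poisson_b**2) / youngs_b
    inv_g = (2.0 - poisson_a) / shear_a + (2.0 - poisson_b) / shear_b
    return DerivedContactProps(
        e_star=1.0 / inv_e,
        g_star=1.0 / inv_g,
        r_star=1.0 / inv_r,
        m_star=1.0 / inv_m,
        beta=damping_beta(restitution),
    )


def damping_beta(restitution) -> np.ndarray | float:
    """Damping ratio beta = -ln e / sqrt(ln^2 e + pi^2); 0 for e = 1."""
    e = np.asarray(restitution, dtype=float)
    if np.any(e <= 0) or np.any(e > 1):
        raise ValueError("restitution must lie in (0, 1]")
    ln_e = np.log(e)
    out = -ln_e / np.sqrt(ln_e**2 + np.pi**2)
    return float(out) if out.ndim == 0 else out


def hertz_normal_force(overlap, e_star, r_star):
    """Hertz elastic normal force magnitude; zero for non-positive overlap."""
    dn = np.maximum(np.asarray(overlap, dtype=float), 0.0)
    f = (4.0 / 3.0) * e_star * np.sqrt(r_star) * dn**1.5
    return float(f) if np.ndim(f) == 0 else f


def normal_stiffness(overlap, e_star, r_star):
    """S_n = 2 E* sqrt(R* dn)."""
    dn = np.maximum(np.asarray(overlap, dtype=float), 0.0)
    return 2.0 * e_star * np.sqrt(r_star * dn)


def tangential_stiffness(overlap, g_star, r_star):
    """S_t = 8 G* sqrt(R* dn)."""
    dn = np.maximum(np.asarray(overlap, dtype=float), 0.0)
    return 8.0 * g_star * np.sqrt(r_star * dn)


_DAMP = 2.0 * np.sqrt(5.0 / 6.0)


def normal_damping_force(beta, s_n, m_star, v_n_rel):
    """Viscous normal damping -2 sqrt(5/6) beta sqrt(S_n m*) v_n_rel."""
    coeff = _DAMP * np.asarray(beta) * np.sqrt(np.asarray(s_n) * np.asarray(m_star))
    return -np.atleast_1d(coeff)[..., None] * np.atleast_2d(v_n_rel)


def tangential_force(s_t, delta_t, beta, m_star, v_t_rel, mu_s, f_n_mag):
    """Mindlin spring + damping with the Coulomb cap.

    Returns ``(force, delta_t)`` where ``delta_t`` has been rescaled onto
    the friction cone wherever |F_t| would exceed mu_s |F_n|.
    """
    s_t = np.atleast_1d(np.asarray(s_t, dtype=float))
    delta_t = np.atleast_2d(np.asarray(delta_t, dtype=float)).copy()
    v_t_rel = np.atleast_2d(np.asarray(v_t_rel, dtype=float))
    spring = -s_t[:, None] * delta_t
    coeff = _DAMP * np.asarray(beta) * np.sqrt(s_t * np.asarray(m_star))
    force = spring + (-np.atleast_1d(coeff)[:, None] * v_t_rel)
    limit = np.atleast_1d(np.asarray(mu_s) * np.asarray(f_n_mag))
    mag = np.linalg.norm(force, axis=1)
    over = mag > limit
    if np.any(over):
        scale = np.where(mag > 0, limit / np.maximum(mag, 1e-300), 0.0)
        force[over] *= scale[over, None]
        # keep the spring on the cone so it does not wind up while sliding
        with np.errstate(divide="ignore", invalid="ignore"):
            delta_t[over] = np.where(
                s_t[over, None] > 0, -force[over] / s_t[over, None], 0.0
            )
    return force, delta_t


def rolling_torque(mu_r, f_n_mag, r_p, omega):
    """Constant-directional rolling resistance -mu_r |F_n| R_p omega_hat."""
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    w = np.linalg.norm(omega, axis=1)
    mag = np.atleast_1d(np.asarray(mu_r) * np.asarray(f_n_mag) * np.asarray(r_p))
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(w[:, None] > 0, omega / np.maximum(w, 1e-300)[:, None], 0.0)
    return -mag[:, None] * unit


# ---------------------------------------------------------------------------
# JKR cohesion
# ---------------------------------------------------------------------------

def jkr_normal_force(a, gamma, e_star, r_star):
    """Signed JKR normal force as a function of contact radius a.

    Negative values are tensile (cohesive); gamma = 0 recovers Hertz with
    a^2 = R* dn.
    """
    a = np.asarray(a, dtype=float)
    f = -4.0 * np.sqrt(np.pi * gamma * e_star) * a**1.5 \
        + (4.0 * e_star / (3.0 * r_star)) * a**3
    return float(f) if f.ndim == 0 else f


def jkr_overlap(a, gamma, e_star, r_star):
    """Overlap dn(a) = a^2/R* - sqrt(4 pi gamma a / E*)."""
    a = np.asarray(a, dtype=float)
    return a**2 / r_star - np.sqrt(4.0 * np.pi * gamma * a / e_star)


def jkr_detachment(gamma, e_star, r_star):
    """Contact radius and (negative) overlap at displacement-control detachment.

    The overlap dn(a) has a fold minimum at a_c; for dn below dn(a_c) no
    contact solution exists and the pair separates.  Accepts scalars or
    arrays; gamma = 0 yields (0, 0).
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.all(gamma == 0):
        z = np.zeros_like(gamma)
        return (0.0, 0.0) if z.ndim == 0 else (z, z)
    # d(dn)/da = 2a/R* - sqrt(pi gamma / (E* a)) = 0
    a_c = (np.asarray(r_star) ** 2 * np.pi * gamma / (4.0 * np.asarray(e_star))
           ) ** (1.0 / 3.0)
    dn_c = np.where(gamma > 0,
                    jkr_overlap(np.maximum(a_c, 1e-300), gamma + (gamma == 0),
                                e_star, r_star), 0.0)
    a_c = np.where(gamma > 0, a_c, 0.0)
    if a_c.ndim == 0:
        return float(a_c), float(dn_c)
    return a_c, dn_c


def jkr_pulloff_force(gamma, r_star) -> float:
    """Pull-off (maximum tensile) force magnitude 3 pi gamma R*."""
    return 3.0 * np.pi * gamma * r_star


def jkr_contact_radius(overlap, gamma, e_star, r_star, a_init=None,
                       iterations: int = 25):
    """Invert dn(a) for the stable (outer) branch by Newton iteration.

    Overlaps below the detachment fold return a = 0 (contact lost).
    """
    dn = np.atleast_1d(np.asarray(overlap, dtype=float))
    if gamma == 0:
        return np.sqrt(r_star * np.maximum(dn, 0.0))
    a_c, dn_c = jkr_detachment(gamma, e_star, r_star)
    active = dn >= dn_c
    # start above the fold so Newton stays on the stable branch
    a = np.maximum(np.sqrt(r_star * np.maximum(dn, 0.0)), 1.5 * a_c)
    if a_init is not None:
        given = np.atleast_1d(np.asarray(a_init, dtype=float))
        a = np.where(given > a_c, given, a)
    c = np.sqrt(4.0 * np.pi * gamma / e_star)
    for _ in range(iterations):
        f = a**2 / r_star - c * np.sqrt(a) - dn
        df = 2.0 * a / r_star - 0.5 * c / np.sqrt(np.maximum(a, 1e-300))
        step = f / df
        a = np.maximum(a - step, a_c)
    return np.where(active, a, 0.0)


def rayleigh_timestep(radii, density, shear_modulus, poisson,
                      fraction: float = 0.25) -> float:
    """Stable time step as a fraction of the Rayleigh surface-wave time.

    T_R = pi R sqrt(rho / G) / (0.1631 nu + 0.8766); dt = fraction * min T_R.
    """
    if fraction <= 0:
        raise ValueError("time-step fraction must be positive")
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    density = np.broadcast_to(np.asarray(density, dtype=float), radii.shape)
    shear = np.broadcast_to(np.asarray(shear_modulus, dtype=float), radii.shape)
    nu = np.broadcast_to(np.asarray(poisson, dtype=float), radii.shape)
    t_r = np.pi * radii * np.sqrt(density / shear) / (0.1631 * nu + 0.8766)
    return float(fraction * t_r.min())
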