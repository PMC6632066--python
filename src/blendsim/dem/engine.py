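"""Soft-sphere DEM core: particle state, neighbour search, time stepping.

The engine integrates Newton's equations for translations and rotations
with a semi-implicit (symplectic) Euler scheme: contact forces are
evaluated from the current state, velocities are updated first and
positions second.  Particle-particle candidate pairs come from a
uniform-grid broad phase kept as a Verlet list with a skin distance;
particle-wall candidates are likewise cached per wall in the mesh body
frame.  Per-contact tangential springs and JKR contact radii persist
across steps keyed by pair id and survive list rebuilds.

Units are SI throughout: positions m, velocities m/s, forces N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ..materials import MaterialParams, pair_interaction
from . import _kernels as K
from . import contacts as C
from .geometry import WallMesh, closest_point_on_triangles

__all__ = ["ParticleSystem", "Simulation", "neighbor_pairs", "brute_force_pairs"]

GRAVITY = np.array([0.0, 0.0, -9.81])


class IntegrationError(RuntimeError):
    """Non-finite particle state detected during stepping."""


# ---------------------------------------------------------------------------
# broad phase
# ---------------------------------------------------------------------------

def neighbor_pairs(positions: np.ndarray, cutoff: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform-grid broad phase: unique (i, j) pairs with i < j.

    Returns every pair of points separated by less than ``cutoff`` (a
    superset of truly overlapping pairs when ``cutoff`` is at least the
    maximum contact distance; a subset of the brute-force list within
    ``cutoff``).  Coincident points are reported once.
    """
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    cells = np.floor(positions / cutoff).astype(np.int64)
    cells -= cells.min(axis=0)
    dims = cells.max(axis=0) + 2
    keys = (cells[:, 0] * dims[1] + cells[:, 1]) * dims[2] + cells[:, 2]
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    uniq, starts = np.unique(sorted_keys, return_index=True)
    counts = np.diff(np.append(starts, n))
    rank = np.empty(n, dtype=np.int64)          # position in the sorted array
    rank[order] = np.arange(n)
    # half the 27-neighbourhood (plus the cell itself) so each unordered
    # cell pair is visited exactly once
    half = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1),
            (0, 1, 1), (1, 1, 1), (1, -1, 0), (1, 0, -1), (0, 1, -1),
            (1, -1, 1), (1, 1, -1), (1, -1, -1)]
    ii, jj = [], []
    for dx, dy, dz in half:
        off = (dx * dims[1] + dy) * dims[2] + dz
        target = keys + off
        loc = np.searchsorted(uniq, target)
        loc_c = np.clip(loc, 0, len(uniq) - 1)
        found = (loc < len(uniq)) & (uniq[loc_c] == target)
        p = np.where(found)[0]
        if len(p) == 0:
            continue
        st = starts[loc_c[p]]
        ln = counts[loc_c[p]]
        if off == 0:
            # only partners later in the sorted order within the same cell
            new_st = rank[p] + 1
            ln = st + ln - new_st
            st = new_st
            keep = ln > 0
            p, st, ln = p[keep], st[keep], ln[keep]
            if len(p) == 0:
                continue
        total = int(ln.sum())
        if total == 0:
            continue
        a = np.repeat(p, ln)
        # flat gather of the candidate ranges (arange trick)
        csum = np.cumsum(ln) - ln
        b_pos = np.repeat(st - csum, ln) + np.arange(total)
        ii.append(a)
        jj.append(order[b_pos])
    if not ii:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    i = np.concatenate(ii)
    j = np.concatenate(jj)
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    keep = d < cutoff
    i, j = i[keep], j[keep]
    swap = i > j
    i2 = np.where(swap, j, i)
    j2 = np.where(swap, i, j)
    return i2, j2


def brute_force_pairs(positions: np.ndarray, cutoff: float
                      ) -> tuple[np.ndarray, np.ndarray]:
    """O(n^2) reference pair list (oracle for the grid broad phase)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    i, j = np.triu_indices(n, k=1)
    d = np.linalg.norm(positions[i] - positions[j], axis=1)
    keep = d < cutoff
    return i[keep], j[keep]


def _clamp_impulse(force: np.ndarray, m_star: np.ndarray, v_rel: np.ndarray,
                   dt: float) -> np.ndarray:
    """Limit a velocity-proportional force so its impulse over one step
    cannot exceed the momentum of the relative motion it opposes."""
    mag = np.linalg.norm(force, axis=1)
    cap = np.asarray(m_star) * np.linalg.norm(v_rel, axis=1) / dt
    scale = np.where(mag > cap, cap / np.maximum(mag, 1e-300), 1.0)
    return force * scale[:, None]


# ---------------------------------------------------------------------------
# particle system
# ---------------------------------------------------------------------------

@dataclass
class ParticleSystem:
    """Particle state plus materials, gravity and wall geometry."""

    pos: np.ndarray
    vel: np.ndarray
    omega: np.ndarray
    radius: np.ndarray
    material_id: np.ndarray
    materials: Sequence[MaterialParams]
    walls: list[WallMesh] = field(default_factory=list)
    gravity: np.ndarray = field(default_factory=lambda: GRAVITY.copy())
    time: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.atleast_2d(np.asarray(self.pos, dtype=float))
        self.vel = np.atleast_2d(np.asarray(self.vel, dtype=float))
        self.omega = np.atleast_2d(np.asarray(self.omega, dtype=float))
        self.radius = np.atleast_1d(np.asarray(self.radius, dtype=float))
        self.material_id = np.atleast_1d(np.asarray(self.material_id, dtype=int))
        self.gravity = np.asarray(self.gravity, dtype=float)
        if np.any(self.radius <= 0):
            raise ValueError("all radii must be positive")
        dens = np.array([m.density for m in self.materials])[self.material_id]
        self.mass = dens * (4.0 / 3.0) * np.pi * self.radius**3
        self.inertia = 0.4 * self.mass * self.radius**2

    @property
    def n(self) -> int:
        return len(self.radius)

    def kinetic_energy(self) -> float:
        trans = 0.5 * np.sum(self.mass * np.einsum("ij,ij->i", self.vel, self.vel))
        rot = 0.5 * np.sum(self.inertia * np.einsum("ij,ij->i", self.omega, self.omega))
        return float(trans + rot)

    def momentum(self) -> np.ndarray:
        return self.mass @ self.vel

    def rayleigh_dt(self, fraction: float = 0.25) -> float:
        dens = np.array([m.density for m in self.materials])[self.material_id]
        shear = np.array([m.shear_modulus_pa for m in self.materials])[self.material_id]
        nu = np.array([m.poisson for m in self.materials])[self.material_id]
        return C.rayleigh_timestep(self.radius, dens, shear, nu, fraction)


# default wall elastic constants: stainless steel
_WALL_YOUNGS = 2.0 * 7e10 * (1.0 + 0.3)
_WALL_POISSON = 0.3
_WALL_SHEAR = 7e10


class Simulation:
    """Drives a :class:`ParticleSystem` forward in time.

    Material-pair scalars (E*, G*, damping ratio, frictions, surface
    energy) are tabulated once per material pair; per-contact tangential
    history and JKR contact radii persist across steps.
    """

    def __init__(self, system: ParticleSystem, skin: float | None = None,
                 integrator: str = "euler", use_kernels: bool | None = None):
        if integrator not in ("euler", "verlet"):
            raise ValueError("integrator must be 'euler' or 'verlet'")
        self.use_kernels = K.HAVE_NUMBA if use_kernels is None else use_kernels
        self.sys = system
        self.skin = skin if skin is not None else 1.2 * system.radius.min()
        self._skin_eff = self.skin
        self._dt_hint = 0.0
        self.integrator = integrator
        self._accel_prev = None
        self._alpha_prev = None
        self._tables()
        # persistent contact state, keyed by encoded pair id
        self._state_keys = np.empty(0, dtype=np.int64)
        self._state_dt = np.empty((0, 3))
        self._state_a = np.empty(0)
        self._pp_pairs = None
        self._pw_cache: list[tuple[np.ndarray, np.ndarray]] = []
        self._pos_at_build = None
        self._wall_angle_at_build = None
        nw = len(system.walls)
        self.wall_reaction_force = [np.zeros(3) for _ in range(nw)]
        self.wall_reaction_torque = [np.zeros(3) for _ in range(nw)]
        # kernel-path caches: pair properties gathered once per rebuild,
        # tangential/JKR state kept aligned with the pair list
        self._ppk: dict | None = None
        self._pp_dt_al = np.empty((0, 3))
        self._pp_a_al = np.empty(0)
        self._pw_props: list[dict] = []

    # ----- material pair tables -------------------------------------------
    def _tables(self) -> None:
        mats = self.sys.materials
        m = len(mats)
        self.e_star_pp = np.zeros((m, m))
        self.g_star_pp = np.zeros((m, m))
        self.beta_pp = np.zeros((m, m))
        self.mu_s_pp = np.zeros((m, m))
        self.mu_r_pp = np.zeros((m, m))
        self.gamma_pp = np.zeros((m, m))
        self.e_star_pw = np.zeros(m)
        self.g_star_pw = np.zeros(m)
        self.beta_pw = np.zeros(m)
        self.mu_s_pw = np.zeros(m)
        self.mu_r_pw = np.zeros(m)
        self.gamma_pw = np.zeros(m)
        for i, a in enumerate(mats):
            for j, b in enumerate(mats):
                inter = pair_interaction(a, b)
                inv_e = ((1 - a.poisson**2) / a.youngs_modulus
                         + (1 - b.poisson**2) / b.youngs_modulus)
                inv_g = ((2 - a.poisson) / a.shear_modulus_pa
                         + (2 - b.poisson) / b.shear_modulus_pa)
                self.e_star_pp[i, j] = 1.0 / inv_e
                self.g_star_pp[i, j] = 1.0 / inv_g
                self.beta_pp[i, j] = C.damping_beta(inter.restitution)
                self.mu_s_pp[i, j] = inter.static_friction
                self.mu_r_pp[i, j] = inter.rolling_friction
                if a.surface_energy_pp > 0 or b.surface_energy_pp > 0:
                    self.gamma_pp[i, j] = 0.5 * (a.surface_energy_pp
                                                 + b.surface_energy_pp)
            inv_e = ((1 - a.poisson**2) / a.youngs_modulus
                     + (1 - _WALL_POISSON**2) / _WALL_YOUNGS)
            inv_g = ((2 - a.poisson) / a.shear_modulus_pa
                     + (2 - _WALL_POISSON) / _WALL_SHEAR)
            self.e_star_pw[i] = 1.0 / inv_e
            self.g_star_pw[i] = 1.0 / inv_g
            self.beta_pw[i] = C.damping_beta(a.pw.restitution)
            self.mu_s_pw[i] = a.pw.static_friction
            self.mu_r_pw[i] = a.pw.rolling_friction
            self.gamma_pw[i] = a.surface_energy_pw

    # ----- neighbour bookkeeping ------------------------------------------
    def _rebuild_lists(self) -> None:
        s = self.sys
        # widen the skin when particles move fast (free fall) so lists
        # survive several steps between rebuilds
        v_max = float(np.abs(s.vel).max()) if s.n else 0.0
        self._skin_eff = max(self.skin, 12.0 * v_max * self._dt_hint)
        cutoff = 2.0 * s.radius.max() + self._skin_eff
        self._pp_pairs = neighbor_pairs(s.pos, cutoff)
        self._pw_cache = []
        for wall in s.walls:
            body = wall.kin.world_to_body(s.pos)
            p_idx, t_idx = wall.candidates(body, s.radius.max() + self._skin_eff)
            self._pw_cache.append((p_idx, t_idx))
        if self.use_kernels:
            self._cache_pair_props()
        self._pos_at_build = s.pos.copy()
        self._wall_angle_at_build = [w.kin.angle for w in s.walls]

    def _cache_pair_props(self) -> None:
        """Gather per-pair material properties once per rebuild and carry
        the aligned tangential/JKR state across the pair-list change."""
        s = self.sys
        old = self._ppk
        i, j = self._pp_pairs
        i = np.ascontiguousarray(i, dtype=np.int64)
        j = np.ascontiguousarray(j, dtype=np.int64)
        mi, mj = s.material_id[i], s.material_id[j]
        keys = i * (s.n + 1) + j
        dt_vec = np.zeros((len(i), 3))
        a_vec = np.zeros(len(i))
        if old is not None and len(old["keys"]):
            order = np.argsort(old["keys"])
            sk = old["keys"][order]
            loc = np.searchsorted(sk, keys)
            loc_c = np.clip(loc, 0, len(sk) - 1)
            hit = sk[loc_c] == keys
            src = order[loc_c[hit]]
            dt_vec[hit] = self._pp_dt_al[src]
            a_vec[hit] = self._pp_a_al[src]
        self._ppk = dict(
            i=i, j=j, keys=keys,
            e=np.ascontiguousarray(self.e_star_pp[mi, mj]),
            g=np.ascontiguousarray(self.g_star_pp[mi, mj]),
            beta=np.ascontiguousarray(self.beta_pp[mi, mj]),
            mus=np.ascontiguousarray(self.mu_s_pp[mi, mj]),
            mur=np.ascontiguousarray(self.mu_r_pp[mi, mj]),
            gamma=np.ascontiguousarray(self.gamma_pp[mi, mj]),
        )
        self._pp_dt_al = dt_vec
        self._pp_a_al = a_vec
        self._pw_props = []
        for (p_idx, t_idx), wall in zip(self._pw_cache, s.walls):
            mw = s.material_id[p_idx]
            self._pw_props.append(dict(
                e=np.ascontiguousarray(self.e_star_pw[mw]),
                g=np.ascontiguousarray(self.g_star_pw[mw]),
                beta=np.ascontiguousarray(self.beta_pw[mw]),
                mus=np.ascontiguousarray(self.mu_s_pw[mw]),
                mur=np.ascontiguousarray(self.mu_r_pw[mw]),
                gamma=np.ascontiguousarray(self.gamma_pw[mw]),
                patch=wall.patch_id[t_idx],
                bound=wall.tri_bound[t_idx],
            ))

    def _lists_stale(self) -> bool:
        if self._pp_pairs is None:
            return True
        disp = np.abs(self.sys.pos - self._pos_at_build).max() if self.sys.n else 0.0
        if disp > 0.45 * self._skin_eff:
            return True
        for wall, a0 in zip(self.sys.walls, self._wall_angle_at_build):
            # wall rotation sweeps particles through the body frame
            extent = np.abs(wall.triangles).max()
            if abs(wall.kin.angle - a0) * extent > 0.4 * self._skin_eff:
                return True
        return False

    # ----- contact state persistence --------------------------------------
    def _lookup_state(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dt = np.zeros((len(keys), 3))
        a = np.zeros(len(keys))
        if len(self._state_keys):
            loc = np.searchsorted(self._state_keys, keys)
            loc_c = np.clip(loc, 0, len(self._state_keys) - 1)
            hit = self._state_keys[loc_c] == keys
            dt[hit] = self._state_dt[loc_c[hit]]
            a[hit] = self._state_a[loc_c[hit]]
        return dt, a

    def _store_state(self, keys: np.ndarray, dt: np.ndarray, a: np.ndarray) -> None:
        order = np.argsort(keys)
        self._state_keys = keys[order]
        self._state_dt = dt[order]
        self._state_a = a[order]

    # ----- stepping --------------------------------------------------------
    def step(self, dt: float, warn_dt: bool = True) -> None:
        s = self.sys
        self._dt_hint = dt
        stable = s.rayleigh_dt(fraction=1.0)
        if warn_dt and dt > 0.35 * stable:
            import warnings
            warnings.warn(f"dt={dt:.3g} s exceeds 35% of the Rayleigh time "
                          f"{stable:.3g} s; integration may be unstable")
        if self.integrator == "verlet":
            # kick-drift-kick: half-kick with the stored acceleration,
            # drift, then evaluate forces and finish the kick below
            if self._accel_prev is not None:
                s.vel += 0.5 * self._accel_prev * dt
                s.omega += 0.5 * self._alpha_prev * dt
            s.pos += s.vel * dt
            for wall in s.walls:
                wall.kin.advance(dt)
        if self._lists_stale():
            self._rebuild_lists()

        force = np.tile(s.gravity, (s.n, 1)) * s.mass[:, None]
        torque = np.zeros((s.n, 3))
        for w in range(len(s.walls)):
            self.wall_reaction_force[w][:] = 0.0
            self.wall_reaction_torque[w][:] = 0.0
        new_keys, new_dt, new_a = [], [], []

        self._pp_forces(dt, force, torque, new_keys, new_dt, new_a)
        self._pw_forces(dt, force, torque, new_keys, new_dt, new_a)

        if new_keys:
            self._store_state(np.concatenate(new_keys), np.vstack(new_dt),
                              np.concatenate(new_a))
        else:
            self._store_state(np.empty(0, dtype=np.int64), np.empty((0, 3)),
                              np.empty(0))

        accel = force / s.mass[:, None]
        alpha = torque / s.inertia[:, None]
        if self.integrator == "verlet":
            if self._accel_prev is None:
                # first step: plain half-kick bootstrap
                s.vel += 0.5 * accel * dt
                s.omega += 0.5 * alpha * dt
                s.pos += s.vel * dt
                for wall in s.walls:
                    wall.kin.advance(dt)
            s.vel += 0.5 * accel * dt
            s.omega += 0.5 * alpha * dt
            self._accel_prev = accel
            self._alpha_prev = alpha
        else:
            s.vel += accel * dt
            s.pos += s.vel * dt
            s.omega += alpha * dt
            for wall in s.walls:
                wall.kin.advance(dt)
        s.time += dt
        if not np.isfinite(s.pos).all():
            bad = np.where(~np.isfinite(s.pos).all(axis=1))[0]
            raise IntegrationError(
                f"non-finite positions at t={s.time:.4g}s for particles {bad[:5]}"
            )

    def run(self, duration: float, dt: float, callback=None,
            callback_every: int = 0) -> None:
        steps = int(round(duration / dt))
        for k in range(steps):
            self.step(dt, warn_dt=(k == 0))
            if callback is not None and callback_every and (k + 1) % callback_every == 0:
                callback(self.sys)

    # ----- particle-particle forces ---------------------------------------
    def _pp_forces(self, dt, force, torque, new_keys, new_dt, new_a) -> None:
        if self.use_kernels:
            self._pp_forces_kernel(dt, force, torque, new_keys, new_dt, new_a)
        else:
            self._pp_forces_numpy(dt, force, torque, new_keys, new_dt, new_a)

    def _pp_forces_kernel(self, dt, force, torque, new_keys, new_dt, new_a
                          ) -> None:
        # pair properties and tangential/JKR state are cached aligned
        # with the pair list at each rebuild
        s = self.sys
        pk = self._ppk
        if pk is None or len(pk["i"]) == 0:
            return
        active = np.empty(len(pk["i"]), dtype=np.bool_)
        K.pp_forces(s.pos, s.vel, s.omega, s.radius, s.mass, s.inertia,
                    pk["i"], pk["j"], pk["e"], pk["g"], pk["beta"],
                    pk["mus"], pk["mur"], pk["gamma"],
                    self._pp_dt_al, self._pp_a_al, dt, force, torque, active)

    def _pp_forces_numpy(self, dt, force, torque, new_keys, new_dt, new_a) -> None:
        s = self.sys
        i, j = self._pp_pairs
        if len(i) == 0:
            return
        rij = s.pos[j] - s.pos[i]
        d = np.linalg.norm(rij, axis=1)
        d = np.maximum(d, 1e-12)
        overlap = s.radius[i] + s.radius[j] - d
        mi, mj = s.material_id[i], s.material_id[j]
        gamma = self.gamma_pp[mi, mj]
        e_star = self.e_star_pp[mi, mj]
        r_star = s.radius[i] * s.radius[j] / (s.radius[i] + s.radius[j])
        # JKR contacts stay active into small negative overlap
        if np.any(gamma > 0):
            a_c = (r_star**2 * np.pi * gamma / (4.0 * e_star)) ** (1.0 / 3.0)
            dn_c = np.where(gamma > 0,
                            C.jkr_overlap(np.maximum(a_c, 1e-300), gamma + 1e-300,
                                          e_star, r_star), 0.0)
            active = overlap > dn_c
        else:
            active = overlap > 0
        if not np.any(active):
            return
        k = np.where(active)[0]
        i, j, d, overlap = i[k], j[k], d[k], overlap[k]
        n_hat = (s.pos[j] - s.pos[i]) / d[:, None]
        mi, mj = mi[k], mj[k]
        e_star, r_star, gamma = e_star[k], r_star[k], gamma[k]
        g_star = self.g_star_pp[mi, mj]
        beta = self.beta_pp[mi, mj]
        mu_s = self.mu_s_pp[mi, mj]
        mu_r = self.mu_r_pp[mi, mj]
        m_star = s.mass[i] * s.mass[j] / (s.mass[i] + s.mass[j])

        keys = i.astype(np.int64) * (s.n + 1) + j
        dt_vec, a_prev = self._lookup_state(keys)

        # normal elastic force (repulsive positive)
        jkr = gamma > 0
        f_rep = C.hertz_normal_force(overlap, e_star, r_star)
        a_new = np.zeros(len(i))
        if np.any(jkr):
            # gamma varies per pair: vectorised Newton per unique value
            a_sol = np.zeros(jkr.sum())
            idx = np.where(jkr)[0]
            for g in np.unique(gamma[jkr]):
                sub = gamma[idx] == g
                a_sol[sub] = C.jkr_contact_radius(
                    overlap[idx][sub], g, e_star[idx][sub], r_star[idx][sub],
                    a_init=a_prev[idx][sub])
            a_new[idx] = a_sol
            f_rep = np.where(jkr, C.jkr_normal_force(a_new, gamma + (gamma == 0),
                                                     e_star, r_star), f_rep)

        # relative velocity at contact (i relative to j)
        r_ci = s.radius[i][:, None] * n_hat
        r_cj = -s.radius[j][:, None] * n_hat
        v_rel = (s.vel[i] + np.cross(s.omega[i], r_ci)
                 - s.vel[j] - np.cross(s.omega[j], r_cj))
        vn_mag = np.einsum("ij,ij->i", v_rel, n_hat)
        vn_vec = vn_mag[:, None] * n_hat
        vt_vec = v_rel - vn_vec

        s_n = C.normal_stiffness(overlap, e_star, r_star)
        s_t = C.tangential_stiffness(overlap, g_star, r_star)
        f_damp = C.normal_damping_force(beta, s_n, m_star, vn_vec)
        # clamp the damping impulse so it can at most cancel the normal
        # relative velocity in one step (guards under-resolved impacts)
        f_damp = _clamp_impulse(f_damp, m_star, vn_vec, dt)

        # tangential spring update
        dt_vec = dt_vec + vt_vec * dt
        dt_vec -= np.einsum("ij,ij->i", dt_vec, n_hat)[:, None] * n_hat
        f_t, dt_vec = C.tangential_force(s_t, dt_vec, beta, m_star, vt_vec,
                                         mu_s, np.abs(f_rep))

        f_pair = -f_rep[:, None] * n_hat + f_damp + f_t
        np.add.at(force, i, f_pair)
        np.add.at(force, j, -f_pair)
        np.add.at(torque, i, np.cross(r_ci, f_t))
        np.add.at(torque, j, np.cross(r_cj, -f_t))

        # rolling resistance, clamped so it cannot reverse spin in one step
        for idx_arr, rad in ((i, s.radius[i]), (j, s.radius[j])):
            t_roll = C.rolling_torque(mu_r, np.abs(f_rep), rad, s.omega[idx_arr])
            cap = (s.inertia[idx_arr] * np.linalg.norm(s.omega[idx_arr], axis=1)
                   / dt)
            mag = np.linalg.norm(t_roll, axis=1)
            scale = np.where(mag > cap, cap / np.maximum(mag, 1e-300), 1.0)
            np.add.at(torque, idx_arr, t_roll * scale[:, None])

        new_keys.append(keys)
        new_dt.append(dt_vec)
        new_a.append(a_new)

    # ----- particle-wall forces -------------------------------------------
    def _pw_forces(self, dt, force, torque, new_keys, new_dt, new_a) -> None:
        if self.use_kernels:
            self._pw_forces_kernel(dt, force, torque, new_keys, new_dt, new_a)
        else:
            self._pw_forces_numpy(dt, force, torque, new_keys, new_dt, new_a)

    def _pw_forces_kernel(self, dt, force, torque, new_keys, new_dt, new_a
                          ) -> None:
        s = self.sys
        for w_idx, wall in enumerate(s.walls):
            p_cand, t_cand = self._pw_cache[w_idx]
            if len(p_cand) == 0:
                continue
            props = self._pw_props[w_idx]
            body_all = wall.kin.world_to_body(s.pos)
            diff_c = body_all[p_cand] - wall.tri_centroid[t_cand]
            reach = (s.radius[p_cand] + props["bound"]
                     + 0.5 * self._skin_eff)
            near = np.einsum("ij,ij->i", diff_c, diff_c) < reach**2
            if not np.any(near):
                continue
            sel_near = np.where(near)[0]
            p_c, t_c = p_cand[sel_near], t_cand[sel_near]
            body = np.ascontiguousarray(body_all[p_c])
            closest_b = np.empty_like(body)
            K.closest_points(np.ascontiguousarray(wall.triangles[t_c]),
                             body, closest_b)
            diff_b = body - closest_b
            dist = np.linalg.norm(diff_b, axis=1)
            overlap = s.radius[p_c] - dist
            gamma = props["gamma"][sel_near]
            e_star = props["e"][sel_near]
            r_star = s.radius[p_c]
            if np.any(gamma > 0):
                a_c = (r_star**2 * np.pi * gamma / (4.0 * e_star)) ** (1.0 / 3.0)
                dn_c = np.where(gamma > 0,
                                C.jkr_overlap(np.maximum(a_c, 1e-300),
                                              gamma + (gamma == 0), e_star,
                                              r_star), 0.0)
                touching = overlap > dn_c
            else:
                touching = overlap > 0
            if not np.any(touching):
                continue
            # deduplicate per (particle, smooth patch): keep deepest overlap
            sel = np.where(touching)[0]
            patch = props["patch"][sel_near[sel]]
            combo = p_c[sel].astype(np.int64) * (wall.patch_id.max() + 1) + patch
            order = np.lexsort((-overlap[sel], combo))
            combo_sorted = combo[order]
            first = np.ones(len(order), dtype=bool)
            first[1:] = combo_sorted[1:] != combo_sorted[:-1]
            sel = sel[order[first]]
            src = sel_near[sel]

            p_i = np.ascontiguousarray(p_c[sel], dtype=np.int64)
            ov = np.ascontiguousarray(overlap[sel])
            n_hat = wall.kin.rotate_vec_to_world(
                diff_b[sel] / np.maximum(dist[sel], 1e-12)[:, None])
            contact_w = s.pos[p_i] - (s.radius[p_i] - ov)[:, None] * n_hat
            wall_v = wall.kin.surface_velocity(contact_w)

            keys = (np.int64(s.n + 1) * (s.n + 1 + w_idx * 4096
                    + props["patch"][src]) + p_i)
            dt_vec, a_prev = self._lookup_state(keys)
            pivot = wall.kin.axis_point + wall.kin.offset
            K.pw_forces(s.pos, s.vel, s.omega, s.radius, s.mass, s.inertia,
                        p_i, np.ascontiguousarray(n_hat), ov,
                        np.ascontiguousarray(contact_w),
                        np.ascontiguousarray(wall_v),
                        np.ascontiguousarray(props["e"][src]),
                        np.ascontiguousarray(props["g"][src]),
                        np.ascontiguousarray(props["beta"][src]),
                        np.ascontiguousarray(props["mus"][src]),
                        np.ascontiguousarray(props["mur"][src]),
                        np.ascontiguousarray(props["gamma"][src]),
                        dt_vec, a_prev, dt, force, torque,
                        self.wall_reaction_force[w_idx],
                        self.wall_reaction_torque[w_idx],
                        np.ascontiguousarray(pivot))
            new_keys.append(keys)
            new_dt.append(dt_vec)
            new_a.append(a_prev)

    def _pw_forces_numpy(self, dt, force, torque, new_keys, new_dt, new_a) -> None:
        s = self.sys
        for w_idx, wall in enumerate(s.walls):
            p_cand, t_cand = self._pw_cache[w_idx]
            if len(p_cand) == 0:
                continue
            # transform all particles once, then cull candidates by a
            # centroid-distance test before the exact closest-point pass
            body_all = wall.kin.world_to_body(s.pos)
            diff_c = body_all[p_cand] - wall.tri_centroid[t_cand]
            reach = (s.radius[p_cand] + wall.tri_bound[t_cand]
                     + 0.5 * self._skin_eff)
            near = np.einsum("ij,ij->i", diff_c, diff_c) < reach**2
            if not np.any(near):
                continue
            p_cand, t_cand = p_cand[near], t_cand[near]
            body = body_all[p_cand]
            closest_b = closest_point_on_triangles(wall.triangles[t_cand], body)
            diff_b = body - closest_b
            dist = np.linalg.norm(diff_b, axis=1)
            overlap = s.radius[p_cand] - dist
            mi = s.material_id[p_cand]
            gamma = self.gamma_pw[mi]
            e_star = self.e_star_pw[mi]
            r_star = s.radius[p_cand]
            if np.any(gamma > 0):
                a_c = (r_star**2 * np.pi * gamma / (4.0 * e_star)) ** (1.0 / 3.0)
                dn_c = np.where(gamma > 0,
                                C.jkr_overlap(np.maximum(a_c, 1e-300),
                                              gamma + 1e-300, e_star, r_star), 0.0)
                touching = overlap > dn_c
            else:
                touching = overlap > 0
            if not np.any(touching):
                continue
            # deduplicate per (particle, smooth patch): keep deepest overlap
            sel = np.where(touching)[0]
            patch = wall.patch_id[t_cand[sel]]
            combo = p_cand[sel].astype(np.int64) * (wall.patch_id.max() + 1) + patch
            order = np.lexsort((-overlap[sel], combo))
            combo_sorted = combo[order]
            first = np.ones(len(order), dtype=bool)
            first[1:] = combo_sorted[1:] != combo_sorted[:-1]
            sel = sel[order[first]]

            p_i = p_cand[sel]
            ov = overlap[sel]
            n_hat = wall.kin.rotate_vec_to_world(
                diff_b[sel] / np.maximum(dist[sel], 1e-12)[:, None])
            contact_w = s.pos[p_i] - (s.radius[p_i] - ov)[:, None] * n_hat
            mi = s.material_id[p_i]
            e_star = self.e_star_pw[mi]
            g_star = self.g_star_pw[mi]
            beta = self.beta_pw[mi]
            mu_s = self.mu_s_pw[mi]
            mu_r = self.mu_r_pw[mi]
            gamma = self.gamma_pw[mi]
            r_star = s.radius[p_i]
            m_star = s.mass[p_i]

            keys = (np.int64(s.n + 1) * (s.n + 1 + w_idx * 4096
                    + wall.patch_id[t_cand[sel]]) + p_i)
            dt_vec, a_prev = self._lookup_state(keys)

            jkr = gamma > 0
            f_rep = C.hertz_normal_force(ov, e_star, r_star)
            a_new = np.zeros(len(p_i))
            if np.any(jkr):
                idx = np.where(jkr)[0]
                a_sol = np.zeros(len(idx))
                for g in np.unique(gamma[idx]):
                    sub = gamma[idx] == g
                    a_sol[sub] = C.jkr_contact_radius(
                        ov[idx][sub], g, e_star[idx][sub], r_star[idx][sub],
                        a_init=a_prev[idx][sub])
                a_new[idx] = a_sol
                f_rep = np.where(jkr, C.jkr_normal_force(
                    a_new, gamma + (gamma == 0), e_star, r_star), f_rep)

            wall_v = wall.kin.surface_velocity(contact_w)
            r_ci = contact_w - s.pos[p_i]
            v_rel = s.vel[p_i] + np.cross(s.omega[p_i], r_ci) - wall_v
            # n_hat points from wall surface toward the particle centre
            vn_mag = np.einsum("ij,ij->i", v_rel, n_hat)
            vn_vec = vn_mag[:, None] * n_hat
            vt_vec = v_rel - vn_vec

            s_n = C.normal_stiffness(ov, e_star, r_star)
            s_t = C.tangential_stiffness(ov, g_star, r_star)
            f_damp = C.normal_damping_force(beta, s_n, m_star, vn_vec)
            f_damp = _clamp_impulse(f_damp, m_star, vn_vec, dt)
            dt_vec = dt_vec + vt_vec * dt
            dt_vec -= np.einsum("ij,ij->i", dt_vec, n_hat)[:, None] * n_hat
            f_t, dt_vec = C.tangential_force(s_t, dt_vec, beta, m_star, vt_vec,
                                             mu_s, np.abs(f_rep))

            f_all = f_rep[:, None] * n_hat + f_damp + f_t
            # reaction on the wall (for torque/force instrumentation)
            pivot = wall.kin.axis_point + wall.kin.offset
            self.wall_reaction_force[w_idx] = -f_all.sum(axis=0)
            self.wall_reaction_torque[w_idx] = np.cross(
                contact_w - pivot, -f_all).sum(axis=0)
            np.add.at(force, p_i, f_all)
            np.add.at(torque, p_i, np.cross(r_ci, f_t))
            t_roll = C.rolling_torque(mu_r, np.abs(f_rep), s.radius[p_i],
                                      s.omega[p_i])
            cap = s.inertia[p_i] * np.linalg.norm(s.omega[p_i], axis=1) / dt
            mag = np.linalg.norm(t_roll, axis=1)
            scale = np.where(mag > cap, cap / np.maximum(mag, 1e-300), 1.0)
            np.add.at(torque, p_i, t_roll * scale[:, None])

            new_keys.append(keys)
            new_dt.append(dt_vec)
            new_a.append(a_new)

    def wall_load(self, wall_index: int) -> tuple[np.ndarray, np.ndarray]:
        """Net particle reaction force and torque (about the wall pivot)
        accumulated on one wall during the most recent step."""
        return (self.wall_reaction_force[wall_index].copy(),
                self.wall_reaction_torque[wall_index].copy())
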