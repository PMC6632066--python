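"""Scalar contact-force kernels, JIT-compiled when numba is available.

These loops implement exactly the same physics as the vectorised numpy
path in :mod:`blendsim.dem.engine` (Hertz-Mindlin normal/tangential
forces with restitution-tied damping, impulse-clamped, Coulomb-capped
tangential springs, clamped rolling resistance and JKR cohesion) —
``tests/test_engine.py`` asserts the two paths agree.  Pure-python
execution works but is slow; numba provides the speed.
"""

from __future__ import annotations

import math

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


_DAMP = 2.0 * math.sqrt(5.0 / 6.0)


@njit(cache=False)
def pp_forces(pos, vel, omega, radius, mass, inertia,
              pi, pj, e_star, g_star, beta, mu_s, mu_r, gamma,
              state_dt, state_a, dt, force, torque, active):
    """Accumulate particle-particle contact forces and torques.

    ``state_dt``/``state_a`` are the per-pair tangential springs and JKR
    contact radii aligned with the pair list; updated in place.
    ``active`` is filled with contact flags for state persistence.
    """
    n_pairs = pi.shape[0]
    for k in range(n_pairs):
        a_i = pi[k]
        b_i = pj[k]
        dx = pos[b_i, 0] - pos[a_i, 0]
        dy = pos[b_i, 1] - pos[a_i, 1]
        dz = pos[b_i, 2] - pos[a_i, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d < 1e-12:
            d = 1e-12
        ri = radius[a_i]
        rj = radius[b_i]
        overlap = ri + rj - d
        g = gamma[k]
        es = e_star[k]
        r_star = ri * rj / (ri + rj)

        a_new = 0.0
        if g > 0.0:
            # displacement-control detachment overlap
            a_c = (r_star * r_star * math.pi * g / (4.0 * es)) ** (1.0 / 3.0)
            dn_c = a_c * a_c / r_star - math.sqrt(4.0 * math.pi * g * a_c / es)
            if overlap <= dn_c:
                active[k] = False
                state_dt[k, 0] = 0.0
                state_dt[k, 1] = 0.0
                state_dt[k, 2] = 0.0
                state_a[k] = 0.0
                continue
            # Newton solve for the stable-branch contact radius
            a_sol = math.sqrt(r_star * overlap) if overlap > 0.0 else 0.0
            if a_sol < 1.5 * a_c:
                a_sol = 1.5 * a_c
            if state_a[k] > a_c:
                a_sol = state_a[k]
            c = math.sqrt(4.0 * math.pi * g / es)
            for _ in range(25):
                f_val = a_sol * a_sol / r_star - c * math.sqrt(a_sol) - overlap
                df = 2.0 * a_sol / r_star - 0.5 * c / math.sqrt(max(a_sol, 1e-300))
                a_sol = a_sol - f_val / df
                if a_sol < a_c:
                    a_sol = a_c
            a_new = a_sol
            f_rep = (-4.0 * math.sqrt(math.pi * g * es) * a_sol ** 1.5
                     + (4.0 * es / (3.0 * r_star)) * a_sol ** 3)
        else:
            if overlap <= 0.0:
                active[k] = False
                state_dt[k, 0] = 0.0
                state_dt[k, 1] = 0.0
                state_dt[k, 2] = 0.0
                state_a[k] = 0.0
                continue
            f_rep = (4.0 / 3.0) * es * math.sqrt(r_star) * overlap ** 1.5

        active[k] = True
        state_a[k] = a_new
        nx = dx / d
        ny = dy / d
        nz = dz / d
        m_star = mass[a_i] * mass[b_i] / (mass[a_i] + mass[b_i])
        ov_pos = overlap if overlap > 0.0 else 0.0
        s_n = 2.0 * es * math.sqrt(r_star * ov_pos)
        s_t = 8.0 * g_star[k] * math.sqrt(r_star * ov_pos)

        # relative velocity at contact (i relative to j)
        rcx = ri * nx
        rcy = ri * ny
        rcz = ri * nz
        vx = (vel[a_i, 0] + omega[a_i, 1] * rcz - omega[a_i, 2] * rcy
              - vel[b_i, 0] + omega[b_i, 1] * rj * nz - omega[b_i, 2] * rj * ny)
        vy = (vel[a_i, 1] + omega[a_i, 2] * rcx - omega[a_i, 0] * rcz
              - vel[b_i, 1] + omega[b_i, 2] * rj * nx - omega[b_i, 0] * rj * nz)
        vz = (vel[a_i, 2] + omega[a_i, 0] * rcy - omega[a_i, 1] * rcx
              - vel[b_i, 2] + omega[b_i, 0] * rj * ny - omega[b_i, 1] * rj * nx)
        vn = vx * nx + vy * ny + vz * nz
        vtx = vx - vn * nx
        vty = vy - vn * ny
        vtz = vz - vn * nz

        # normal damping with the per-step impulse clamp
        coeff = _DAMP * beta[k] * math.sqrt(s_n * m_star)
        fdx = -coeff * vn * nx
        fdy = -coeff * vn * ny
        fdz = -coeff * vn * nz
        fd_mag = math.sqrt(fdx * fdx + fdy * fdy + fdz * fdz)
        cap = m_star * abs(vn) / dt
        if fd_mag > cap and fd_mag > 0.0:
            sc = cap / fd_mag
            fdx *= sc
            fdy *= sc
            fdz *= sc

        # tangential spring: accumulate, project, spring + damping, cap
        tx = state_dt[k, 0] + vtx * dt
        ty = state_dt[k, 1] + vty * dt
        tz = state_dt[k, 2] + vtz * dt
        tn = tx * nx + ty * ny + tz * nz
        tx -= tn * nx
        ty -= tn * ny
        tz -= tn * nz
        coeff_t = _DAMP * beta[k] * math.sqrt(s_t * m_star)
        ftx = -s_t * tx - coeff_t * vtx
        fty = -s_t * ty - coeff_t * vty
        ftz = -s_t * tz - coeff_t * vtz
        ft_mag = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
        limit = mu_s[k] * abs(f_rep)
        if ft_mag > limit:
            sc = limit / ft_mag if ft_mag > 0.0 else 0.0
            ftx *= sc
            fty *= sc
            ftz *= sc
            if s_t > 0.0:
                tx = -ftx / s_t
                ty = -fty / s_t
                tz = -ftz / s_t
            else:
                tx = 0.0
                ty = 0.0
                tz = 0.0
        state_dt[k, 0] = tx
        state_dt[k, 1] = ty
        state_dt[k, 2] = tz

        fx = -f_rep * nx + fdx + ftx
        fy = -f_rep * ny + fdy + fty
        fz = -f_rep * nz + fdz + ftz
        force[a_i, 0] += fx
        force[a_i, 1] += fy
        force[a_i, 2] += fz
        force[b_i, 0] -= fx
        force[b_i, 1] -= fy
        force[b_i, 2] -= fz
        # torque from tangential force: r_c x F_t
        torque[a_i, 0] += rcy * ftz - rcz * fty
        torque[a_i, 1] += rcz * ftx - rcx * ftz
        torque[a_i, 2] += rcx * fty - rcy * ftx
        torque[b_i, 0] += (-rj * ny) * (-ftz) - (-rj * nz) * (-fty)
        torque[b_i, 1] += (-rj * nz) * (-ftx) - (-rj * nx) * (-ftz)
        torque[b_i, 2] += (-rj * nx) * (-fty) - (-rj * ny) * (-ftx)

        # rolling resistance on both particles, clamped per step
        fr = abs(f_rep)
        for (p_idx, rp) in ((a_i, ri), (b_i, rj)):
            wx = omega[p_idx, 0]
            wy = omega[p_idx, 1]
            wz = omega[p_idx, 2]
            w_mag = math.sqrt(wx * wx + wy * wy + wz * wz)
            if w_mag > 0.0:
                t_mag = mu_r[k] * fr * rp
                cap_r = inertia[p_idx] * w_mag / dt
                if t_mag > cap_r:
                    t_mag = cap_r
                torque[p_idx, 0] -= t_mag * wx / w_mag
                torque[p_idx, 1] -= t_mag * wy / w_mag
                torque[p_idx, 2] -= t_mag * wz / w_mag


@njit(cache=False)
def closest_points(tri, pts, out):
    """Scalar closest-point-on-triangle for each (triangle, point) row."""
    for k in range(pts.shape[0]):
        ax = tri[k, 0, 0]
        ay = tri[k, 0, 1]
        az = tri[k, 0, 2]
        bx = tri[k, 1, 0]
        by = tri[k, 1, 1]
        bz = tri[k, 1, 2]
        cx = tri[k, 2, 0]
        cy = tri[k, 2, 1]
        cz = tri[k, 2, 2]
        px = pts[k, 0]
        py = pts[k, 1]
        pz = pts[k, 2]
        abx = bx - ax
        aby = by - ay
        abz = bz - az
        acx = cx - ax
        acy = cy - ay
        acz = cz - az
        apx = px - ax
        apy = py - ay
        apz = pz - az
        d1 = abx * apx + aby * apy + abz * apz
        d2 = acx * apx + acy * apy + acz * apz
        if d1 <= 0.0 and d2 <= 0.0:
            out[k, 0] = ax
            out[k, 1] = ay
            out[k, 2] = az
            continue
        bpx = px - bx
        bpy = py - by
        bpz = pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            out[k, 0] = bx
            out[k, 1] = by
            out[k, 2] = bz
            continue
        vc = d1 * d4 - d3 * d2
        if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
            v = d1 / (d1 - d3)
            out[k, 0] = ax + v * abx
            out[k, 1] = ay + v * aby
            out[k, 2] = az + v * abz
            continue
        cpx = px - cx
        cpy = py - cy
        cpz = pz - cz
        d5 = abx * cpx + aby * cpy + abz * cpz
        d6 = acx * cpx + acy * cpy + acz * cpz
        if d6 >= 0.0 and d5 <= d6:
            out[k, 0] = cx
            out[k, 1] = cy
            out[k, 2] = cz
            continue
        vb = d5 * d2 - d1 * d6
        if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
            w = d2 / (d2 - d6)
            out[k, 0] = ax + w * acx
            out[k, 1] = ay + w * acy
            out[k, 2] = az + w * acz
            continue
        va = d3 * d6 - d5 * d4
        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
            out[k, 0] = bx + w * (cx - bx)
            out[k, 1] = by + w * (cy - by)
            out[k, 2] = bz + w * (cz - bz)
            continue
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        out[k, 0] = ax + v * abx + w * acx
        out[k, 1] = ay + v * aby + w * acy
        out[k, 2] = az + v * abz + w * acz


@njit(cache=False)
def pw_forces(pos, vel, omega, radius, mass, inertia,
              p_idx, n_hat, overlap, contact, wall_v,
              e_star, g_star, beta, mu_s, mu_r, gamma,
              state_dt, state_a, dt, force, torque, reaction_f, reaction_t,
              pivot):
    """Particle-wall contact forces for deduplicated contacts.

    ``n_hat`` points from the wall surface toward the particle centre;
    ``wall_v`` is the wall surface velocity at the contact point.  Also
    accumulates the reaction force/torque (about ``pivot``) on the wall.
    """
    n_c = p_idx.shape[0]
    for k in range(n_c):
        i = p_idx[k]
        ov = overlap[k]
        g = gamma[k]
        es = e_star[k]
        r_star = radius[i]
        a_new = 0.0
        if g > 0.0:
            a_c = (r_star * r_star * math.pi * g / (4.0 * es)) ** (1.0 / 3.0)
            c = math.sqrt(4.0 * math.pi * g / es)
            a_sol = math.sqrt(r_star * ov) if ov > 0.0 else 0.0
            if a_sol < 1.5 * a_c:
                a_sol = 1.5 * a_c
            if state_a[k] > a_c:
                a_sol = state_a[k]
            for _ in range(25):
                f_val = a_sol * a_sol / r_star - c * math.sqrt(a_sol) - ov
                df = 2.0 * a_sol / r_star - 0.5 * c / math.sqrt(max(a_sol, 1e-300))
                a_sol = a_sol - f_val / df
                if a_sol < a_c:
                    a_sol = a_c
            a_new = a_sol
            f_rep = (-4.0 * math.sqrt(math.pi * g * es) * a_sol ** 1.5
                     + (4.0 * es / (3.0 * r_star)) * a_sol ** 3)
        else:
            f_rep = (4.0 / 3.0) * es * math.sqrt(r_star) * ov ** 1.5
        state_a[k] = a_new

        nx = n_hat[k, 0]
        ny = n_hat[k, 1]
        nz = n_hat[k, 2]
        m_star = mass[i]
        ov_pos = ov if ov > 0.0 else 0.0
        s_n = 2.0 * es * math.sqrt(r_star * ov_pos)
        s_t = 8.0 * g_star[k] * math.sqrt(r_star * ov_pos)

        rcx = contact[k, 0] - pos[i, 0]
        rcy = contact[k, 1] - pos[i, 1]
        rcz = contact[k, 2] - pos[i, 2]
        vx = (vel[i, 0] + omega[i, 1] * rcz - omega[i, 2] * rcy - wall_v[k, 0])
        vy = (vel[i, 1] + omega[i, 2] * rcx - omega[i, 0] * rcz - wall_v[k, 1])
        vz = (vel[i, 2] + omega[i, 0] * rcy - omega[i, 1] * rcx - wall_v[k, 2])
        vn = vx * nx + vy * ny + vz * nz
        vtx = vx - vn * nx
        vty = vy - vn * ny
        vtz = vz - vn * nz

        coeff = _DAMP * beta[k] * math.sqrt(s_n * m_star)
        fdx = -coeff * vn * nx
        fdy = -coeff * vn * ny
        fdz = -coeff * vn * nz
        fd_mag = math.sqrt(fdx * fdx + fdy * fdy + fdz * fdz)
        cap = m_star * abs(vn) / dt
        if fd_mag > cap and fd_mag > 0.0:
            sc = cap / fd_mag
            fdx *= sc
            fdy *= sc
            fdz *= sc

        tx = state_dt[k, 0] + vtx * dt
        ty = state_dt[k, 1] + vty * dt
        tz = state_dt[k, 2] + vtz * dt
        tn = tx * nx + ty * ny + tz * nz
        tx -= tn * nx
        ty -= tn * ny
        tz -= tn * nz
        coeff_t = _DAMP * beta[k] * math.sqrt(s_t * m_star)
        ftx = -s_t * tx - coeff_t * vtx
        fty = -s_t * ty - coeff_t * vty
        ftz = -s_t * tz - coeff_t * vtz
        ft_mag = math.sqrt(ftx * ftx + fty * fty + ftz * ftz)
        limit = mu_s[k] * abs(f_rep)
        if ft_mag > limit:
            sc = limit / ft_mag if ft_mag > 0.0 else 0.0
            ftx *= sc
            fty *= sc
            ftz *= sc
            if s_t > 0.0:
                tx = -ftx / s_t
                ty = -fty / s_t
                tz = -ftz / s_t
            else:
                tx = 0.0
                ty = 0.0
                tz = 0.0
        state_dt[k, 0] = tx
        state_dt[k, 1] = ty
        state_dt[k, 2] = tz

        fx = f_rep * nx + fdx + ftx
        fy = f_rep * ny + fdy + fty
        fz = f_rep * nz + fdz + ftz
        force[i, 0] += fx
        force[i, 1] += fy
        force[i, 2] += fz
        torque[i, 0] += rcy * ftz - rcz * fty
        torque[i, 1] += rcz * ftx - rcx * ftz
        torque[i, 2] += rcx * fty - rcy * ftx

        # wall reaction (for rheometer instrumentation)
        reaction_f[0] -= fx
        reaction_f[1] -= fy
        reaction_f[2] -= fz
        gx = contact[k, 0] - pivot[0]
        gy = contact[k, 1] - pivot[1]
        gz = contact[k, 2] - pivot[2]
        reaction_t[0] += gy * (-fz) - gz * (-fy)
        reaction_t[1] += gz * (-fx) - gx * (-fz)
        reaction_t[2] += gx * (-fy) - gy * (-fx)

        wx = omega[i, 0]
        wy = omega[i, 1]
        wz = omega[i, 2]
        w_mag = math.sqrt(wx * wx + wy * wy + wz * wz)
        if w_mag > 0.0:
            t_mag = mu_r[k] * abs(f_rep) * radius[i]
            cap_r = inertia[i] * w_mag / dt
            if t_mag > cap_r:
                t_mag = cap_r
            torque[i, 0] -= t_mag * wx / w_mag
            torque[i, 1] -= t_mag * wy / w_mag
            torque[i, 2] -= t_mag * wz / w_mag
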