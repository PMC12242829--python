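"""Compiled force/energy kernels (numba).

These operate on flattened index arrays prepared by the owning modules; all
analytic gradients here are exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["vm_eval", "fiber_eval", "min_edge_scan"]


@njit(cache=True, fastmath=True)
def vm_eval(pos, f_off, f_idx, f_tension,
            c_f_off, c_f_face, c_f_orient,
            KV, KA, V0, A0,
            want_forces, forces, cellV, cellA):
    """Vertex-model energy terms and (optionally) forces.

    Faces are fan-triangulated from their vertex-mean centroid; the centroid
    is a dependent point, so its gradient is redistributed equally over the
    face's vertices (chain rule).  ``f_tension[f]`` is the interfacial tension
    coefficient of face ``f`` (Gamma for interface faces, 0 otherwise).
    Returns (volume_term, area_term, tension_term).
    """
    nf = f_off.shape[0] - 1
    nc = c_f_off.shape[0] - 1
    areas = np.zeros(nf)
    vols = np.zeros(nf)
    cents = np.zeros((nf, 3))
    # pass 1: per-face geometry
    for f in range(nf):
        a, b = f_off[f], f_off[f + 1]
        n = b - a
        cx = 0.0
        cy = 0.0
        cz = 0.0
        for k in range(a, b):
            v = f_idx[k]
            cx += pos[v, 0]
            cy += pos[v, 1]
            cz += pos[v, 2]
        cx /= n
        cy /= n
        cz /= n
        cents[f, 0] = cx
        cents[f, 1] = cy
        cents[f, 2] = cz
        A = 0.0
        Vol = 0.0
        for k in range(n):
            i1 = f_idx[a + k]
            i2 = f_idx[a + (k + 1) % n]
            ux = pos[i1, 0] - cx
            uy = pos[i1, 1] - cy
            uz = pos[i1, 2] - cz
            vx = pos[i2, 0] - cx
            vy = pos[i2, 1] - cy
            vz = pos[i2, 2] - cz
            wx = uy * vz - uz * vy
            wy = uz * vx - ux * vz
            wz = ux * vy - uy * vx
            A += 0.5 * np.sqrt(wx * wx + wy * wy + wz * wz)
            # det[c, p1, p2] / 6
            p1x = pos[i1, 0]
            p1y = pos[i1, 1]
            p1z = pos[i1, 2]
            p2x = pos[i2, 0]
            p2y = pos[i2, 1]
            p2z = pos[i2, 2]
            Vol += (cx * (p1y * p2z - p1z * p2y)
                    + cy * (p1z * p2x - p1x * p2z)
                    + cz * (p1x * p2y - p1y * p2x)) / 6.0
        areas[f] = A
        vols[f] = Vol
    # per-cell sums and face coefficients
    E_vol = 0.0
    E_area = 0.0
    E_tens = 0.0
    coefA = np.zeros(nf)
    coefV = np.zeros(nf)
    for c in range(nc):
        Vj = 0.0
        Aj = 0.0
        for k in range(c_f_off[c], c_f_off[c + 1]):
            f = c_f_face[k]
            Vj += c_f_orient[k] * vols[f]
            Aj += areas[f]
        cellV[c] = Vj
        cellA[c] = Aj
        E_vol += KV * (Vj - V0) ** 2
        E_area += KA * (Aj - A0) ** 2
        if want_forces:
            for k in range(c_f_off[c], c_f_off[c + 1]):
                f = c_f_face[k]
                coefV[f] += 2.0 * KV * (Vj - V0) * c_f_orient[k]
                coefA[f] += 2.0 * KA * (Aj - A0)
    for f in range(nf):
        E_tens += f_tension[f] * areas[f]
        coefA[f] += f_tension[f]
    if not want_forces:
        return E_vol, E_area, E_tens
    # pass 2: gradients (force = -dE/dr)
    for f in range(nf):
        a, b = f_off[f], f_off[f + 1]
        n = b - a
        cA = coefA[f]
        cV = coefV[f]
        if cA == 0.0 and cV == 0.0:
            continue
        cx = cents[f, 0]
        cy = cents[f, 1]
        cz = cents[f, 2]
        gcx = 0.0
        gcy = 0.0
        gcz = 0.0
        for k in range(n):
            i1 = f_idx[a + k]
            i2 = f_idx[a + (k + 1) % n]
            p1x = pos[i1, 0]
            p1y = pos[i1, 1]
            p1z = pos[i1, 2]
            p2x = pos[i2, 0]
            p2y = pos[i2, 1]
            p2z = pos[i2, 2]
            ux = p1x - cx
            uy = p1y - cy
            uz = p1z - cz
            vx = p2x - cx
            vy = p2y - cy
            vz = p2z - cz
            wx = uy * vz - uz * vy
            wy = uz * vx - ux * vz
            wz = ux * vy - uy * vx
            nw = np.sqrt(wx * wx + wy * wy + wz * wz)
            if nw > 1e-14 and cA != 0.0:
                hx = wx / nw
                hy = wy / nw
                hz = wz / nw
                # dA/dp1 = 0.5 (v x w_hat), dA/dp2 = 0.5 (w_hat x u)
                g1x = 0.5 * (vy * hz - vz * hy)
                g1y = 0.5 * (vz * hx - vx * hz)
                g1z = 0.5 * (vx * hy - vy * hx)
                g2x = 0.5 * (hy * uz - hz * uy)
                g2y = 0.5 * (hz * ux - hx * uz)
                g2z = 0.5 * (hx * uy - hy * ux)
                forces[i1, 0] -= cA * g1x
                forces[i1, 1] -= cA * g1y
                forces[i1, 2] -= cA * g1z
                forces[i2, 0] -= cA * g2x
                forces[i2, 1] -= cA * g2y
                forces[i2, 2] -= cA * g2z
                gcx += cA * (-(g1x + g2x))
                gcy += cA * (-(g1y + g2y))
                gcz += cA * (-(g1z + g2z))
            if cV != 0.0:
                # d vol / dp1 = (p2 x c)/6, dp2 = (c x p1)/6, dc = (p1 x p2)/6
                forces[i1, 0] -= cV * (p2y * cz - p2z * cy) / 6.0
                forces[i1, 1] -= cV * (p2z * cx - p2x * cz) / 6.0
                forces[i1, 2] -= cV * (p2x * cy - p2y * cx) / 6.0
                forces[i2, 0] -= cV * (cy * p1z - cz * p1y) / 6.0
                forces[i2, 1] -= cV * (cz * p1x - cx * p1z) / 6.0
                forces[i2, 2] -= cV * (cx * p1y - cy * p1x) / 6.0
                gcx += cV * (p1y * p2z - p1z * p2y) / 6.0
                gcy += cV * (p1z * p2x - p1x * p2z) / 6.0
                gcz += cV * (p1x * p2y - p1y * p2x) / 6.0
        sx = gcx / n
        sy = gcy / n
        sz = gcz / n
        for k in range(a, b):
            v = f_idx[k]
            forces[v, 0] -= sx
            forces[v, 1] -= sy
            forces[v, 2] -= sz
    return E_vol, E_area, E_tens


@njit(cache=True, fastmath=True)
def fiber_eval(pos, bi, bj, l0, KS, ti, tj, tk, KB, want_forces, forces):
    """Fiber stretching + collinear bending energy and forces.

    Bonds are Hookean in length; bending triples penalize the deviation of the
    angle at the shared phantom node from pi.  Returns
    (stretch_term, bend_term, status) with status 1 on a degenerate
    (zero-length) bond.
    """
    E_s = 0.0
    status = 0
    for n in range(bi.shape[0]):
        a = bi[n]
        b = bj[n]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        if l < 1e-12:
            status = 1
            continue
        dl = l - l0[n]
        E_s += 0.5 * KS * dl * dl
        if want_forces:
            fm = KS * dl / l
            forces[a, 0] += fm * dx
            forces[a, 1] += fm * dy
            forces[a, 2] += fm * dz
            forces[b, 0] -= fm * dx
            forces[b, 1] -= fm * dy
            forces[b, 2] -= fm * dz
    E_b = 0.0
    for n in range(ti.shape[0]):
        i = ti[n]
        j = tj[n]
        k = tk[n]
        ux = pos[i, 0] - pos[j, 0]
        uy = pos[i, 1] - pos[j, 1]
        uz = pos[i, 2] - pos[j, 2]
        vx = pos[k, 0] - pos[j, 0]
        vy = pos[k, 1] - pos[j, 1]
        vz = pos[k, 2] - pos[j, 2]
        lu = np.sqrt(ux * ux + uy * uy + uz * uz)
        lv = np.sqrt(vx * vx + vy * vy + vz * vz)
        if lu < 1e-12 or lv < 1e-12:
            status = 1
            continue
        ct = (ux * vx + uy * vy + uz * vz) / (lu * lv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        # theta - pi = -arcsin(sin theta) for theta > pi/2; the series is
        # cheaper than arccos and exact to ~1e-9 for angles within 20 deg of pi
        s2 = 1.0 - ct * ct
        if ct < -0.93:
            ss = np.sqrt(s2)
            d = -ss * (1.0 + s2 * (1.0 / 6.0 + s2 * (3.0 / 40.0
                       + s2 * (15.0 / 336.0 + s2 * (105.0 / 3456.0)))))
        else:
            d = np.arccos(ct) - np.pi
        E_b += 0.5 * KB * d * d
        if want_forces:
            st = np.sqrt(s2)
            if st < 1e-8:
                fac = -KB  # limit of (theta - pi)/sin(theta) as theta -> pi
            else:
                fac = KB * d / st
            # F_i = fac * (v_hat - ct*u_hat)/lu ; F_k symmetric; F_j = -(F_i+F_k)
            fix = fac * (vx / lv - ct * ux / lu) / lu
            fiy = fac * (vy / lv - ct * uy / lu) / lu
            fiz = fac * (vz / lv - ct * uz / lu) / lu
            fkx = fac * (ux / lu - ct * vx / lv) / lv
            fky = fac * (uy / lu - ct * vy / lv) / lv
            fkz = fac * (uz / lu - ct * vz / lv) / lv
            forces[i, 0] += fix
            forces[i, 1] += fiy
            forces[i, 2] += fiz
            forces[k, 0] += fkx
            forces[k, 1] += fky
            forces[k, 2] += fkz
            forces[j, 0] -= fix + fkx
            forces[j, 1] -= fiy + fky
            forces[j, 2] -= fiz + fkz
    return E_s, E_b, status


@njit(cache=True)
def min_edge_scan(pos, e1, e2, threshold, out_flags):
    """Flag edges shorter than threshold; returns the number flagged."""
    n = 0
    for k in range(e1.shape[0]):
        a = e1[k]
        b = e2[k]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        if dx * dx + dy * dy + dz * dz < threshold * threshold:
            out_flags[k] = True
            n += 1
        else:
            out_flags[k] = False
    return n


@njit(cache=True, fastmath=True)
def advance_block(pos_c, pos_f,
                  f_off, f_idx, f_tension, c_f_off, c_f_face, c_f_orient,
                  KV, KA, V0, A0,
                  bi, bj, bl0, KS, ti, tj, tk, KB,
                  lk_node, lk_rest, lk_fv_idx, lk_fv_off, K_LS,
                  mobile, free_nodes,
                  noise, mu_dt, muf_dt, sigma,
                  t0, dt, sched_ton, sched_l0, sched_l1, sched_interval,
                  cell_F, fib_F, cellV, cellA):
    """Advance ``noise.shape[0]`` coupled time steps (no topology changes).

    Cell vertices: Euler-Maruyama with pre-drawn unit normals in ``noise``
    (one row per mobile vertex).  Fiber nodes: plain Euler on the free set.
    Linker rest lengths follow the monotone contraction schedule in place.
    """
    nsteps = noise.shape[0]
    t = t0
    n_lk = lk_node.shape[0]
    for s in range(nsteps):
        cell_F[:] = 0.0
        fib_F[:] = 0.0
        vm_eval(pos_c, f_off, f_idx, f_tension, c_f_off, c_f_face, c_f_orient,
                KV, KA, V0, A0, True, cell_F, cellV, cellA)
        fiber_eval(pos_f, bi, bj, bl0, KS, ti, tj, tk, KB, True, fib_F)
        # linker schedule (monotone: never revisit longer rest lengths)
        if t <= sched_ton:
            r_now = sched_l0
        else:
            frac = (t - sched_ton) / sched_interval
            if frac >= 1.0:
                r_now = sched_l1
            else:
                r_now = sched_l0 + frac * (sched_l1 - sched_l0)
        for i in range(n_lk):
            if lk_rest[i] > r_now:
                lk_rest[i] = r_now
            a, b = lk_fv_off[i], lk_fv_off[i + 1]
            nv = b - a
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for k in range(a, b):
                v = lk_fv_idx[k]
                cx += pos_c[v, 0]
                cy += pos_c[v, 1]
                cz += pos_c[v, 2]
            cx /= nv
            cy /= nv
            cz /= nv
            node = lk_node[i]
            dx = pos_f[node, 0] - cx
            dy = pos_f[node, 1] - cy
            dz = pos_f[node, 2] - cz
            l = np.sqrt(dx * dx + dy * dy + dz * dz)
            if l < 1e-12:
                continue
            coef = -K_LS * (l - lk_rest[i]) / l
            fib_F[node, 0] += coef * dx
            fib_F[node, 1] += coef * dy
            fib_F[node, 2] += coef * dz
            back = -coef / nv
            for k in range(a, b):
                v = lk_fv_idx[k]
                cell_F[v, 0] += back * dx
                cell_F[v, 1] += back * dy
                cell_F[v, 2] += back * dz
        # integrate
        for k in range(mobile.shape[0]):
            v = mobile[k]
            pos_c[v, 0] += mu_dt * cell_F[v, 0] + sigma * noise[s, k, 0]
            pos_c[v, 1] += mu_dt * cell_F[v, 1] + sigma * noise[s, k, 1]
            pos_c[v, 2] += mu_dt * cell_F[v, 2] + sigma * noise[s, k, 2]
        for k in range(free_nodes.shape[0]):
            v = free_nodes[k]
            pos_f[v, 0] += muf_dt * fib_F[v, 0]
            pos_f[v, 1] += muf_dt * fib_F[v, 1]
            pos_f[v, 2] += muf_dt * fib_F[v, 2]
        t += dt
    return t
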