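"""Numba kernels: exact voxel ray traversal, EPL dose, stochastic transport.

These are the numerical hot paths behind the two dose engines.  All geometry
is in world mm; densities are water-equivalent rho_w on a regular grid whose
voxel (i, j, k) center sits at origin + index * spacing (voxel faces at
half-integer indices).  Outside the grid rho_w = 0.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_EPS = 1e-9


@njit(cache=True)
def raysum(vals, sp, org, ax, ay, az, bx, by, bz):
    """Exact line integral of the voxel field along segment a->b (value*mm).

    Amanatides-Woo traversal over piecewise-constant voxels; segments
    outside the grid contribute zero.  Additive over concatenated segments.
    """
    nx, ny, nz = vals.shape
    dx, dy, dz = bx - ax, by - ay, bz - az
    L = math.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= 0.0:
        return 0.0
    ux, uy, uz = dx / L, dy / L, dz / L

    lox = org[0] - 0.5 * sp[0]
    loy = org[1] - 0.5 * sp[1]
    loz = org[2] - 0.5 * sp[2]
    hix = lox + nx * sp[0]
    hiy = loy + ny * sp[1]
    hiz = loz + nz * sp[2]

    tmin, tmax = 0.0, L
    # slab clipping per axis
    for axis in range(3):
        if axis == 0:
            u, a, lo, hi = ux, ax, lox, hix
        elif axis == 1:
            u, a, lo, hi = uy, ay, loy, hiy
        else:
            u, a, lo, hi = uz, az, loz, hiz
        if abs(u) < _EPS:
            if a < lo or a > hi:
                return 0.0
        else:
            t1 = (lo - a) / u
            t2 = (hi - a) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax - tmin <= _EPS:
        return 0.0

    t = tmin
    px = ax + (t + 1e-7) * ux
    py = ay + (t + 1e-7) * uy
    pz = az + (t + 1e-7) * uz
    i = int(math.floor((px - lox) / sp[0]))
    j = int(math.floor((py - loy) / sp[1]))
    k = int(math.floor((pz - loz) / sp[2]))
    if i < 0:
        i = 0
    if i > nx - 1:
        i = nx - 1
    if j < 0:
        j = 0
    if j > ny - 1:
        j = ny - 1
    if k < 0:
        k = 0
    if k > nz - 1:
        k = nz - 1

    if ux > 0:
        stepi, tnx, tdx = 1, ((i + 1) * sp[0] + lox - ax) / ux, sp[0] / ux
    elif ux < 0:
        stepi, tnx, tdx = -1, (i * sp[0] + lox - ax) / ux, -sp[0] / ux
    else:
        stepi, tnx, tdx = 0, math.inf, math.inf
    if uy > 0:
        stepj, tny, tdy = 1, ((j + 1) * sp[1] + loy - ay) / uy, sp[1] / uy
    elif uy < 0:
        stepj, tny, tdy = -1, (j * sp[1] + loy - ay) / uy, -sp[1] / uy
    else:
        stepj, tny, tdy = 0, math.inf, math.inf
    if uz > 0:
        stepk, tnz, tdz = 1, ((k + 1) * sp[2] + loz - az) / uz, sp[2] / uz
    elif uz < 0:
        stepk, tnz, tdz = -1, (k * sp[2] + loz - az) / uz, -sp[2] / uz
    else:
        stepk, tnz, tdz = 0, math.inf, math.inf

    total = 0.0
    while t < tmax - _EPS:
        tnext = tnx
        axis = 0
        if tny < tnext:
            tnext = tny
            axis = 1
        if tnz < tnext:
            tnext = tnz
            axis = 2
        if tnext > tmax:
            tnext = tmax
            axis = -1
        total += vals[i, j, k] * (tnext - t)
        t = tnext
        if axis == 0:
            i += stepi
            tnx += tdx
            if i < 0 or i >= nx:
                break
        elif axis == 1:
            j += stepj
            tny += tdy
            if j < 0 or j >= ny:
                break
        elif axis == 2:
            k += stepk
            tnz += tdz
            if k < 0 or k >= nz:
                break
        else:
            break
    return total


@njit(cache=True)
def _scatter_capture(diameter, p_sc, sig_sc):
    """Fraction of kernel energy captured inside a circular field."""
    r = 0.5 * diameter
    return (1.0 - p_sc) + p_sc * (1.0 - math.exp(-r * r / (2.0 * sig_sc * sig_sc)))


@njit(cache=True)
def _pdd(deff, beta, mu_w, fmax):
    return (1.0 - math.exp(-beta * deff)) * math.exp(-mu_w * deff) / fmax


@njit(cache=True)
def epl_dose_full(
    vals, sp, org, srcs, tgts, dias, mus,
    beta, mu_w, pen, cal, p_sc, sig_sc, ref_dia, out,
):
    """Accumulate EPL dose for all beams on the full grid."""
    nx, ny, nz = vals.shape
    dmax = math.log((beta + mu_w) / mu_w) / beta
    fmax = (1.0 - math.exp(-beta * dmax)) * math.exp(-mu_w * dmax)
    sf_ref = _scatter_capture(ref_dia, p_sc, sig_sc)
    sig_iso = pen / 1.683

    for b in range(srcs.shape[0]):
        if mus[b] <= 0.0:
            continue
        sx0, sy0, sz0 = srcs[b, 0], srcs[b, 1], srcs[b, 2]
        dxb = tgts[b, 0] - sx0
        dyb = tgts[b, 1] - sy0
        dzb = tgts[b, 2] - sz0
        sadb = math.sqrt(dxb * dxb + dyb * dyb + dzb * dzb)
        ux, uy, uz = dxb / sadb, dyb / sadb, dzb / sadb
        sfb = _scatter_capture(dias[b], p_sc, sig_sc) / sf_ref
        R = 0.5 * dias[b]
        w = mus[b] * cal * sfb
        for i in range(nx):
            vx = org[0] + i * sp[0]
            for j in range(ny):
                vy = org[1] + j * sp[1]
                for k in range(nz):
                    vz = org[2] + k * sp[2]
                    wx, wy, wz = vx - sx0, vy - sy0, vz - sz0
                    zb = wx * ux + wy * uy + wz * uz
                    if zb < 1.0:
                        continue
                    rx = wx - zb * ux
                    ry = wy - zb * uy
                    rz = wz - zb * uz
                    r = math.sqrt(rx * rx + ry * ry + rz * rz)
                    zf = zb / sadb
                    Rp = R * zf
                    sigp = sig_iso * zf
                    if r > Rp + 5.0 * sigp + 2.0:
                        continue
                    deff = raysum(vals, sp, org, sx0, sy0, sz0, vx, vy, vz)
                    oar = 0.5 * math.erfc((r - Rp) / (1.4142135623730951 * sigp))
                    out[i, j, k] += (
                        w * (sadb / zb) ** 2 * _pdd(deff, beta, mu_w, fmax) * oar
                    )


@njit(cache=True)
def epl_dose_points(
    vals, sp, org, srcs, tgts, dias, mus,
    beta, mu_w, pen, cal, p_sc, sig_sc, ref_dia, idx, out,
):
    """Per-beam EPL dose at listed voxels; out has shape (n_points, n_beams)."""
    dmax = math.log((beta + mu_w) / mu_w) / beta
    fmax = (1.0 - math.exp(-beta * dmax)) * math.exp(-mu_w * dmax)
    sf_ref = _scatter_capture(ref_dia, p_sc, sig_sc)
    sig_iso = pen / 1.683

    for b in range(srcs.shape[0]):
        sx0, sy0, sz0 = srcs[b, 0], srcs[b, 1], srcs[b, 2]
        dxb = tgts[b, 0] - sx0
        dyb = tgts[b, 1] - sy0
        dzb = tgts[b, 2] - sz0
        sadb = math.sqrt(dxb * dxb + dyb * dyb + dzb * dzb)
        ux, uy, uz = dxb / sadb, dyb / sadb, dzb / sadb
        sfb = _scatter_capture(dias[b], p_sc, sig_sc) / sf_ref
        R = 0.5 * dias[b]
        w = mus[b] * cal * sfb
        for p in range(idx.shape[0]):
            vx = org[0] + idx[p, 0] * sp[0]
            vy = org[1] + idx[p, 1] * sp[1]
            vz = org[2] + idx[p, 2] * sp[2]
            wx, wy, wz = vx - sx0, vy - sy0, vz - sz0
            zb = wx * ux + wy * uy + wz * uz
            if zb < 1.0:
                continue
            rx = wx - zb * ux
            ry = wy - zb * uy
            rz = wz - zb * uz
            r = math.sqrt(rx * rx + ry * ry + rz * rz)
            zf = zb / sadb
            Rp = R * zf
            sigp = sig_iso * zf
            if r > Rp + 5.0 * sigp + 2.0:
                continue
            deff = raysum(vals, sp, org, sx0, sy0, sz0, vx, vy, vz)
            oar = 0.5 * math.erfc((r - Rp) / (1.4142135623730951 * sigp))
            out[p, b] = w * (sadb / zb) ** 2 * _pdd(deff, beta, mu_w, fmax) * oar


@njit(cache=True)
def _bbox_entry(sp, org, shape0, shape1, shape2, ax, ay, az, ux, uy, uz):
    """Parametric entry distance of ray a + t*u into the grid box (-1 if missed)."""
    lox = org[0] - 0.5 * sp[0]
    loy = org[1] - 0.5 * sp[1]
    loz = org[2] - 0.5 * sp[2]
    hix = lox + shape0 * sp[0]
    hiy = loy + shape1 * sp[1]
    hiz = loz + shape2 * sp[2]
    tmin, tmax = 0.0, math.inf
    for axis in range(3):
        if axis == 0:
            u, a, lo, hi = ux, ax, lox, hix
        elif axis == 1:
            u, a, lo, hi = uy, ay, loy, hiy
        else:
            u, a, lo, hi = uz, az, loz, hiz
        if abs(u) < _EPS:
            if a < lo or a > hi:
                return -1.0
        else:
            t1 = (lo - a) / u
            t2 = (hi - a) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin:
        return -1.0
    return tmin


@njit(cache=True)
def mc_batch(
    vals, sp, org, srcs, tgts, dias, mus,
    n_hist, seed,
    mu_att, step, lat_scale, fwd_range, broad_frac, broad_sigma,
    src_sigma, rho_floor, rho_zero,
    edep, tallies,
):
    """One batch of stochastic kerma-spread transport.

    Photon rays are sampled from the point source through the (blurred)
    collimator aperture; energy attenuates deterministically along the ray
    (exp(-mu*rho*ds) per step) and each step's released energy is deposited
    at a stochastically displaced point: forward by an exponential range and
    laterally by a Gaussian, both scaling as 1/rho_w of the interaction
    voxel.  tallies accumulates [launched, deposited, lost_massless].
    """
    np.random.seed(seed)
    nx, ny, nz = vals.shape
    nb = srcs.shape[0]
    # MU is a fluence weight: beam energy scales with MU x aperture area
    w_total = 0.0
    for b in range(nb):
        w_total += mus[b] * dias[b] * dias[b]
    if w_total <= 0.0:
        return

    for b in range(nb):
        w_beam = mus[b] * dias[b] * dias[b]
        if w_beam <= 0.0:
            continue
        n_b = int(round(n_hist * w_beam / w_total))
        if n_b < 10:
            n_b = 10
        e_hist = w_beam / n_b

        sx0, sy0, sz0 = srcs[b, 0], srcs[b, 1], srcs[b, 2]
        dxb = tgts[b, 0] - sx0
        dyb = tgts[b, 1] - sy0
        dzb = tgts[b, 2] - sz0
        sadb = math.sqrt(dxb * dxb + dyb * dyb + dzb * dzb)
        ux, uy, uz = dxb / sadb, dyb / sadb, dzb / sadb
        # perpendicular basis of the beam axis
        if abs(ux) < 0.9:
            e1x, e1y, e1z = 1.0 - ux * ux, -ux * uy, -ux * uz
        else:
            e1x, e1y, e1z = -uy * ux, 1.0 - uy * uy, -uy * uz
        n1 = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
        e1x, e1y, e1z = e1x / n1, e1y / n1, e1z / n1
        e2x = uy * e1z - uz * e1y
        e2y = uz * e1x - ux * e1z
        e2z = ux * e1y - uy * e1x
        R = 0.5 * dias[b]

        for _ in range(n_b):
            # aperture sample at the target plane, blurred by the source size
            rad = R * math.sqrt(np.random.random())
            ang = 2.0 * math.pi * np.random.random()
            a1 = rad * math.cos(ang) + src_sigma * np.random.normal()
            a2 = rad * math.sin(ang) + src_sigma * np.random.normal()
            px = tgts[b, 0] + a1 * e1x + a2 * e2x
            py = tgts[b, 1] + a1 * e1y + a2 * e2y
            pz = tgts[b, 2] + a1 * e1z + a2 * e2z
            ddx, ddy, ddz = px - sx0, py - sy0, pz - sz0
            dn = math.sqrt(ddx * ddx + ddy * ddy + ddz * ddz)
            wx, wy, wz = ddx / dn, ddy / dn, ddz / dn
            # ray-perpendicular basis for lateral displacement
            if abs(wx) < 0.9:
                f1x, f1y, f1z = 1.0 - wx * wx, -wx * wy, -wx * wz
            else:
                f1x, f1y, f1z = -wy * wx, 1.0 - wy * wy, -wy * wz
            fn = math.sqrt(f1x * f1x + f1y * f1y + f1z * f1z)
            f1x, f1y, f1z = f1x / fn, f1y / fn, f1z / fn
            f2x = wy * f1z - wz * f1y
            f2y = wz * f1x - wx * f1z
            f2z = wx * f1y - wy * f1x

            t_in = _bbox_entry(sp, org, nx, ny, nz, sx0, sy0, sz0, wx, wy, wz)
            if t_in < 0.0:
                continue
            energy = e_hist
            tallies[0] += energy
            # random start phase: decorrelates the marching comb from the
            # voxel lattice (no aliasing ripple along near-parallel rays)
            t = t_in + step * np.random.random()
            while True:
                qx = sx0 + t * wx
                qy = sy0 + t * wy
                qz = sz0 + t * wz
                i = int(math.floor((qx - org[0]) / sp[0] + 0.5))
                j = int(math.floor((qy - org[1]) / sp[1] + 0.5))
                k = int(math.floor((qz - org[2]) / sp[2] + 0.5))
                if i < 0 or i >= nx or j < 0 or j >= ny or k < 0 or k >= nz:
                    break
                rho = vals[i, j, k]
                if rho > rho_zero:
                    de = energy * (1.0 - math.exp(-mu_att * rho * step))
                    # displacement sampled in radiological (water-equivalent)
                    # length, then marched through the actual density: short
                    # physical range in dense tissue, long in lung
                    if np.random.random() < broad_frac:
                        sig = broad_sigma
                    else:
                        sig = lat_scale
                    fwd = np.random.exponential() * fwd_range
                    g1 = sig * np.random.normal()
                    g2 = sig * np.random.normal()
                    s_rad = math.sqrt(fwd * fwd + g1 * g1 + g2 * g2)
                    di, dj, dk = i, j, k
                    if s_rad > 1e-12:
                        ex = (fwd * wx + g1 * f1x + g2 * f2x) / s_rad
                        ey = (fwd * wy + g1 * f1y + g2 * f2y) / s_rad
                        ez = (fwd * wz + g1 * f1z + g2 * f2z) / s_rad
                        mstep = 0.8 * (sp[0] if sp[0] < sp[2] else sp[2])
                        yx, yy, yz = qx, qy, qz
                        acc = 0.0
                        travelled = 0.0
                        while acc < s_rad and travelled < 150.0:
                            ry = vals[di, dj, dk]
                            acc += ry * mstep
                            travelled += mstep
                            if acc >= s_rad:
                                break
                            yx += mstep * ex
                            yy += mstep * ey
                            yz += mstep * ez
                            di = int(math.floor((yx - org[0]) / sp[0] + 0.5))
                            dj = int(math.floor((yy - org[1]) / sp[1] + 0.5))
                            dk = int(math.floor((yz - org[2]) / sp[2] + 0.5))
                            if di < 0 or di >= nx or dj < 0 or dj >= ny or dk < 0 or dk >= nz:
                                di = -1
                                break
                    if di >= 0:
                        if vals[di, dj, dk] > rho_zero:
                            edep[di, dj, dk] += de
                            tallies[1] += de
                        else:
                            tallies[2] += de
                    energy -= de
                t += step
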