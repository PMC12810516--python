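"""Numba kernels for the jet-geometry Monte Carlo photon transport.

Geometry and conventions (all lengths in micrometres inside the kernel):

* The beam propagates along +Z.  A slab of "air-like" host medium spans
  0 <= z <= slab_zmax and is infinite in X and Y.
* An infinite circular cylinder (the jet) has its axis along Y at
  (x = 0, z = cyl_zc) with radius cyl_r; media index 0 is the slab,
  1 is the cylinder.
* Photon packets carry a weight; at each collision the fraction
  mu_a / mu_t of the current weight is deposited (discrete absorption
  weighting) and the packet scatters through a Henyey-Greenstein
  deflection.  Fluence is accumulated with a track-length estimator on a
  regular voxel grid.
* Refractive-index mismatch is applied only at the cylinder surface
  (unpolarized Fresnel average, Snell refraction, total internal
  reflection); the slab outer faces are index-matched and absorbing
  (photons crossing them are terminated and their weight booked as
  exited).
* Low-weight packets undergo Russian roulette; the weight created or
  destroyed by roulette is booked separately so that

      absorbed + exited + roulette_loss - roulette_gain = launched

  holds to floating-point round-off for every batch.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS_T = 1e-7     # minimum accepted boundary-hit distance, um
_NUDGE = 1e-4     # surface-crossing nudge, um
_MAX_STEPS = 1_000_000
_INF = 1e30


@njit(cache=True, inline="always")
def _hg_cos(g: float, u: float) -> float:
    """Henyey-Greenstein deflection cosine from a uniform variate u."""
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, ct, phi):
    """Rotate a unit vector by deflection cosine ct and azimuth phi."""
    st = np.sqrt(max(1.0 - ct * ct, 0.0))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _dist_cylinder(x, z, ux, uz, cyl_zc, cyl_r):
    """Distance along the ray to the cylinder surface, or +inf."""
    A = ux * ux + uz * uz
    if A < 1e-14:
        return _INF
    px = x
    pz = z - cyl_zc
    B = 2.0 * (px * ux + pz * uz)
    C = px * px + pz * pz - cyl_r * cyl_r
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        return _INF
    sq = np.sqrt(disc)
    t1 = (-B - sq) / (2.0 * A)
    t2 = (-B + sq) / (2.0 * A)
    if t1 > _EPS_T:
        return t1
    if t2 > _EPS_T:
        return t2
    return _INF


@njit(cache=True, inline="always")
def _dist_slab(z, uz, slab_zmax):
    if uz > 1e-14:
        return (slab_zmax - z) / uz
    if uz < -1e-14:
        return -z / uz
    return _INF


@njit(cache=True)
def _tally_segment(tally, w, x, y, z, ux, uy, uz, seg,
                   x0, y0, z0, dx, dy, dz, nx, ny, nz):
    """Deposit w * pathlength into every voxel the segment crosses."""
    # clip [0, seg] to the grid box (slabs method)
    tmin = 0.0
    tmax = seg
    for axis in range(3):
        if axis == 0:
            p, u, lo, hi = x, ux, x0, x0 + nx * dx
        elif axis == 1:
            p, u, lo, hi = y, uy, y0, y0 + ny * dy
        else:
            p, u, lo, hi = z, uz, z0, z0 + nz * dz
        if abs(u) < 1e-14:
            if p < lo or p > hi:
                return
        else:
            ta = (lo - p) / u
            tb = (hi - p) / u
            if ta > tb:
                ta, tb = tb, ta
            if ta > tmin:
                tmin = ta
            if tb < tmax:
                tmax = tb
    if tmax <= tmin:
        return
    # voxel walk
    t = tmin
    px = x + (t + 1e-9) * ux
    py = y + (t + 1e-9) * uy
    pz = z + (t + 1e-9) * uz
    ix = int((px - x0) / dx)
    iy = int((py - y0) / dy)
    iz = int((pz - z0) / dz)
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= nx:
        ix = nx - 1
    if iy >= ny:
        iy = ny - 1
    if iz >= nz:
        iz = nz - 1
    while t < tmax - 1e-12:
        # distance to the next voxel wall along each axis
        if ux > 1e-14:
            tx = (x0 + (ix + 1) * dx - x) / ux
        elif ux < -1e-14:
            tx = (x0 + ix * dx - x) / ux
        else:
            tx = _INF
        if uy > 1e-14:
            ty = (y0 + (iy + 1) * dy - y) / uy
        elif uy < -1e-14:
            ty = (y0 + iy * dy - y) / uy
        else:
            ty = _INF
        if uz > 1e-14:
            tz = (z0 + (iz + 1) * dz - z) / uz
        elif uz < -1e-14:
            tz = (z0 + iz * dz - z) / uz
        else:
            tz = _INF
        tnext = tx
        axis_hit = 0
        if ty < tnext:
            tnext = ty
            axis_hit = 1
        if tz < tnext:
            tnext = tz
            axis_hit = 2
        if tnext > tmax:
            tnext = tmax
            axis_hit = -1
        dl = tnext - t
        if dl > 0.0:
            tally[ix, iy, iz] += w * dl
        t = tnext
        if axis_hit == 0:
            ix += 1 if ux > 0.0 else -1
            if ix < 0 or ix >= nx:
                return
        elif axis_hit == 1:
            iy += 1 if uy > 0.0 else -1
            if iy < 0 or iy >= ny:
                return
        elif axis_hit == 2:
            iz += 1 if uz > 0.0 else -1
            if iz < 0 or iz >= nz:
                return
        else:
            return


@njit(cache=True)
def transport(n_photons, seed,
              mu_a, mu_s, g_arr, n_arr,      # per-medium arrays (0 slab, 1 cylinder), um^-1
              slab_zmax, cyl_zc, cyl_r,
              sig_x, sig_y,
              tally, x0, y0, z0, dx, dy, dz,
              w_min, p_survive):
    """Transport n_photons packets; returns bookkeeping totals.

    Returns (absorbed, exited, exited_ballistic, roulette_gain,
    roulette_loss).  `tally` is modified in place and holds summed
    weight * pathlength per voxel (caller normalizes by voxel volume and
    photon count).
    """
    nx, ny, nz = tally.shape
    np.random.seed(seed)
    absorbed = 0.0
    exited = 0.0
    exited_ball = 0.0
    r_gain = 0.0
    r_loss = 0.0
    has_cyl = cyl_r > 0.0

    for _ in range(n_photons):
        x = np.random.normal() * sig_x
        y = np.random.normal() * sig_y
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0
        n_coll = 0
        if has_cyl and (x * x + (z - cyl_zc) ** 2 < cyl_r * cyl_r):
            med = 1
        else:
            med = 0

        for _step in range(_MAX_STEPS):
            mt = mu_a[med] + mu_s[med]
            s = -np.log(np.random.random()) / mt
            t_cyl = _dist_cylinder(x, z, ux, uz, cyl_zc, cyl_r) if has_cyl else _INF
            t_slab = _dist_slab(z, uz, slab_zmax)
            t_b = t_cyl if t_cyl < t_slab else t_slab
            if s < t_b:
                seg = s
                event = 0        # collision
            elif t_cyl < t_slab:
                seg = t_b
                event = 1        # cylinder surface
            else:
                seg = t_b
                event = 2        # slab face
            _tally_segment(tally, w, x, y, z, ux, uy, uz, seg,
                           x0, y0, z0, dx, dy, dz, nx, ny, nz)
            x += seg * ux
            y += seg * uy
            z += seg * uz

            if event == 0:
                n_coll += 1
                dep = w * mu_a[med] / mt
                absorbed += dep
                w -= dep
                if w <= 0.0:
                    break
                ct = _hg_cos(g_arr[med], np.random.random())
                phi = 2.0 * np.pi * np.random.random()
                ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                if w < w_min:
                    if np.random.random() < p_survive:
                        r_gain += w * (1.0 / p_survive - 1.0)
                        w /= p_survive
                    else:
                        r_loss += w
                        break
            elif event == 1:
                # outward surface normal at the hit point
                nrx = x / cyl_r
                nrz = (z - cyl_zc) / cyl_r
                ndotu = ux * nrx + uz * nrz
                if ndotu < 0.0:          # entering the cylinder
                    n1 = n_arr[0]
                    n2 = n_arr[1]
                    onx, onz = nrx, nrz  # oriented against the ray
                    cosi = -ndotu
                else:                     # leaving the cylinder
                    n1 = n_arr[1]
                    n2 = n_arr[0]
                    onx, onz = -nrx, -nrz
                    cosi = ndotu
                if cosi > 1.0:
                    cosi = 1.0
                eta = n1 / n2
                sin2t = eta * eta * (1.0 - cosi * cosi)
                reflect = False
                if sin2t >= 1.0:
                    reflect = True       # total internal reflection
                elif n1 != n2:
                    cost = np.sqrt(1.0 - sin2t)
                    rs = (n1 * cosi - n2 * cost) / (n1 * cosi + n2 * cost)
                    rp = (n1 * cost - n2 * cosi) / (n1 * cost + n2 * cosi)
                    R = 0.5 * (rs * rs + rp * rp)
                    if np.random.random() < R:
                        reflect = True
                if reflect:
                    ux = ux + 2.0 * cosi * onx
                    uz = uz + 2.0 * cosi * onz
                else:
                    cost = np.sqrt(max(1.0 - sin2t, 0.0))
                    ux = eta * ux + (eta * cosi - cost) * onx
                    uy = eta * uy
                    uz = eta * uz + (eta * cosi - cost) * onz
                norm = np.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                x += _NUDGE * ux
                y += _NUDGE * uy
                z += _NUDGE * uz
                if z <= 0.0 or z >= slab_zmax:   # nudged out of the slab
                    exited += w
                    break
                if x * x + (z - cyl_zc) ** 2 < cyl_r * cyl_r:
                    med = 1
                else:
                    med = 0
            else:
                exited += w
                if n_coll == 0:
                    exited_ball += w
                break

    return absorbed, exited, exited_ball, r_gain, r_loss
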