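"""Numba photon-transport kernels.

Serial weighted-packet Monte Carlo on a regular voxel lattice.  Per-photon
RNG substreams are derived from the run seed with a splitmix64 finalizer,
so tallies do not depend on launch order and repeat runs with the same seed
are bit-identical.

Estimator: fluence is accumulated per voxel with the exact path-length
integral of the continuously absorbed packet weight,
integral_0^L w0 exp(-mu_a l) dl = (w0 - w1)/mu_a, which reduces to w0*L
when mu_a = 0.  The caller divides tallies by (n_photons * voxel_volume)
to obtain fluence per launched photon in mm^-2.
"""

import math

import numpy as np
from numba import njit

U64 = np.uint64
_GOLD = U64(0x9E3779B97F4A7C15)
_INV53 = 1.1102230246251565e-16  # 2**-53
C_VACUUM_MM_NS = 299.792458

# geometry codes
GEOM_SLAB = 0  # Fresnel top face at z=0, absorbing other five faces
GEOM_INFINITE = 1  # unbounded medium; deposit only inside the grid


@njit(cache=True)
def _mix64(z):
    """splitmix64 finalizer: decorrelates consecutive photon indices."""
    z = z + _GOLD
    z = (z ^ (z >> U64(30))) * U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> U64(27))) * U64(0x94D049BB133111EB)
    return z ^ (z >> U64(31))


@njit(cache=True)
def _next(s):
    # xorshift64; state must never be zero
    s ^= s << U64(13)
    s ^= s >> U64(7)
    s ^= s << U64(17)
    return s


@njit(cache=True)
def fresnel_unpolarized(n_in, n_out, cos_i):
    if n_in == n_out:
        return 0.0
    sin2_i = 1.0 - cos_i * cos_i
    sin2_t = (n_in / n_out) * (n_in / n_out) * sin2_i
    if sin2_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin2_t)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True)
def hg_cos_theta(g, u):
    """Inverse-CDF sample of the Henyey-Greenstein polar cosine."""
    if g == 0.0:
        return 2.0 * u - 1.0
    f = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - f * f) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=True, fastmath=True)
def transport(
    flu,
    dx,
    mu_a,
    mu_s,
    g,
    n_med,
    n_out,
    src_x,
    src_y,
    src_z,
    isotropic,
    n_photons,
    seed,
    time_gate_ns,
    roulette_threshold,
    roulette_survival,
    geometry,
):
    """Trace ``n_photons`` packets, accumulating path-length tallies in ``flu``.

    Returns (absorbed, escaped, inflight, n_scatter_events).  The three
    weight tallies sum to n_photons up to float rounding; roulette kills and
    boosts are folded into the absorbed tally so the budget closes exactly.
    """
    nx, ny, nz = flu.shape
    c_med = C_VACUUM_MM_NS / n_med
    max_path = time_gate_ns * c_med
    inv_mua = 1.0 / mu_a if mu_a > 0.0 else 0.0
    two_pi = 6.283185307179586
    absorbed = 0.0
    escaped = 0.0
    inflight = 0.0
    n_scat = 0
    nsrc = src_x.shape[0]
    for ip in range(n_photons):
        s = _mix64(seed ^ (U64(ip) * _GOLD))
        if s == U64(0):
            s = U64(0x1234567887654321)
        jsrc = ip % nsrc
        x = src_x[jsrc]
        y = src_y[jsrc]
        z = src_z[jsrc]
        if isotropic:
            s = _next(s)
            u1 = (s >> U64(11)) * _INV53
            s = _next(s)
            u2 = (s >> U64(11)) * _INV53
            uz = 2.0 * u1 - 1.0
            st0 = math.sqrt(max(0.0, 1.0 - uz * uz))
            ph0 = two_pi * u2
            ux = st0 * math.cos(ph0)
            uy = st0 * math.sin(ph0)
        else:
            ux = 0.0
            uy = 0.0
            uz = 1.0
        w = 1.0
        path = 0.0
        ix = int(math.floor(x / dx))
        iy = int(math.floor(y / dx))
        iz = int(math.floor(z / dx))
        if iz < 0:
            iz = 0  # pencil launch exactly on the z=0 plane
        alive = True
        inv_ux = 0.0
        inv_uy = 0.0
        inv_uz = 1.0
        if isotropic:
            inv_ux = 1.0 / ux if ux != 0.0 else 0.0
            inv_uy = 1.0 / uy if uy != 0.0 else 0.0
            inv_uz = 1.0 / uz if uz != 0.0 else 0.0
        while alive:
            s = _next(s)
            u = (s >> U64(11)) * _INV53
            remaining = -math.log(1.0 - u) / mu_s
            while remaining > 0.0:
                # fast path: step fits inside the current voxel and the gate
                cx = x - ix * dx
                cy = y - iy * dx
                cz = z - iz * dx
                clear = cx
                if dx - cx < clear:
                    clear = dx - cx
                if cy < clear:
                    clear = cy
                if dx - cy < clear:
                    clear = dx - cy
                if cz < clear:
                    clear = cz
                if dx - cz < clear:
                    clear = dx - cz
                if remaining < clear and path + remaining < max_path:
                    d = remaining
                    xa = mu_a * d
                    if xa < 0.01:
                        dec = xa * (1.0 - 0.5 * xa * (1.0 - xa * 0.3333333333333333))
                        dw = w * dec
                    else:
                        dw = w * (1.0 - math.exp(-xa))
                    if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                        if mu_a > 0.0:
                            flu[ix, iy, iz] += dw * inv_mua
                        else:
                            flu[ix, iy, iz] += w * d
                    absorbed += dw
                    w -= dw
                    x += ux * d
                    y += uy * d
                    z += uz * d
                    path += d
                    remaining = 0.0
                    continue
                if ux > 0.0:
                    tx = ((ix + 1) * dx - x) * inv_ux
                elif ux < 0.0:
                    tx = (ix * dx - x) * inv_ux
                else:
                    tx = 1.0e30
                if uy > 0.0:
                    ty = ((iy + 1) * dx - y) * inv_uy
                elif uy < 0.0:
                    ty = (iy * dx - y) * inv_uy
                else:
                    ty = 1.0e30
                if uz > 0.0:
                    tz = ((iz + 1) * dx - z) * inv_uz
                elif uz < 0.0:
                    tz = (iz * dx - z) * inv_uz
                else:
                    tz = 1.0e30
                d = remaining
                axis = -1
                if tx < d:
                    d = tx
                    axis = 0
                if ty < d:
                    d = ty
                    axis = 1
                if tz < d:
                    d = tz
                    axis = 2
                gated = False
                if path + d >= max_path:
                    d = max_path - path
                    gated = True
                if d < 0.0:
                    d = 0.0
                xa = mu_a * d
                if xa < 0.01:
                    wn = w * (1.0 - xa * (1.0 - 0.5 * xa * (1.0 - xa * 0.3333333333333333)))
                else:
                    wn = w * math.exp(-xa)
                if 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
                    if mu_a > 0.0:
                        flu[ix, iy, iz] += (w - wn) * inv_mua
                    else:
                        flu[ix, iy, iz] += w * d
                absorbed += w - wn
                w = wn
                x += ux * d
                y += uy * d
                z += uz * d
                path += d
                if gated:
                    inflight += w
                    alive = False
                    break
                if axis == -1:
                    remaining = 0.0
                    continue
                remaining -= d
                # snap to the wall and step the index to keep floor() honest
                if axis == 0:
                    if ux > 0.0:
                        ix += 1
                        x = ix * dx
                    else:
                        x = ix * dx
                        ix -= 1
                elif axis == 1:
                    if uy > 0.0:
                        iy += 1
                        y = iy * dx
                    else:
                        y = iy * dx
                        iy -= 1
                else:
                    if uz > 0.0:
                        iz += 1
                        z = iz * dx
                    else:
                        z = iz * dx
                        iz -= 1
                if geometry == GEOM_SLAB:
                    if iz < 0:
                        # hit the illuminated surface from below: Fresnel test
                        refl = fresnel_unpolarized(n_med, n_out, -uz)
                        s = _next(s)
                        u2 = (s >> U64(11)) * _INV53
                        if u2 < refl:
                            uz = -uz
                            inv_uz = -inv_uz
                            iz = 0
                        else:
                            escaped += w
                            alive = False
                            break
                    elif ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz >= nz:
                        escaped += w
                        alive = False
                        break
            if not alive:
                break
            # scattering event: Henyey-Greenstein deflection
            n_scat += 1
            s = _next(s)
            u1 = (s >> U64(11)) * _INV53
            ct = hg_cos_theta(g, u1)
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            # azimuth via rejection on the unit disk (no trig calls)
            while True:
                s = _next(s)
                pa = 2.0 * ((s >> U64(11)) * _INV53) - 1.0
                s = _next(s)
                pb = 2.0 * ((s >> U64(11)) * _INV53) - 1.0
                pr2 = pa * pa + pb * pb
                if 0.0 < pr2 <= 1.0:
                    break
            pinv = 1.0 / math.sqrt(pr2)
            cp = pa * pinv
            sp = pb * pinv
            if uz > 0.99999 or uz < -0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz > 0.0 else -ct
            else:
                den = math.sqrt(1.0 - uz * uz)
                inv_den = 1.0 / den
                uxn = st * (ux * uz * cp - uy * sp) * inv_den + ux * ct
                uyn = st * (uy * uz * cp + ux * sp) * inv_den + uy * ct
                uzn = -st * cp * den + uz * ct
                ux = uxn
                uy = uyn
                uz = uzn
            inv_ux = 1.0 / ux if ux != 0.0 else 0.0
            inv_uy = 1.0 / uy if uy != 0.0 else 0.0
            inv_uz = 1.0 / uz if uz != 0.0 else 0.0
            # Russian roulette on low-weight packets
            if w < roulette_threshold:
                s = _next(s)
                u3 = (s >> U64(11)) * _INV53
                if u3 < roulette_survival:
                    boost = w * (1.0 / roulette_survival - 1.0)
                    w += boost
                    absorbed -= boost
                else:
                    absorbed += w
                    alive = False
    return absorbed, escaped, inflight, n_scat
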