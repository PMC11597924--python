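"""Numba-compiled core of the stochastic photon-transport engine.

All geometry here is in metres.  The curved phantom's interfaces are
concentric circles about ``C = (0, R)``; a negative or zero ``R`` selects
the flat-slab branch.  Photons are traced one at a time with a per-photon
deterministic seed, so results are independent of execution order and
bit-reproducible for a given run seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Roots closer than this (m) are treated as the photon standing on the
# boundary it just crossed.
_TMIN = 1e-12
# Post-event nudge (m) pushing the photon off the interface it sits on.
_NUDGE = 1e-10
# Russian-roulette threshold and survival probability (unbiased termination).
_W_ROULETTE = 1e-4
_P_SURVIVE = 0.1
_MAX_EVENTS = 10_000_000


@njit(cache=True)
def _seed(s):
    np.random.seed(s)


@njit(cache=True)
def _photon_seed(seed_base, index):
    # Knuth multiplicative hash onto the 31-bit seed range.
    v = (np.uint64(seed_base) + np.uint64(2654435761) * (np.uint64(index) + np.uint64(1))) % np.uint64(
        2147483647
    )
    return np.int64(v)


@njit(cache=True)
def _hg_angle(g):
    """Sample the 2D Henyey-Greenstein deflection angle (mean cosine g)."""
    u = np.random.random()
    if g == 0.0:
        return (2.0 * u - 1.0) * np.pi
    return 2.0 * np.arctan((1.0 - g) / (1.0 + g) * np.tan(np.pi * (u - 0.5)))


@njit(cache=True)
def _dist_to_boundary(x, y, ux, uy, R, curved, d_top, d_bot, half_width):
    """Distance to the current layer's nearest boundary along (ux, uy).

    Returns (distance, which): which = 0 upper interface, 1 lower interface,
    2 lateral wall, -1 none found (should not happen for a photon inside).
    """
    tbest = 1.0e30
    which = -1
    if curved:
        ox = x
        oy = y - R
        b = ox * ux + oy * uy
        rr = ox * ox + oy * oy
        # upper interface: larger circle radius R - d_top
        r1 = R - d_top
        c = rr - r1 * r1
        disc = b * b - c
        if disc > 0.0:
            sq = np.sqrt(disc)
            t1 = -b - sq
            t2 = -b + sq
            t = 1.0e30
            if t1 > _TMIN:
                t = t1
            elif t2 > _TMIN:
                t = t2
            if t < tbest:
                tbest = t
                which = 0
        # lower interface: smaller circle radius R - d_bot
        r2 = R - d_bot
        c = rr - r2 * r2
        disc = b * b - c
        if disc > 0.0:
            sq = np.sqrt(disc)
            t1 = -b - sq
            t2 = -b + sq
            t = 1.0e30
            if t1 > _TMIN:
                t = t1
            elif t2 > _TMIN:
                t = t2
            if t < tbest:
                tbest = t
                which = 1
    else:
        if uy < 0.0:
            t = (d_top - y) / uy
            if t > _TMIN and t < tbest:
                tbest = t
                which = 0
        elif uy > 0.0:
            t = (d_bot - y) / uy
            if t > _TMIN and t < tbest:
                tbest = t
                which = 1
    if ux > 0.0:
        t = (half_width - x) / ux
        if t > _TMIN and t < tbest:
            tbest = t
            which = 2
    elif ux < 0.0:
        t = (-half_width - x) / ux
        if t > _TMIN and t < tbest:
            tbest = t
            which = 2
    return tbest, which


@njit(cache=True)
def _launch(s_center, spot_sigma, half_angle, tilt, R, curved, d_launch):
    """Sample a launch state on the surface at depth ``d_launch``.

    Position: Gaussian arc offset about the diode centre (sigma = spot/2)
    truncated at +/- 2 sigma.  Direction: uniform within +/- half_angle
    about the local inward normal rotated by the tilt.
    Returns (x, y, ux, uy).
    """
    if spot_sigma > 0.0:
        t = np.random.normal(0.0, spot_sigma)
        while np.abs(t) > 2.0 * spot_sigma:
            t = np.random.normal(0.0, spot_sigma)
    else:
        t = 0.0
    s = s_center + t
    if curved:
        r_launch = R - d_launch
        phi = s / r_launch
        x = r_launch * np.sin(phi)
        y = R - r_launch * np.cos(phi)
        nx = -np.sin(phi)
        ny = np.cos(phi)
    else:
        x = s
        y = d_launch
        nx = 0.0
        ny = 1.0
    if half_angle > 0.0:
        a = tilt + (2.0 * np.random.random() - 1.0) * half_angle
    else:
        a = tilt
    ca = np.cos(a)
    sa = np.sin(a)
    ux = ca * nx - sa * ny
    uy = sa * nx + ca * ny
    return x, y, ux, uy


@njit(cache=True)
def _trace(x, y, ux, uy, w, layer,
           R, curved, bounds, n_arr, mu_a, mu_s, g_arr,
           half_width, h, nx_cells, ny_cells,
           grid, layer_abs, entered, accounts):
    """Trace one photon to termination, accumulating tallies in place.

    ``accounts``: [0] reflected through the entry surface, [1] transmitted
    through the deep surface, [2] lateral escape, [3] residual (event-cap
    safety, zero in practice).
    """
    nl = bounds.shape[0] - 1
    x += ux * _NUDGE
    y += uy * _NUDGE
    w_min = _W_ROULETTE * w  # roulette threshold relative to the launch weight
    events = 0
    alive = True
    while alive and events < _MAX_EVENTS:
        events += 1
        mt = mu_a[layer] + mu_s[layer]
        if mt > 0.0:
            step = -np.log(np.random.random() + 1e-300) / mt
        else:
            step = 1.0e30
        db, which = _dist_to_boundary(
            x, y, ux, uy, R, curved, bounds[layer], bounds[layer + 1], half_width
        )
        if step < db:
            # interaction inside the layer: deposit, then scatter
            x += ux * step
            y += uy * step
            dep = w * mu_a[layer] / mt
            w -= dep
            layer_abs[layer] += dep
            ix = int((x + half_width) / h)
            iy = int(y / h)
            if ix < 0:
                ix = 0
            if ix >= nx_cells:
                ix = nx_cells - 1
            if iy < 0:
                iy = 0
            if iy >= ny_cells:
                iy = ny_cells - 1
            grid[iy, ix] += dep
            phi = _hg_angle(g_arr[layer])
            c = np.cos(phi)
            s = np.sin(phi)
            tx = c * ux - s * uy
            uy = s * ux + c * uy
            ux = tx
            if w < w_min:
                if np.random.random() < _P_SURVIVE:
                    w /= _P_SURVIVE
                else:
                    alive = False
        else:
            x += ux * db
            y += uy * db
            if which == 2:
                accounts[2] += w
                alive = False
            elif which == 0 and layer == 0:
                accounts[0] += w
                alive = False
            elif which == 1 and layer == nl - 1:
                accounts[1] += w
                alive = False
            elif which == -1:
                accounts[3] += w
                alive = False
            else:
                m = layer - 1 if which == 0 else layer + 1
                if curved:
                    ox = x
                    oy = y - R
                    on = np.sqrt(ox * ox + oy * oy)
                    nhx = ox / on
                    nhy = oy / on
                else:
                    nhx = 0.0
                    nhy = -1.0
                dot = ux * nhx + uy * nhy
                if dot > 0.0:
                    nhx = -nhx
                    nhy = -nhy
                    dot = -dot
                ci = -dot
                n1 = n_arr[layer]
                n2 = n_arr[m]
                eta = n1 / n2
                s2 = eta * eta * (1.0 - ci * ci)
                ct = 0.0
                if s2 >= 1.0:
                    rf = 1.0
                else:
                    ct = np.sqrt(1.0 - s2)
                    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
                    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
                    rf = 0.5 * (rs * rs + rp * rp)
                if np.random.random() < rf:
                    # specular reflection: u - 2 (u.n) n with u.n = -ci
                    ux = ux + 2.0 * ci * nhx
                    uy = uy + 2.0 * ci * nhy
                else:
                    ux = eta * ux + (eta * ci - ct) * nhx
                    uy = eta * uy + (eta * ci - ct) * nhy
                    norm = np.sqrt(ux * ux + uy * uy)
                    ux /= norm
                    uy /= norm
                    layer = m
                    entered[layer] += w
                x += ux * _NUDGE
                y += uy * _NUDGE
    if alive:
        accounts[3] += w
    return w


@njit(cache=True)
def run_photons(seed_base, n_photons, weight,
                s_center, spot_sigma, half_angle, tilt, d_launch, layer0,
                R, curved, bounds, n_arr, mu_a, mu_s, g_arr,
                half_width, h, nx_cells, ny_cells,
                grid, layer_abs, entered, accounts):
    """Trace ``n_photons`` from one diode, each with its own derived seed."""
    for i in range(n_photons):
        _seed(_photon_seed(seed_base, i))
        x, y, ux, uy = _launch(s_center, spot_sigma, half_angle, tilt, R, curved, d_launch)
        entered[layer0] += weight
        _trace(x, y, ux, uy, weight, layer0,
               R, curved, bounds, n_arr, mu_a, mu_s, g_arr,
               half_width, h, nx_cells, ny_cells,
               grid, layer_abs, entered, accounts)
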