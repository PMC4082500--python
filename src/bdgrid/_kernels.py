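"""Numba kernels for the analytic DH-sphere fast path of the BD engine.

Grid-free solutes (net charge + soft core, isotropic) admit analytic pair
forces, so long statistical runs are propagated in compiled chunks instead
of per-step Python.  The general gridded path lives in :mod:`bdgrid.engine`
and uses finite-difference forces; the two paths are cross-checked in the
unit tests.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _tokuyama(phi):
    b = np.sqrt(9.0 * phi / 8.0)
    c = 11.0 * phi / 16.0
    h = (2.0 * b * b / (1.0 - b)
         - c / (1.0 + 2.0 * c)
         - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c)))
    return 1.0 / (1.0 + h)


@njit(cache=True)
def _lens_volume(d, r1, r2):
    if d >= r1 + r2:
        return 0.0
    rmin = r1 if r1 < r2 else r2
    if d <= abs(r1 - r2):
        return 4.0 / 3.0 * np.pi * rmin**3
    return (np.pi * (r1 + r2 - d)**2 *
            (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2)**2) / (12.0 * d))


@njit(cache=True)
def run_dh_chunk(pos, img, normals, box_side, periodic,
                 pref, kappa, contact, sc_eps, sc_n, dh_cutoff,
                 d0, stokes, volumes, r_cut, use_hydro, use_dh,
                 dt, kt, d_accum):
    """Propagate ``normals.shape[0]`` BD steps in place.

    pos (N,3) wrapped positions; img (N,3) integer image counts; normals
    (steps, N, 3) standard normals; pref (N,N) DH prefactors C_ij so that
    w = C e^(−κ(d−a))/d; contact (N,N) contact distances a_ij; soft core
    E = sc_eps (a_ij/d)^sc_n.  d_accum (N,) accumulates the per-step
    short-time diffusion coefficients actually used (for diagnostics).
    Returns (dh_energy, softcore_energy) of the final configuration.
    """
    n = pos.shape[0]
    steps = normals.shape[0]
    forces = np.zeros((n, 3))
    phi = np.zeros(n)
    e_dh = 0.0
    e_sc = 0.0
    for s in range(steps):
        last = s == steps - 1
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
            phi[i] = 0.0
        e_dh = 0.0
        e_sc = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[j, 0] - pos[i, 0]
                dy = pos[j, 1] - pos[i, 1]
                dz = pos[j, 2] - pos[i, 2]
                if periodic:
                    dx -= box_side * np.floor(dx / box_side + 0.5)
                    dy -= box_side * np.floor(dy / box_side + 0.5)
                    dz -= box_side * np.floor(dz / box_side + 0.5)
                d2 = dx * dx + dy * dy + dz * dz
                d = np.sqrt(d2)
                if d < 1e-9:
                    continue
                fmag = 0.0
                a = contact[i, j]
                if use_dh and d <= dh_cutoff:
                    w = pref[i, j] * np.exp(-kappa * (d - a)) / d
                    fmag += w * (kappa + 1.0 / d)
                    if last:
                        e_dh += w
                if sc_eps > 0.0:
                    esc = sc_eps * (a / d) ** sc_n
                    fmag += sc_n * esc / d
                    if last:
                        e_sc += esc
                # fmag > 0 = repulsive along the i->j axis
                fx = fmag * dx / d
                fy = fmag * dy / d
                fz = fmag * dz / d
                forces[i, 0] -= fx
                forces[i, 1] -= fy
                forces[i, 2] -= fz
                forces[j, 0] += fx
                forces[j, 1] += fy
                forces[j, 2] += fz
                if use_hydro:
                    if d < r_cut - stokes[j]:
                        phi[i] += volumes[j]
                    elif d < r_cut + stokes[j]:
                        phi[i] += _lens_volume(d, r_cut, stokes[j])
                    if d < r_cut - stokes[i]:
                        phi[j] += volumes[i]
                    elif d < r_cut + stokes[i]:
                        phi[j] += _lens_volume(d, r_cut, stokes[i])
        v_local = 4.0 / 3.0 * np.pi * r_cut**3
        for i in range(n):
            dt_short = d0[i]
            if use_hydro:
                f = phi[i] / v_local
                if f > 0.6:
                    f = 0.6
                dt_short = d0[i] * _tokuyama(f)
            d_accum[i] += dt_short
            drift = dt_short * dt / kt
            sigma = np.sqrt(2.0 * dt_short * dt)
            for k in range(3):
                pos[i, k] += drift * forces[i, k] + sigma * normals[s, i, k]
                if periodic:
                    shift = np.floor(pos[i, k] / box_side)
                    if shift != 0.0:
                        img[i, k] += int(shift)
                        pos[i, k] -= shift * box_side
    return e_dh, e_sc
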