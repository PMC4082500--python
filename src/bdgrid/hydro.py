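"""Mean-field hydrodynamics.

Instead of a full configuration-dependent diffusion tensor (whose square
root requires a Cholesky factorization every step), each solute carries a
scalar short-time diffusion coefficient that depends on the volume fraction
φ_i of its local environment: a sphere of radius R_cut centered on the
solute.  Solutes wholly inside the local sphere contribute their full
(Stokes-sphere) volume; solutes straddling its surface contribute the
two-sphere lens intersection volume.

The φ-dependence uses published hard-sphere suspension results:

* translation — Tokuyama & Oppenheim short-time self-diffusion,
  D_t(φ)/D0 = 1/(1 + H(φ)) with
  H(φ) = 2b²/(1−b) − c/(1+2c) − b c (2+c)/((1+c)(1−b+c)),
  b = √(9φ/8), c = 11φ/16   (refs: Tokuyama & Oppenheim, PRE 50 (1994) R16;
  PRE 56 (1997) 2658).
* rotation — Cichocki, Ekiel-Jeżewska & Wajnryb virial series with
  lubrication, D_r(φ)/D0 = 1 − 0.631 φ − 0.726 φ²
  (ref: J. Chem. Phys. 111 (1999) 3265).
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .model import BoxSpec, wrap_minimum_image

# Cichocki et al. (1999) rotational virial coefficients
CICHOCKI_C1 = 0.631
CICHOCKI_C2 = 0.726

# random close packing: upper bound of the Tokuyama model's validity
PHI_MAX = 0.64


def sphere_cap_intersection_volume(d: float, r1: float, r2: float) -> float:
    """Volume of the lens formed by two intersecting spheres (Å³).

    Full smaller-sphere volume when one sphere contains the other
    (d ≤ |r1−r2|), zero when disjoint (d ≥ r1+r2), otherwise the standard
    two-cap lens formula.
    """
    if d < 0 or r1 < 0 or r2 < 0:
        raise ValueError("negative distance or radius")
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 4.0 / 3.0 * np.pi * min(r1, r2) ** 3
    return (np.pi * (r1 + r2 - d) ** 2 *
            (d * d + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2) / (12.0 * d))


def effective_rcut(grid_side: float, box_side: float, factor: float = 4.0) -> float:
    """Local-volume cutoff: ``factor`` × the side of the largest interaction
    grid, rescaled down to half the box when the box is small."""
    return min(factor * grid_side, box_side / 2.0)


def local_volume_fraction(positions, stokes_radii, volumes, i: int,
                          r_cut: float, box: Optional[BoxSpec] = None,
                          include_self: bool = False) -> float:
    """Occupied volume fraction φ_i of the local sphere of radius ``r_cut``
    around solute ``i``.

    Neighbors with center distance d < r_cut − σ_j contribute their full
    volume v_j; partially included neighbors (r_cut − σ_j < d < r_cut + σ_j)
    contribute the solute-sphere ∩ local-sphere lens volume.  The central
    solute's own volume is excluded unless ``include_self``.
    """
    positions = np.asarray(positions, float)
    stokes_radii = np.asarray(stokes_radii, float)
    volumes = np.asarray(volumes, float)
    if r_cut <= stokes_radii.max():
        raise ValueError("r_cut must exceed the largest Stokes radius")
    sep = positions - positions[i]
    if box is not None and box.periodic:
        sep = wrap_minimum_image(sep, box)
    d = np.linalg.norm(sep, axis=1)
    occupied = volumes[i] if include_self else 0.0
    for j in range(len(positions)):
        if j == i:
            continue
        if d[j] < r_cut - stokes_radii[j]:
            occupied += volumes[j]
        elif d[j] < r_cut + stokes_radii[j]:
            occupied += sphere_cap_intersection_volume(d[j], r_cut, stokes_radii[j])
    v_local = 4.0 / 3.0 * np.pi * r_cut**3
    return occupied / v_local


def tokuyama_dt_short(phi):
    """Short-time translational self-diffusion ratio D_t(φ)/D0 for a
    hard-sphere suspension (Tokuyama model).  Valid for 0 ≤ φ < 0.64."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr >= PHI_MAX):
        raise ValueError(f"phi must lie in [0, {PHI_MAX})")
    b = np.sqrt(9.0 * phi_arr / 8.0)
    c = 11.0 * phi_arr / 16.0
    h = (2.0 * b**2 / (1.0 - b)
         - c / (1.0 + 2.0 * c)
         - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c)))
    out = 1.0 / (1.0 + h)
    return out if out.ndim else float(out)


def cichocki_dr_short(phi):
    """Short-time rotational self-diffusion ratio D_r(φ)/D0 (Cichocki et
    al. two/three-body virial series with lubrication)."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < 0) or np.any(phi_arr >= PHI_MAX):
        raise ValueError(f"phi must lie in [0, {PHI_MAX})")
    out = 1.0 - CICHOCKI_C1 * phi_arr - CICHOCKI_C2 * phi_arr**2
    return out if out.ndim else float(out)
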