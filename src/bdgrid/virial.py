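"""Second osmotic virial coefficients for two-sphere test systems.

B22 quantifies the leading deviation from solution ideality:

    B22 = −½ ∫ (e^(−w(r)/kBT) − 1) 4π r² dr,

positive for net repulsion.  Only the *long-range* contribution is
considered here — the lower integration bound lb is placed at the contact
distance plus (or at) a multiple of the Debye length — because the
second-order expansion used for the closed form requires |w/kT| ≪ 1.

Three routes are implemented and cross-checked:

* a closed form from the second-order expansion of the Mayer function with
  the DH potential of mean force,
* adaptive 1-D quadrature (full exponent or second-order),
* the 3-D lattice protocol: one sphere fixed at the box center, the other
  visiting every vertex of a regular lattice (avoiding overlaps), energies
  from the hybrid grid/DH pair model, B22 as a Riemann sum over vertices.

The built-in test system is a pair of fullerene-like spheres: 180 point
charges quasi-uniformly covering a 6 Å sphere, net charge split evenly,
with each sphere's electrostatic grid filled from the analytic DH exterior
solution of a uniformly charged sphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.integrate import quad

from .constants import COULOMB
from .electro import DHPair, dh_pmf, grid_value
from .model import (AtomSet, PotentialGrid, Solute, SolventModel,
                    grid_nodes_for_extent)

SPHERE_RADIUS = 6.0     # Å, test-particle radius
SPHERE_ATOMS = 180      # point charges per particle


@dataclass
class B22Result:
    """A B22 estimate (Å³) with, for the lattice route, random-subset
    statistics and the lower integration bound used."""

    value: float
    method: str
    lower_bound: float
    subset_mean: Optional[float] = None
    subset_sd: Optional[float] = None
    n_points: Optional[int] = None
    expansion_valid: bool = True


@dataclass
class SphereSystem:
    """Two fullerene-like charged spheres with analytic DH grids."""

    solute1: Solute
    solute2: Solute
    solvent: SolventModel

    @property
    def contact_distance(self) -> float:
        return self.solute1.stokes_radius + self.solute2.stokes_radius

    def dh_pair(self) -> DHPair:
        return DHPair.from_solutes(self.solute1, self.solute2, self.solvent)


def fibonacci_sphere(n: int, radius: float) -> np.ndarray:
    """n quasi-uniform points on a sphere (golden-spiral layout).

    The raw spiral has a small (~1e-3·R) center-of-geometry offset; it is
    removed by iterative recenter-and-reproject so every point sits at
    exactly ``radius`` from the exact center of geometry.
    """
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azim = np.pi * (1.0 + np.sqrt(5.0)) * i
    pts = radius * np.stack([np.cos(azim) * np.sin(polar),
                             np.sin(azim) * np.sin(polar),
                             np.cos(polar)], axis=1)
    for _ in range(100):
        pts = pts - pts.mean(axis=0)
        pts = radius * pts / np.linalg.norm(pts, axis=1)[:, None]
        if np.abs(pts.mean(axis=0)).max() < 1e-14 * radius:
            break
    return pts


def sphere_dh_grid(z: float, radius: float, solvent: SolventModel,
                   side: float, spacing: float = 1.0) -> PotentialGrid:
    """Electrostatic grid (kcal/mol/e) of a uniformly charged sphere.

    Exterior of the sphere: the DH solution
    Φ(r) = z e e^(−κ(r−a0)) / (4π ε0 εr r (1+κ a0)); the interior is filled
    with the surface value (charges never probe it in valid configurations).
    This stands in for a numerically solved linearized Poisson-Boltzmann
    grid, which it equals exactly for a centrosymmetric charge density.
    """
    if side < 4.0 * radius:
        raise ValueError("grid side should be at least 4x the sphere radius")
    n = grid_nodes_for_extent(side, spacing)
    half = (n - 1) * spacing / 2.0
    ax = np.arange(n) * spacing - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X * X + Y * Y + Z * Z)
    r = np.maximum(r, radius)
    kappa = solvent.kappa
    vals = (z * COULOMB * np.exp(-kappa * (r - radius)) /
            (solvent.relative_permittivity * r * (1.0 + kappa * radius)))
    return PotentialGrid("electrostatic", origin=np.array([-half] * 3),
                         spacing=spacing, values=vals)


def make_sphere_system(z1: float, z2: float, solvent: Optional[SolventModel] = None,
                       grid_side: float = 100.0, grid_spacing: float = 1.0,
                       with_grids: bool = True) -> SphereSystem:
    """Build the two-sphere test system: each particle is a 6 Å shell of
    180 atoms carrying z/180 e each (layout deterministic), with an
    analytically filled electrostatic grid of the requested side."""
    if solvent is None:
        solvent = SolventModel.monovalent(0.005)

    def build(z, name):
        pts = fibonacci_sphere(SPHERE_ATOMS, SPHERE_RADIUS)
        atoms = AtomSet(pts, np.full(SPHERE_ATOMS, z / SPHERE_ATOMS),
                        np.full(SPHERE_ATOMS, 1.0))
        grids = {}
        if with_grids:
            grids["electrostatic"] = sphere_dh_grid(z, SPHERE_RADIUS, solvent,
                                                    grid_side, grid_spacing)
        return Solute(atoms, stokes_radius=SPHERE_RADIUS, grids=grids, name=name)

    return SphereSystem(build(z1, "sphere1"), build(z2, "sphere2"), solvent)


# ---------------------------------------------------------------------------
# closed form and quadrature
# ---------------------------------------------------------------------------

def b22_analytic_longrange(pair: DHPair, lb: float) -> B22Result:
    """Closed-form long-range B22 from the second-order expansion of the
    Mayer function with the DH potential of mean force:

        B22 = 2πCβ e^(−κ(lb−a)) (κ·lb + 1)/κ² − πβ²C² e^(−2κ(lb−a))/(2κ),

    C = z_i z_j e²/(4π ε0 εr (1+κa)), β = 1/kBT.  Warns (and flags the
    result) when |w(lb)/kT| ≥ 0.5, where the truncated expansion degrades
    and the corresponding full-exponent integral may diverge for attractive
    pairs.
    """
    a, k = pair.contact_distance, pair.kappa
    if lb < a:
        raise ValueError("lower bound must be at least the contact distance")
    if k == 0:
        raise ValueError("closed form requires screening (kappa > 0)")
    from .constants import kT
    beta = 1.0 / kT(pair.temperature)
    c = pair.prefactor
    w_lb = abs(c) * np.exp(-k * (lb - a)) / lb * beta
    valid = w_lb < 0.5
    if not valid:
        warnings.warn(f"|w(lb)/kT| = {w_lb:.2f} >= 0.5: second-order "
                      "expansion unreliable at this lower bound")
    t1 = 2.0 * np.pi * c * beta * np.exp(-k * (lb - a)) * (k * lb + 1.0) / k**2
    t2 = np.pi * beta**2 * c**2 * np.exp(-2.0 * k * (lb - a)) / (2.0 * k)
    return B22Result(float(t1 - t2), "analytic", lb, expansion_valid=valid)


def b22_quadrature(w: Callable, lb: float, kt: float,
                   order: str = "full") -> B22Result:
    """Adaptive quadrature of −½ ∫_lb^∞ (e^(−w/kT) − 1) 4π r² dr ("full")
    or of its second-order expansion ("second").  ``w`` maps r (Å) to
    kcal/mol and must vanish at infinity."""
    if order not in ("full", "second"):
        raise ValueError("order must be 'full' or 'second'")

    if order == "full":
        def integrand(r):
            return -0.5 * np.expm1(-w(r) / kt) * 4.0 * np.pi * r * r
    else:
        def integrand(r):
            x = w(r) / kt
            return -0.5 * (-x + 0.5 * x * x) * 4.0 * np.pi * r * r

    val, err = quad(integrand, lb, np.inf, limit=400)
    if not np.isfinite(val) or (abs(val) > 1e-12 and err > 0.05 * abs(val)):
        raise RuntimeError(f"B22 quadrature did not converge (value {val}, "
                           f"error estimate {err})")
    return B22Result(float(val), f"quadrature[{order}]", lb)


def b22_hard_sphere(sigma: float) -> float:
    """Textbook hard-sphere value (2/3)πσ³ (used as a quadrature oracle)."""
    return 2.0 / 3.0 * np.pi * sigma**3


# ---------------------------------------------------------------------------
# lattice protocol
# ---------------------------------------------------------------------------

def lattice_vertices(box_side: float, lattice_n: int) -> np.ndarray:
    """Centers of a regular lattice_n³ lattice filling the box, centered on
    the origin (where the fixed particle sits)."""
    h = box_side / lattice_n
    ax = (np.arange(lattice_n) + 0.5) * h - box_side / 2.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _lattice_energies(system: SphereSystem, pos: np.ndarray, use_dh: bool,
                      chunk: int = 4000) -> np.ndarray:
    """Hybrid grid/DH pair energy at each lattice position (sphere 1 at the
    origin, sphere 2 at pos; orientations fixed; overlapping vertices get
    +inf).  Vectorized specialization of the pair model for the isotropic
    test system."""
    s1, s2 = system.solute1, system.solute2
    solvent = system.solvent
    d = np.linalg.norm(pos, axis=1)
    contact = system.contact_distance
    energy = np.full(len(pos), np.inf)
    grid1 = s1.grids.get("electrostatic")
    grid2 = s2.grids.get("electrostatic")
    from .electro import switch_radius
    r_switch = switch_radius(s1, s2)

    ok = d >= contact
    energy[ok] = 0.0

    in_grid = ok & (d < r_switch)
    idx = np.where(in_grid)[0]
    if len(idx):
        atoms2 = s2.effective_charges.positions
        atoms1 = s1.effective_charges.positions
        q2 = s2.effective_charges.charges
        q1 = s1.effective_charges.charges
        for lo in range(0, len(idx), chunk):
            sel = idx[lo:lo + chunk]
            # charges of 2 in the field of 1 (grid centered at origin)
            pts = pos[sel][:, None, :] + atoms2[None, :, :]
            r = np.linalg.norm(pts, axis=2)
            mask = r < grid1.cutoff_radius
            phi = np.zeros(r.shape)
            phi[mask] = grid_value(grid1, pts[mask])
            e12 = phi @ q2
            # charges of 1 in the field of 2 (grid centered at pos)
            pts = atoms1[None, :, :] - pos[sel][:, None, :]
            r = np.linalg.norm(pts, axis=2)
            mask = r < grid2.cutoff_radius
            phi = np.zeros(r.shape)
            phi[mask] = grid_value(grid2, pts[mask])
            e21 = phi @ q1
            energy[sel] = 0.5 * (e12 + e21)

    if use_dh:
        far = ok & (d >= r_switch)
        pair = system.dh_pair()
        energy[far] = dh_pmf(d[far], pair)
    return energy


def b22_lattice(system: SphereSystem, lb: float, use_dh: bool = True,
                box_side: float = 400.0, lattice_n: int = 100,
                subsets: tuple = (100, 100000), seed: int = 0) -> B22Result:
    """Lattice-integrated long-range B22.

    One particle is fixed at the box center, the other visits every vertex
    of a regular ``lattice_n``³ lattice in a ``box_side``³ box; overlapping
    vertices (center distance below contact) are excluded.  The energy at
    each remaining vertex comes from the hybrid pair model (grid term with
    the isotropic per-charge cutoff inside the switch radius; DH tail
    beyond it when ``use_dh``).  Then

        B22 = −½ Σ_{r_k ≥ lb} (e^(−E_k/kBT) − 1) ΔV,   ΔV = (box/lattice_n)³.

    Subset statistics: ``subsets = (n_subsets, subset_size)`` random subsets
    of the counted vertices, each rescaled to the full integration volume,
    give an unbiased subset mean and SD.
    """
    if lb < system.contact_distance:
        raise ValueError("lower bound lies inside the overlap region")
    pos = lattice_vertices(box_side, lattice_n)
    d = np.linalg.norm(pos, axis=1)
    energy = _lattice_energies(system, pos, use_dh)
    counted = (d >= lb) & np.isfinite(energy)
    kt = system.solvent.kT
    dv = (box_side / lattice_n) ** 3
    mayer = -np.expm1(-energy[counted] / kt)  # = −(e^(−E/kT) − 1)
    value = 0.5 * mayer.sum() * dv

    n_sub, sub_size = subsets
    subset_mean = subset_sd = None
    n_counted = int(counted.sum())
    if n_sub > 0 and n_counted > 0:
        rng = np.random.default_rng(seed)
        size = min(sub_size, n_counted)
        vals = np.empty(n_sub)
        v_total = n_counted * dv
        for s in range(n_sub):
            pick = rng.choice(n_counted, size=size, replace=False)
            vals[s] = 0.5 * mayer[pick].mean() * v_total
        subset_mean, subset_sd = float(vals.mean()), float(vals.std())
    return B22Result(float(value), "lattice", lb, subset_mean, subset_sd,
                     n_points=n_counted)


def debye_length_bound(system: SphereSystem, multiple: float = 1.0,
                       from_contact: bool = False) -> float:
    """Common lower bounds: ``multiple`` Debye lengths, optionally measured
    from the contact distance a (lb = a + n/κ) instead of from zero."""
    lb = multiple / system.solvent.kappa
    return system.contact_distance + lb if from_contact else lb
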