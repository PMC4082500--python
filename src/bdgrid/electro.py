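"""Pairwise interaction energies and forces.

Implements the four grid-based terms of the rigid-body interaction free
energy (electrostatic charge-on-grid, electrostatic desolvation, non-polar
desolvation, soft-core repulsion), the analytic Debye-Hückel (DH) screened
Coulomb potential of mean force between net-charged spheres, the hybrid
grid/DH switching scheme, and finite-difference forces and torques.

The hybrid scheme: inside the inscribed sphere of the partner's
electrostatic grid the charge-on-grid terms are used (with an isotropic
per-charge distance cutoff); once the center-to-center distance reaches the
inscribed-sphere radius, the molecule's potential is assumed centrosymmetric
and the full electrostatic term is *replaced* by the analytic DH interaction
of the net charges.  The two descriptions are never summed for one pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import COULOMB
from .model import (AtomSet, BoxSpec, PotentialGrid, Solute, SolventModel,
                    body_to_lab, quat_from_rotvec, quat_multiply,
                    wrap_minimum_image)

ENERGY_TERMS = ("electrostatic_grid", "dh_tail", "edesolv", "npdesolv", "softcore")


# ---------------------------------------------------------------------------
# Debye-Hückel theory
# ---------------------------------------------------------------------------

def inverse_debye_length(solvent: SolventModel) -> float:
    """Inverse Debye length κ in Å⁻¹ (proportional to √(ionic strength))."""
    return solvent.kappa


@dataclass
class DHPair:
    """Two net-charged spheres in a screened electrolyte.

    ``contact_distance`` is a = a_i + a_j; by convention each a is the
    solute's Stokes radius unless overridden.
    """

    z_i: float
    z_j: float
    contact_distance: float
    kappa: float
    relative_permittivity: float = 78.5
    temperature: float = 300.0

    def __post_init__(self):
        if self.contact_distance <= 0:
            raise ValueError("contact distance must be positive")

    @classmethod
    def from_solutes(cls, s1: Solute, s2: Solute, solvent: SolventModel) -> "DHPair":
        return cls(s1.net_charge, s2.net_charge, s1.stokes_radius + s2.stokes_radius,
                   solvent.kappa, solvent.relative_permittivity, solvent.temperature)

    @property
    def prefactor(self) -> float:
        """C = z_i z_j e²/(4π ε0 εr (1+κa)) in kcal·Å/mol, so that
        w(r) = C e^(−κ(r−a))/r."""
        return (self.z_i * self.z_j * COULOMB /
                (self.relative_permittivity * (1.0 + self.kappa * self.contact_distance)))


def dh_pmf(r, pair: DHPair):
    """Debye-Hückel potential of mean force w(r), kcal/mol.

    w(r) = z_i z_j e² e^(−κ(r−a)) / (4π ε0 εr r (1+κa)) for r ≥ a and +∞
    inside the hard-sphere contact distance a.  Scalar or array ``r``.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise ValueError("r must be positive")
    a, k = pair.contact_distance, pair.kappa
    w = pair.prefactor * np.exp(-k * (r_arr - a)) / r_arr
    # hard overlap is +inf regardless of charge sign
    w = np.where(r_arr < a, np.inf, w)
    return w if w.ndim else float(w)


def dh_force_magnitude(r, pair: DHPair):
    """−dw/dr for r ≥ a: radial force magnitude (positive = repulsive),
    kcal/mol/Å."""
    r_arr = np.asarray(r, dtype=float)
    a, k = pair.contact_distance, pair.kappa
    w = pair.prefactor * np.exp(-k * (r_arr - a)) / r_arr
    f = w * (k + 1.0 / r_arr)
    return f if f.ndim else float(f)


# ---------------------------------------------------------------------------
# grid interpolation
# ---------------------------------------------------------------------------

def _interpolator(grid: PotentialGrid) -> RegularGridInterpolator:
    interp = getattr(grid, "_interp", None)
    if interp is None:
        interp = RegularGridInterpolator(grid.axes(), grid.values,
                                         method="linear", bounds_error=True)
        grid._interp = interp
    return interp


def grid_value(grid: PotentialGrid, points):
    """Trilinear interpolation of the grid at one or more body-frame points.

    Points must lie inside the grid bounding box; callers apply cutoff
    logic before interpolating.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    vals = _interpolator(grid)(pts)
    return vals if np.asarray(points).ndim > 1 else float(vals[0])


def grid_charge_energy(grid: PotentialGrid, charges: AtomSet,
                       grid_center, charge_positions=None) -> float:
    """Σ_k q_k Φ(r_k) over charges within the grid's inscribed-sphere
    cutoff of ``grid_center`` (lab frame).  Charges at or beyond the cutoff
    contribute exactly zero.  Result in kcal/mol for an electrostatic grid.
    """
    if grid.kind != "electrostatic":
        raise ValueError("grid_charge_energy requires an electrostatic grid")
    pos = np.atleast_2d(charges.positions if charge_positions is None
                        else np.asarray(charge_positions, float))
    center = np.asarray(grid_center, dtype=float)
    rel = pos - center
    inside = np.linalg.norm(rel, axis=1) < grid.cutoff_radius
    if not inside.any():
        return 0.0
    phi = _interpolator(grid)(rel[inside] + grid.center)
    return float(np.dot(charges.charges[inside], phi))


def _grid_sum(grid: PotentialGrid, weights, lab_points, grid_center) -> float:
    """Σ w_k Φ(r_k) with the isotropic inscribed-sphere cutoff (generic
    helper for the desolvation and soft-core terms)."""
    pts = np.atleast_2d(np.asarray(lab_points, float))
    rel = pts - np.asarray(grid_center, float)
    inside = np.linalg.norm(rel, axis=1) < grid.cutoff_radius
    if not inside.any():
        return 0.0
    phi = _interpolator(grid)(rel[inside] + grid.center)
    return float(np.dot(np.asarray(weights, float)[inside], phi))


# ---------------------------------------------------------------------------
# pair energy
# ---------------------------------------------------------------------------

@dataclass
class PairEnergyBreakdown:
    """Per-term interaction free energy of one solute pair, kcal/mol."""

    electrostatic_grid: float = 0.0
    dh_tail: float = 0.0
    edesolv: float = 0.0
    npdesolv: float = 0.0
    softcore: float = 0.0

    @property
    def total(self) -> float:
        return (self.electrostatic_grid + self.dh_tail + self.edesolv +
                self.npdesolv + self.softcore)

    def as_dict(self) -> dict:
        return {t: getattr(self, t) for t in ENERGY_TERMS} | {"total": self.total}


def charge_extent(s: Solute) -> float:
    """Largest body-frame distance of an effective charge from the solute
    center (rotation-invariant)."""
    return float(np.linalg.norm(s.effective_charges.positions, axis=1).max())


def switch_radius(s1: Solute, s2: Solute) -> float:
    """Grid→DH transition distance for a pair.

    The transition occurs at the shortest center-to-center distance at
    which a partner's charge can reach a grid boundary, i.e.
    min(cutoff₁ − extent₂, cutoff₂ − extent₁): below it every charge lies
    inside the partner's inscribed sphere and the grid terms are complete;
    at and beyond it the potential is taken as centrosymmetric and the DH
    net-charge term substitutes the whole electrostatic term.  0 when
    neither solute carries an electrostatic grid (pure DH spheres).
    """
    if "electrostatic" not in s1.grids or "electrostatic" not in s2.grids:
        return 0.0
    r = min(s1.grids["electrostatic"].cutoff_radius - charge_extent(s2),
            s2.grids["electrostatic"].cutoff_radius - charge_extent(s1))
    return max(r, 0.0)


def _require_both(kind: str, s1: Solute, s2: Solute):
    have1, have2 = kind in s1.grids, kind in s2.grids
    if have1 != have2:
        raise ValueError(f"grid kind {kind!r} present on only one solute of the pair")
    return have1


def pair_energy(s1: Solute, s2: Solute, pos1, quat1, pos2, quat2,
                solvent: SolventModel, use_dh: bool = True,
                dh_cutoff: Optional[float] = None,
                box: Optional[BoxSpec] = None) -> PairEnergyBreakdown:
    """Interaction free energy of a solute pair, term by term.

    Grid terms follow the charge-on-grid formalism with the isotropic
    per-charge cutoff; beyond the switch radius the electrostatic term is
    replaced by the DH potential of the net charges (zero when ``use_dh``
    is false).  ``dh_cutoff`` truncates the DH tail (None = no truncation).
    Positions may be unwrapped; with a periodic ``box`` the minimum-image
    separation is used.
    """
    pos1 = np.asarray(pos1, float)
    pos2 = np.asarray(pos2, float)
    sep = pos2 - pos1
    if box is not None and box.periodic:
        sep = wrap_minimum_image(sep, box)
    d = float(np.linalg.norm(sep))
    # evaluate everything with solute 1 at the origin and solute 2 at sep
    lab1 = body_to_lab(s1.atoms.positions, np.zeros(3), quat1)
    lab2 = body_to_lab(s2.atoms.positions, sep, quat2)
    eff1 = body_to_lab(s1.effective_charges.positions, np.zeros(3), quat1)
    eff2 = body_to_lab(s2.effective_charges.positions, sep, quat2)

    out = PairEnergyBreakdown()
    for kind in set(s1.grids) | set(s2.grids):
        _require_both(kind, s1, s2)
    r_switch = switch_radius(s1, s2)

    if d < r_switch and "electrostatic" in s1.grids:
        e = 0.5 * grid_charge_energy(s1.grids["electrostatic"], s2.effective_charges,
                                     np.zeros(3), charge_positions=eff2)
        e += 0.5 * grid_charge_energy(s2.grids["electrostatic"], s1.effective_charges,
                                      sep, charge_positions=eff1)
        out.electrostatic_grid = e
    elif use_dh:
        if dh_cutoff is None or d <= dh_cutoff:
            pair = DHPair.from_solutes(s1, s2, solvent)
            out.dh_tail = float(dh_pmf(max(d, 1e-12), pair))

    if "edesolv" in s1.grids:
        q2sq = s2.effective_charges.charges**2
        q1sq = s1.effective_charges.charges**2
        g1, g2 = s1.grids["edesolv"], s2.grids["edesolv"]
        out.edesolv = (_grid_sum(g1, q2sq, eff2, np.zeros(3)) +
                       _grid_sum(g2, q1sq, eff1, sep))

    if "npdesolv" in s1.grids:
        if s1.atoms.sasa is None or s2.atoms.sasa is None:
            raise ValueError("non-polar desolvation term requires per-atom SASA")
        g1, g2 = s1.grids["npdesolv"], s2.grids["npdesolv"]
        out.npdesolv = (_grid_sum(g1, s2.atoms.sasa, lab2, np.zeros(3)) +
                        _grid_sum(g2, s1.atoms.sasa, lab1, sep))

    if "softcore" in s1.grids:
        ones1 = np.ones(len(s1.atoms))
        ones2 = np.ones(len(s2.atoms))
        g1, g2 = s1.grids["softcore"], s2.grids["softcore"]
        out.softcore = (_grid_sum(g1, ones2, lab2, np.zeros(3)) +
                        _grid_sum(g2, ones1, lab1, sep))
    return out


def pair_forces_torques(s1: Solute, s2: Solute, pos1, quat1, pos2, quat2,
                        solvent: SolventModel, use_dh: bool = True,
                        dh_cutoff: Optional[float] = None,
                        box: Optional[BoxSpec] = None,
                        delta: float = 0.1, delta_theta: float = 0.01):
    """Central finite-difference forces (kcal/mol/Å) and torques (kcal/mol)
    on both solutes.

    Returns (F1, T1, F2, T2).  Steps ``delta`` (Å) and ``delta_theta``
    (rad) control the O(δ²) truncation error.
    """
    if delta <= 0 or delta_theta <= 0:
        raise ValueError("finite-difference steps must be positive")

    def energy(p1, q1, p2, q2):
        return pair_energy(s1, s2, p1, q1, p2, q2, solvent, use_dh, dh_cutoff, box).total

    pos1 = np.asarray(pos1, float)
    pos2 = np.asarray(pos2, float)
    F1, F2 = np.zeros(3), np.zeros(3)
    T1, T2 = np.zeros(3), np.zeros(3)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = delta
        F1[ax] = -(energy(pos1 + e, quat1, pos2, quat2) -
                   energy(pos1 - e, quat1, pos2, quat2)) / (2 * delta)
        F2[ax] = -(energy(pos1, quat1, pos2 + e, quat2) -
                   energy(pos1, quat1, pos2 - e, quat2)) / (2 * delta)
        rv = np.zeros(3)
        rv[ax] = delta_theta
        qp, qm = quat_from_rotvec(rv), quat_from_rotvec(-rv)
        T1[ax] = -(energy(pos1, quat_multiply(qp, quat1), pos2, quat2) -
                   energy(pos1, quat_multiply(qm, quat1), pos2, quat2)) / (2 * delta_theta)
        T2[ax] = -(energy(pos1, quat1, pos2, quat_multiply(qp, quat2)) -
                   energy(pos1, quat1, pos2, quat_multiply(qm, quat2))) / (2 * delta_theta)
    return F1, T1, F2, T2


def switch_discontinuity(s1: Solute, s2: Solute, solvent: SolventModel,
                         direction=(1.0, 0.0, 0.0), eps: float = 1e-3) -> dict:
    """Diagnostic: energy jump across the grid/DH switch radius along a
    given direction (the hybrid scheme is not interpolated at the boundary,
    which can leave a discontinuity for non-centrosymmetric potentials)."""
    r_sw = switch_radius(s1, s2)
    if r_sw == 0.0:
        return {"switch_radius": 0.0, "jump": 0.0, "inside": 0.0, "outside": 0.0}
    u = np.asarray(direction, float)
    u = u / np.linalg.norm(u)
    q = np.array([1.0, 0, 0, 0])
    e_in = pair_energy(s1, s2, np.zeros(3), q, u * (r_sw - eps), q, solvent).total
    e_out = pair_energy(s1, s2, np.zeros(3), q, u * (r_sw + eps), q, solvent).total
    return {"switch_radius": r_sw, "jump": e_out - e_in,
            "inside": e_in, "outside": e_out}


# ---------------------------------------------------------------------------
# soft-core grid construction
# ---------------------------------------------------------------------------

def softcore_from_atoms(atoms: AtomSet, side: float, spacing: float,
                        exponent: int = 6, prefactor: float = 1.0,
                        cap: float = 100.0) -> PotentialGrid:
    """Build a soft-core repulsion grid Σ_atoms ε (σ_atom/d)^n on a cubic
    grid of the given side length, truncated at ``cap`` kcal/mol.

    The inverse-power form is smooth, avoiding abrupt force changes at
    close contact; σ_atom is the atomic radius.
    """
    from .model import grid_nodes_for_extent
    n_nodes = grid_nodes_for_extent(side, spacing)
    half = (n_nodes - 1) * spacing / 2.0
    ax = np.arange(n_nodes) * spacing - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    vals = np.zeros_like(X)
    for p, sigma in zip(atoms.positions, atoms.radii):
        if sigma <= 0:
            continue
        d = np.sqrt((X - p[0])**2 + (Y - p[1])**2 + (Z - p[2])**2)
        d = np.maximum(d, 1e-6)
        vals += prefactor * (sigma / d) ** exponent
    np.minimum(vals, cap, out=vals)
    return PotentialGrid("softcore", origin=np.array([-half, -half, -half]),
                         spacing=spacing, values=vals)
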