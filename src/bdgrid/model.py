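"""Domain types shared by all modules.

Conventions
-----------
* Units: Å, ps, kcal/mol, elementary charge e, Kelvin.
* The "center" of a solute is the center of geometry of its atoms; solute
  atoms are stored in a body frame whose origin is that center.
* Orientations are unit quaternions (w, x, y, z).
* Interaction grids are node-centered regular cubic scalar fields: the
  value at index (i, j, k) lives at ``origin + (i·h, j·h, k·h)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import COULOMB, MOLAR_TO_A3, kT

GRID_KINDS = ("electrostatic", "edesolv", "npdesolv", "softcore")


# ---------------------------------------------------------------------------
# atoms
# ---------------------------------------------------------------------------

@dataclass
class AtomSet:
    """A set of point atoms: positions (Å), partial charges (e), radii (Å)
    and optional per-atom solvent-accessible surface areas (Å²)."""

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    sasa: Optional[np.ndarray] = None
    names: Optional[list] = None

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.positions)
        if self.positions.shape != (n, 3):
            raise ValueError("positions must be (n, 3)")
        if self.charges.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("charges/radii length inconsistent with positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite atom positions")
        if np.any(self.radii < 0):
            raise ValueError("negative atomic radius")
        if self.sasa is not None:
            self.sasa = np.asarray(self.sasa, dtype=float)
            if self.sasa.shape != (n,):
                raise ValueError("sasa length inconsistent with positions")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    def center_of_geometry(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def translated(self, shift) -> "AtomSet":
        return AtomSet(self.positions + np.asarray(shift, float), self.charges.copy(),
                       self.radii.copy(),
                       None if self.sasa is None else self.sasa.copy(), self.names)


# ---------------------------------------------------------------------------
# grids
# ---------------------------------------------------------------------------

@dataclass
class PotentialGrid:
    """Regular cubic scalar field holding one precomputed interaction
    potential of a solute.

    ``values[i, j, k]`` is the potential at ``origin + (i, j, k) * spacing``
    relative to the solute's center of geometry (the grid is centered on it).
    ``cutoff_radius`` is the radius of the largest sphere inscribed in the
    grid box; interactions are only evaluated inside it.
    """

    kind: str
    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self):
        if self.kind not in GRID_KINDS:
            raise ValueError(f"unknown grid kind {self.kind!r}")
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("grid values must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self):
        return self.values.shape

    @property
    def side_lengths(self) -> np.ndarray:
        return (np.array(self.shape) - 1) * self.spacing

    @property
    def cutoff_radius(self) -> float:
        """Radius of the largest sphere enclosed by the grid."""
        return float(self.side_lengths.min()) / 2.0

    @property
    def center(self) -> np.ndarray:
        return self.origin + self.side_lengths / 2.0

    def axes(self):
        return tuple(self.origin[d] + self.spacing * np.arange(self.shape[d])
                     for d in range(3))


def grid_nodes_for_extent(extent: float, spacing: float) -> int:
    """Number of nodes per axis needed to cover ``extent`` Å at ``spacing`` Å.

    A grid spanning L Å with node spacing h has L/h cells and L/h + 1 nodes,
    e.g. 201 nodes per axis for a 200 Å extent at 1 Å spacing.
    """
    if extent <= 0 or spacing <= 0:
        raise ValueError("extent and spacing must be positive")
    return int(np.ceil(extent / spacing - 1e-9)) + 1


# ---------------------------------------------------------------------------
# solvent
# ---------------------------------------------------------------------------

@dataclass
class SolventModel:
    """Continuum electrolyte: temperature, relative permittivity and ionic
    composition, from which the inverse Debye length κ follows.

    ``species`` is a list of (concentration mol/L, integer valence) pairs.
    κ² = (e²/(ε0 εr kB T)) Σ ρ_i z_i²  with ρ_i as number densities; for a
    1:1 electrolyte at ionic strength I both species enter at concentration I.
    """

    temperature: float = 300.0
    relative_permittivity: float = 78.5
    species: Sequence = field(default_factory=list)
    viscosity_cp: float = 0.89

    def __post_init__(self):
        for conc, _z in self.species:
            if conc < 0:
                raise ValueError("negative ion concentration")

    @classmethod
    def monovalent(cls, ionic_strength: float, temperature: float = 300.0,
                   relative_permittivity: float = 78.5, **kw) -> "SolventModel":
        """1:1 electrolyte at the given ionic strength (mol/L)."""
        species = [] if ionic_strength == 0 else [(ionic_strength, 1), (ionic_strength, -1)]
        return cls(temperature, relative_permittivity, species, **kw)

    @property
    def kT(self) -> float:
        return kT(self.temperature)

    @property
    def bjerrum_length(self) -> float:
        return COULOMB / (self.relative_permittivity * self.kT)

    @property
    def kappa(self) -> float:
        """Inverse Debye length, Å⁻¹ (0 for pure water)."""
        s = sum(conc * MOLAR_TO_A3 * z * z for conc, z in self.species)
        return float(np.sqrt(4.0 * np.pi * self.bjerrum_length * s))

    @property
    def debye_length(self) -> float:
        k = self.kappa
        return np.inf if k == 0 else 1.0 / k


# ---------------------------------------------------------------------------
# solutes
# ---------------------------------------------------------------------------

@dataclass
class Solute:
    """A rigid-body solute: body-frame atoms, the (possibly reduced)
    effective-charge set used for electrostatics, per-solute scalars and the
    attached interaction grids."""

    atoms: AtomSet
    stokes_radius: float
    net_charge: Optional[float] = None
    effective_charges: Optional[AtomSet] = None
    volume: Optional[float] = None
    grids: dict = field(default_factory=dict)
    name: str = "solute"

    def __post_init__(self):
        if self.stokes_radius <= 0:
            raise ValueError("stokes_radius must be positive")
        cog = self.atoms.center_of_geometry()
        if np.any(np.abs(cog) > 1e-6):
            # recenter to the body-frame convention
            self.atoms = self.atoms.translated(-cog)
            if self.effective_charges is not None:
                self.effective_charges = self.effective_charges.translated(-cog)
        if self.effective_charges is None:
            self.effective_charges = self.atoms
        if self.net_charge is None:
            self.net_charge = self.effective_charges.total_charge
        elif abs(self.net_charge - self.effective_charges.total_charge) > 1e-6:
            raise ValueError("net_charge inconsistent with effective charges")
        if self.volume is None:
            self.volume = 4.0 / 3.0 * np.pi * self.stokes_radius**3
        for kind in self.grids:
            if kind not in GRID_KINDS:
                raise ValueError(f"unknown grid kind {kind!r}")

    @property
    def has_grids(self) -> bool:
        return bool(self.grids)


# ---------------------------------------------------------------------------
# box / state
# ---------------------------------------------------------------------------

@dataclass
class BoxSpec:
    """Cubic periodic (or open) simulation box."""

    side: float
    periodic: bool = True

    def __post_init__(self):
        if self.side <= 0:
            raise ValueError("box side must be positive")

    @property
    def volume(self) -> float:
        return self.side**3


def wrap_minimum_image(displacement, box: BoxSpec):
    """Minimum-image convention: wrap each displacement component into
    [−side/2, side/2).  Non-periodic boxes return the input unchanged
    (with a warning)."""
    d = np.asarray(displacement, dtype=float)
    if not box.periodic:
        warnings.warn("minimum image requested for a non-periodic box; returning input")
        return d
    L = box.side
    return d - L * np.floor(d / L + 0.5)


def wrap_positions(positions, box: BoxSpec):
    """Wrap absolute positions into the primary cell [0, side) and return
    (wrapped positions, image shift counts)."""
    p = np.asarray(positions, dtype=float)
    if not box.periodic:
        return p, np.zeros_like(p, dtype=int)
    img = np.floor(p / box.side).astype(int)
    return p - img * box.side, img


# ---------------------------------------------------------------------------
# quaternions
# ---------------------------------------------------------------------------

def quat_normalize(q):
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q)


def quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_from_rotvec(v):
    """Unit quaternion for a rotation vector (axis * angle, rad)."""
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v)
    if theta < 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = v / theta
    return np.concatenate([[np.cos(theta / 2.0)], np.sin(theta / 2.0) * axis])


def quat_to_matrix(q):
    w, x, y, z = quat_normalize(q)
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def random_quaternion(rng) -> np.ndarray:
    """Uniform random orientation (Shoemake's method)."""
    u1, u2, u3 = rng.random(3)
    return np.array([
        np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
        np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
        np.sqrt(u1) * np.sin(2 * np.pi * u3),
        np.sqrt(u1) * np.cos(2 * np.pi * u3),
    ])


def body_to_lab(body_positions, center, quaternion):
    """Map body-frame coordinates to the lab frame."""
    R = quat_to_matrix(quaternion)
    return np.asarray(center, float) + np.asarray(body_positions, float) @ R.T


def lab_to_body(lab_positions, center, quaternion):
    R = quat_to_matrix(quaternion)
    return (np.asarray(lab_positions, float) - np.asarray(center, float)) @ R


@dataclass
class SimulationState:
    """Instantaneous configuration: per-solute centers (lab frame, Å) and
    orientations (unit quaternions)."""

    time: float
    positions: np.ndarray
    quaternions: np.ndarray

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.quaternions = np.atleast_2d(np.asarray(self.quaternions, dtype=float))
        norms = np.linalg.norm(self.quaternions, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("quaternions must be normalized")

    @property
    def n_solutes(self) -> int:
        return len(self.positions)
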