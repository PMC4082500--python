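"""File formats and run configuration.

Formats: PQR for atoms (whitespace-separated ATOM/HETATM records carrying
position, partial charge and radius), OpenDX scalar fields for interaction
grids (the "regular positions, regular connections" dialect emitted by
common Poisson-Boltzmann solvers, via gridData), a compressed npz container
for trajectories (see :class:`bdgrid.engine.Trajectory`) and TSV for
analysis tables.  Run configurations are flat YAML with sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from gridData import Grid as _DXGrid

from .model import AtomSet, BoxSpec, PotentialGrid, Solute, SolventModel

_PQR_RECORDS = ("ATOM", "HETATM")


# ---------------------------------------------------------------------------
# PQR
# ---------------------------------------------------------------------------

def read_pqr(path) -> AtomSet:
    """Read a whitespace-delimited PQR file.

    Expected record layout: ``ATOM serial name resname [chain] resseq
    x y z charge radius``; TER/REMARK/other records are skipped.
    """
    positions, charges, radii, names = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields or fields[0] not in _PQR_RECORDS:
                continue
            try:
                # chain id is optional: numbers sit in the last five columns
                x, y, z, q, r = (float(v) for v in fields[-5:])
            except (ValueError, IndexError) as err:
                raise ValueError(f"{path}: malformed PQR record at line "
                                 f"{lineno}: {line.rstrip()}") from err
            positions.append((x, y, z))
            charges.append(q)
            radii.append(r)
            names.append(fields[2] if len(fields) > 2 else "X")
    if not positions:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    return AtomSet(np.array(positions), np.array(charges), np.array(radii),
                   names=names)


def write_pqr(atoms: AtomSet, path, resname: str = "SOL") -> None:
    """Write an AtomSet as whitespace-delimited PQR (full float precision
    is not required by the dialect; we print 6 significant decimals)."""
    with open(path, "w") as fh:
        fh.write("REMARK generated by bdgrid\n")
        for i in range(len(atoms)):
            name = atoms.names[i] if atoms.names else f"A{i + 1}"
            x, y, z = atoms.positions[i]
            fh.write(f"ATOM {i + 1:6d} {name:<4s} {resname:<4s} {1:4d} "
                     f"{x:12.6f} {y:12.6f} {z:12.6f} "
                     f"{atoms.charges[i]:13.9f} {atoms.radii[i]:8.4f}\n")
        fh.write("TER\nEND\n")


# ---------------------------------------------------------------------------
# OpenDX grids
# ---------------------------------------------------------------------------

def read_dx(path, kind: Optional[str] = None) -> PotentialGrid:
    """Read an OpenDX scalar field.  Only uniform cubic spacing is
    supported.  The grid kind is inferred from a ``# bdgrid kind: <kind>``
    comment when present, else must be supplied."""
    if kind is None:
        with open(path) as fh:
            for line in fh:
                if line.startswith("# bdgrid kind:"):
                    kind = line.split(":", 1)[1].strip()
                    break
                if not line.startswith("#"):
                    break
    if kind is None:
        raise ValueError(f"{path}: grid kind not found in header; pass kind=")
    g = _DXGrid(str(path))
    deltas = np.array([g.delta[i] for i in range(3)], dtype=float).ravel()
    if not np.allclose(deltas, deltas[0], rtol=1e-8):
        raise ValueError(f"{path}: non-uniform grid spacing {deltas}; "
                         "only uniform cubic grids are supported")
    return PotentialGrid(kind, origin=np.asarray(g.origin, float),
                         spacing=float(deltas[0]), values=np.asarray(g.grid))


def write_dx(grid: PotentialGrid, path) -> None:
    """Write a PotentialGrid as OpenDX, tagging the kind in a comment."""
    g = _DXGrid(grid.values, origin=grid.origin,
                delta=[grid.spacing] * 3)
    g.export(str(path), typequote='"')
    # prepend the kind comment for round-tripping
    text = Path(path).read_text()
    Path(path).write_text(f"# bdgrid kind: {grid.kind}\n{text}")


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_table(path, columns: dict) -> None:
    """Write named columns as TSV at 6 significant digits."""
    keys = list(columns)
    arrs = [np.asarray(columns[k]) for k in keys]
    with open(path, "w") as fh:
        fh.write("\t".join(keys) + "\n")
        for row in zip(*arrs):
            fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class SoluteEntry:
    pqr: str
    stokes_radius: float
    copies: int = 1
    net_charge: Optional[float] = None
    grids: dict = field(default_factory=dict)  # kind -> dx path


@dataclass
class RunConfig:
    """Structured run configuration (YAML, flat key-value with sections:
    ``solutes``, ``box``, ``solvent``, ``bd``)."""

    solutes: list
    box_side: float
    ionic_strength: float = 0.005
    temperature: float = 300.0
    relative_permittivity: float = 78.5
    viscosity_cp: float = 0.89
    dt: float = 0.5
    n_steps: int = 1000
    record_every: float = 500.0
    seed: int = 0
    use_dh: bool = True
    use_hydro: bool = True
    dh_cutoff_factor: float = 4.0
    rcut_factor: float = 4.0
    equilibration_fraction: float = 0.2

    @classmethod
    def load(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        entries = []
        for s in raw.get("solutes", []):
            entry = SoluteEntry(
                pqr=str(base / s["pqr"]),
                stokes_radius=float(s["stokes_radius"]),
                copies=int(s.get("copies", 1)),
                net_charge=s.get("net_charge"),
                grids={k: str(base / v) for k, v in s.get("grids", {}).items()})
            if not Path(entry.pqr).exists():
                raise FileNotFoundError(entry.pqr)
            for p in entry.grids.values():
                if not Path(p).exists():
                    raise FileNotFoundError(p)
            entries.append(entry)
        box = raw.get("box", {})
        solv = raw.get("solvent", {})
        bd = raw.get("bd", {})
        return cls(
            solutes=entries,
            box_side=float(box["side"]),
            ionic_strength=float(solv.get("ionic_strength", 0.005)),
            temperature=float(solv.get("temperature", 300.0)),
            relative_permittivity=float(solv.get("relative_permittivity", 78.5)),
            viscosity_cp=float(solv.get("viscosity_cp", 0.89)),
            dt=float(bd.get("dt", 0.5)),
            n_steps=int(bd.get("n_steps", 1000)),
            record_every=float(bd.get("record_every", 500.0)),
            seed=int(bd.get("seed", 0)),
            use_dh=bool(bd.get("use_dh", True)),
            use_hydro=bool(bd.get("use_hydro", True)),
            dh_cutoff_factor=float(bd.get("dh_cutoff_factor", 4.0)),
            rcut_factor=float(bd.get("rcut_factor", 4.0)),
            equilibration_fraction=float(bd.get("equilibration_fraction", 0.2)))

    def build_system(self):
        """Instantiate (solutes, box, solvent) from the configuration."""
        solutes = []
        for entry in self.solutes:
            atoms = read_pqr(entry.pqr)
            grids = {k: read_dx(p, kind=k) for k, p in entry.grids.items()}
            for _ in range(entry.copies):
                solutes.append(Solute(atoms, stokes_radius=entry.stokes_radius,
                                      net_charge=entry.net_charge, grids=grids,
                                      name=Path(entry.pqr).stem))
        box = BoxSpec(self.box_side)
        solvent = SolventModel.monovalent(self.ionic_strength, self.temperature,
                                          self.relative_permittivity,
                                          viscosity_cp=self.viscosity_cp)
        return solutes, box, solvent
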