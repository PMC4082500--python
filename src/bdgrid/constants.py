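"""Physical constants in the package's working units.

Working units throughout: length Å, time ps, energy kcal/mol, charge in
elementary charges e, temperature K.  All constants are derived from SI
values in :mod:`scipy.constants` at import time so they can be audited
against CODATA.
"""

import numpy as np
from scipy import constants as _si

#: Boltzmann constant, kcal/mol/K
KB = _si.k * _si.N_A / _si.calorie / 1000.0

#: Coulomb constant e² / (4 π ε0), kcal·Å/mol per e²  (≈ 332.06)
COULOMB = _si.e**2 / (4.0 * np.pi * _si.epsilon_0) * _si.N_A * 1e10 / (_si.calorie * 1000.0)

#: Avogadro constant, 1/mol
N_A = _si.N_A

#: mol/L -> number density in Å⁻³
MOLAR_TO_A3 = _si.N_A * 1e-27

#: m²/s -> Å²/ps
M2S_TO_A2PS = 1e8


def kT(temperature: float) -> float:
    """Thermal energy kB·T in kcal/mol."""
    return KB * temperature


def bjerrum_length(temperature: float, relative_permittivity: float) -> float:
    """Bjerrum length λB = e²/(4π ε0 εr kB T) in Å.

    Distance at which two unit charges interact with thermal energy;
    ≈ 7.1 Å in water at 300 K.
    """
    return COULOMB / (relative_permittivity * kT(temperature))


def stokes_einstein_dt(stokes_radius: float, temperature: float,
                       viscosity_cp: float = 0.89) -> float:
    """Translational diffusion coefficient at infinite dilution, Å²/ps.

    D0 = kB T / (6 π η σ) for a sphere of hydrodynamic radius
    ``stokes_radius`` (Å) in a solvent of viscosity ``viscosity_cp`` (cP).
    """
    d_si = _si.k * temperature / (6.0 * np.pi * viscosity_cp * 1e-3 * stokes_radius * 1e-10)
    return d_si * M2S_TO_A2PS


def stokes_einstein_dr(stokes_radius: float, temperature: float,
                       viscosity_cp: float = 0.89) -> float:
    """Rotational diffusion coefficient at infinite dilution, rad²/ps.

    D0r = kB T / (8 π η σ³).
    """
    d_si = _si.k * temperature / (8.0 * np.pi * viscosity_cp * 1e-3 * (stokes_radius * 1e-10) ** 3)
    return d_si / 1e12  # 1/s -> 1/ps
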