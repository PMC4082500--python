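"""Solution observables from trajectories.

Center-to-center radial distribution function g(r), static structure factor

    S(q) = 1 + 4π n_p ∫ h(r) sin(qr)/(qr) r² dr,   h = g − 1,

oblate-ellipsoid form factor P(q), the normalized small-angle scattering
intensity I(q)/(A n_p) = P(q) S(q), a g(r) convergence report and the
long-time self-diffusion coefficient from the ensemble mean-squared
displacement.  S(q→0) is the normalized isothermal osmotic compressibility
n_p kB T χ_T, which long-range repulsion suppresses.

q grids are in nm⁻¹ on the public surface (the convention of small-angle
scattering plots); distances are Å, so q is converted internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .engine import Trajectory
from .model import BoxSpec, wrap_minimum_image

NM_PER_A = 0.1  # q[Å⁻¹] = q[nm⁻¹] / 10


@dataclass
class RadialProfile:
    r: np.ndarray          # bin centers, Å
    g: np.ndarray          # g(r)
    counts: np.ndarray
    number_density: float  # Å⁻³

    @property
    def h(self) -> np.ndarray:
        """Total correlation function h(r) = g(r) − 1."""
        return self.g - 1.0


@dataclass
class Spectrum:
    q: np.ndarray                      # nm⁻¹
    s: Optional[np.ndarray] = None     # structure factor
    p: Optional[np.ndarray] = None     # form factor
    intensity: Optional[np.ndarray] = None  # I(q)/(A n_p)


def default_q_grid(n: int = 200, q_min: float = 0.05, q_max: float = 4.0) -> np.ndarray:
    """Default scattering-vector grid, nm⁻¹."""
    return np.linspace(q_min, q_max, n)


# ---------------------------------------------------------------------------
# g(r)
# ---------------------------------------------------------------------------

def _pair_distances(frame_positions, box: BoxSpec) -> np.ndarray:
    n = len(frame_positions)
    iu = np.triu_indices(n, k=1)
    sep = frame_positions[iu[0]] - frame_positions[iu[1]]
    if box.periodic:
        sep = wrap_minimum_image(sep, box)
    return np.linalg.norm(sep, axis=1)


def radial_distribution(traj: Trajectory, bin_width: float = 1.0,
                        r_max: Optional[float] = None,
                        skip_fraction: float = 0.0) -> RadialProfile:
    """PBC-normalized center-to-center pair histogram.

    counts / (ideal-gas shell counts); ``skip_fraction`` discards the
    leading fraction of frames (equilibration).
    """
    if traj.n_solutes < 2:
        raise ValueError("g(r) needs at least two solutes")
    box = traj.box
    if r_max is None:
        r_max = box.side / 2.0
    if r_max > box.side / 2.0 + 1e-9:
        raise ValueError("r_max must not exceed half the box side")
    first = int(np.floor(skip_fraction * traj.n_frames))
    frames = traj.positions[first:]
    if len(frames) == 0:
        raise ValueError("no frames left after equilibration skip")
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for f in frames:
        d = _pair_distances(f, box)
        c, _ = np.histogram(d, bins=edges)
        counts += c
    n = traj.n_solutes
    n_p = n / box.volume
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    # ideal-gas expectation per bin: N(N−1)/2 · shell/V per frame
    ideal = len(frames) * 0.5 * n * (n - 1) * shell / box.volume
    g = counts / ideal
    centers = 0.5 * (edges[1:] + edges[:-1])
    return RadialProfile(centers, g, counts, n_p)


# ---------------------------------------------------------------------------
# S(q), P(q), I(q)
# ---------------------------------------------------------------------------

def structure_factor(profile: RadialProfile, q=None,
                     taper: bool = False) -> Spectrum:
    """Fourier transform of h(r) (trapezoidal, truncated at the profile's
    extent).  ``taper`` applies a half-cosine window over the outer half of
    the r range to suppress truncation ringing.  q in nm⁻¹; q = 0 is handled
    by the sin(x)/x → 1 limit."""
    if q is None:
        q = default_q_grid()
    q = np.asarray(q, dtype=float)
    r = profile.r
    h = profile.h.copy()
    if taper:
        r_max = r[-1]
        outer = r > 0.5 * r_max
        h[outer] *= 0.5 * (1.0 + np.cos(np.pi * (r[outer] - 0.5 * r_max) / (0.5 * r_max)))
    qa = q[:, None] * NM_PER_A  # Å⁻¹
    x = qa * r[None, :]
    sinc = np.where(np.abs(x) < 1e-12, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
    integrand = h[None, :] * sinc * r[None, :] ** 2
    s = 1.0 + 4.0 * np.pi * profile.number_density * np.trapezoid(integrand, r, axis=1)
    return Spectrum(q=q, s=s)


def s_q_zero(profile: RadialProfile) -> float:
    """Long-wavelength limit S(q→0) = 1 + 4π n_p ∫ h r² dr (the normalized
    isothermal osmotic compressibility n_p kB T χ_T)."""
    return float(1.0 + 4.0 * np.pi * profile.number_density *
                 np.trapezoid(profile.h * profile.r**2, profile.r))


def _sphere_amplitude(u):
    """3(sin u − u cos u)/u³ with the u→0 limit of 1."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-6
    us = np.where(small, 1.0, u)
    amp = 3.0 * (np.sin(us) - us * np.cos(us)) / us**3
    return np.where(small, 1.0 - u**2 / 10.0, amp)


def oblate_form_factor(q, a: float = 17.5, b: float = 47.4,
                       n_alpha: int = 256) -> np.ndarray:
    """Orientationally averaged form factor of an oblate ellipsoid with
    semi-axis of revolution ``a`` and equatorial radius ``b`` (Å):

        P(q) = ∫₀^{π/2} [3(sin u − u cos u)/u³]² sin α dα,
        u = q √(a² cos²α + b² sin²α),

    normalized so that P(0) = 1 exactly.  q in nm⁻¹; Gauss-Legendre in
    cos α with ``n_alpha`` nodes.  a = b reduces to the homogeneous-sphere
    form factor."""
    if a <= 0 or b <= 0:
        raise ValueError("semi-axes must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    # integrate over t = cos α uniformly on [0, 1]
    t, wts = np.polynomial.legendre.leggauss(n_alpha)
    t = 0.5 * (t + 1.0)
    wts = 0.5 * wts
    radius = np.sqrt(a * a * t**2 + b * b * (1.0 - t**2))  # (n_alpha,)
    u = (q[:, None] * NM_PER_A) * radius[None, :]
    p = (_sphere_amplitude(u) ** 2) @ wts
    return np.where(q == 0.0, 1.0, p)


def normalized_intensity(spectrum: Spectrum) -> Spectrum:
    """I(q)/(A n_p) = P(q) S(q) on the spectrum's common q grid."""
    if spectrum.s is None or spectrum.p is None:
        raise ValueError("spectrum must carry both S(q) and P(q)")
    if len(spectrum.s) != len(spectrum.p):
        raise ValueError("S and P are on different q grids")
    return Spectrum(q=spectrum.q, s=spectrum.s, p=spectrum.p,
                    intensity=spectrum.p * spectrum.s)


def debye_structure_factor(positions, q, box: Optional[BoxSpec] = None) -> np.ndarray:
    """Direct Debye double sum S(q) = 1 + (2/N) Σ_{i<j} sin(q d_ij)/(q d_ij)
    for a single configuration (independent oracle for the g(r) route;
    q in nm⁻¹)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    iu = np.triu_indices(n, k=1)
    sep = positions[iu[0]] - positions[iu[1]]
    if box is not None and box.periodic:
        sep = wrap_minimum_image(sep, box)
    d = np.linalg.norm(sep, axis=1)
    q = np.atleast_1d(np.asarray(q, dtype=float)) * NM_PER_A
    x = q[:, None] * d[None, :]
    sinc = np.where(np.abs(x) < 1e-12, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
    return 1.0 + 2.0 / n * sinc.sum(axis=1)


# ---------------------------------------------------------------------------
# convergence & diffusion
# ---------------------------------------------------------------------------

def _segment_profiles(traj: Trajectory, bounds, bin_width: float):
    """Per-segment radial profiles for sequential frame ranges."""
    out = []
    for s in range(len(bounds) - 1):
        sub = Trajectory(traj.times[bounds[s]:bounds[s + 1]],
                         traj.positions[bounds[s]:bounds[s + 1]],
                         traj.quaternions[bounds[s]:bounds[s + 1]],
                         traj.images[bounds[s]:bounds[s + 1]],
                         {k: v[bounds[s]:bounds[s + 1]]
                          for k, v in traj.energies.items()},
                         traj.box, traj.stokes_radii, traj.d0_translation)
        out.append(radial_distribution(sub, bin_width))
    return out


def gr_convergence(traj: Trajectory, n_segments: int = 20,
                   bin_width: float = 1.0, z_threshold: float = 6.0,
                   skip_fraction: float = 0.0) -> dict:
    """g(r) stationarity check against ``n_segments`` sequential segments.

    For equal-length segments the full-trajectory g(r) equals the mean of
    the segment g(r)s by construction, so the discriminating statistic is
    the normalized per-segment deviation of bin *counts* from the
    expectation under the full-trajectory g(r):
    z = (counts − expected)/√(expected+1).  ``converged`` when the largest
    |z| over segments and bins is below ``z_threshold``; the per-bin SD of
    the segment g(r)s is also reported.
    """
    first = int(np.floor(skip_fraction * traj.n_frames))
    n_avail = traj.n_frames - first
    if n_avail < n_segments:
        raise ValueError(f"need at least {n_segments} frames, have {n_avail}")
    full = radial_distribution(traj, bin_width, skip_fraction=skip_fraction)
    bounds = np.linspace(first, traj.n_frames, n_segments + 1, dtype=int)
    profiles = _segment_profiles(traj, bounds, bin_width)
    seg_g = np.array([p.g for p in profiles])
    max_z = 0.0
    n = traj.n_solutes
    for s, p in enumerate(profiles):
        n_frames_seg = bounds[s + 1] - bounds[s]
        # expected counts: this segment's ideal-gas shell counts modulated
        # by the full-trajectory g(r)
        edges = np.concatenate([p.r - bin_width / 2, [p.r[-1] + bin_width / 2]])
        shell = 4.0 / 3.0 * np.pi * (edges[1:]**3 - edges[:-1]**3)
        expected = (n_frames_seg * 0.5 * n * (n - 1) * shell /
                    traj.box.volume) * full.g
        z = (p.counts - expected) / np.sqrt(expected + 1.0)
        max_z = max(max_z, float(np.max(np.abs(z))))
    seg_mean = seg_g.mean(axis=0)
    seg_sd = seg_g.std(axis=0)
    return {"r": full.r, "g_full": full.g, "g_segment_mean": seg_mean,
            "g_segment_sd": seg_sd,
            "max_deviation": float(np.max(np.abs(seg_g - full.g))),
            "max_z": max_z, "converged": max_z < z_threshold}


def mean_squared_displacement(traj: Trajectory, skip_fraction: float = 0.0,
                              max_lags: int = 200) -> tuple:
    """Ensemble MSD(τ) over all solutes and time origins (unwrapped
    coordinates), evaluated on at most ``max_lags`` evenly spaced lags.
    Returns (lag times ps, msd Å²)."""
    first = int(np.floor(skip_fraction * traj.n_frames))
    pos = traj.unwrapped_positions()[first:]
    times = traj.times[first:]
    n_frames = len(pos)
    if n_frames < 2:
        raise ValueError("not enough frames for an MSD")
    all_lags = np.arange(1, n_frames)
    if len(all_lags) > max_lags:
        lags = np.unique(np.linspace(1, n_frames - 1, max_lags).astype(int))
    else:
        lags = all_lags
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        msd[k] = np.mean(np.sum(disp**2, axis=2))
    return times[lags] - times[0], msd


def long_time_self_diffusion(traj: Trajectory, fit_window: tuple = (0.1, 0.5),
                             skip_fraction: float = 0.0) -> dict:
    """Long-time self-diffusion from the MSD slope: D = slope/6 on the lag
    window ``fit_window`` (fractions of the available lag range).  Returns
    D (Å²/ps) and D/D0 with D0 the mean infinite-dilution coefficient."""
    lo, hi = fit_window
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("fit_window must satisfy 0 <= lo < hi <= 1")
    tau, msd = mean_squared_displacement(traj, skip_fraction)
    i0 = int(np.floor(lo * len(tau)))
    i1 = max(i0 + 2, int(np.ceil(hi * len(tau))))
    if i1 > len(tau):
        raise ValueError("fit window outside the trajectory")
    slope, _ = np.polyfit(tau[i0:i1], msd[i0:i1], 1)
    d_long = slope / 6.0
    d0 = float(traj.d0_translation.mean())
    return {"d_long": float(d_long), "d0": d0,
            "d_long_over_d0": float(d_long / d0),
            "tau": tau, "msd": msd, "fit_slice": (i0, i1)}
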