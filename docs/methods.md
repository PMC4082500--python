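# Methods

Working units throughout: Å, ps, kcal/mol, elementary charges, Kelvin.
Physical constants are derived from SI values in `scipy.constants` at
import time (`bdgrid.constants`); e²/(4πε0) = 332.0637 kcal·Å/mol·e⁻².

## Model

### Solutes and grids

A solute is a rigid atomic body: body-frame atoms (positions, partial
charges, radii, optional per-atom SASA) with the center of geometry at the
origin, a reduced *effective charge* set used for the electrostatic terms
(by default all atoms), per-solute scalars (net charge, Stokes radius
σ_stokes, volume v = 4/3·π·σ_stokes³), and up to four node-centered cubic
interaction grids: electrostatic (kcal/mol/e), electrostatic desolvation
(kcal/mol/e²), non-polar desolvation (kcal/mol/Å²) and soft-core
(kcal/mol).  Grid values live on lattice nodes; `values[i,j,k]` sits at
`origin + (i,j,k)·h`.  Interpolation is trilinear
(`scipy.interpolate.RegularGridInterpolator`); the usable region is the
inscribed sphere of radius `cutoff_radius = min(side)/2`.  Orientations
are unit quaternions (the representation is an implementation choice; the
physics is representation-free).

### Pair interaction free energy

For a pair (1, 2) the energy is the sum of

* electrostatic: ½ Σ_k q_k(2) Φ_el(1)(r_k) + ½ Σ_k q_k(1) Φ_el(2)(r_k),
  each charge counted only while within the partner grid's inscribed
  sphere (isotropic per-charge cutoff);
* electrostatic desolvation: Σ q² Φ_edesolv (both directions, no ½);
* non-polar desolvation: Σ SASA Φ_npdesolv (both directions);
* soft-core repulsion: Σ E_softcore (both directions).  Soft-core grids
  are built as Σ_atoms ε (σ_atom/d)^n (default n = 6, ε = 1 kcal/mol,
  capped at 100 kcal/mol) — a smooth inverse-power excluded-volume term.

### The Debye-Hückel long-range correction

Beyond the grids the solute is treated as a net-charged DH sphere.  The
pair potential of mean force is

    w(r) = z_i z_j e² e^(−κ(r−a)) / (4π ε0 εr r (1 + κa)),  r ≥ a,
    w(r) = +∞,                                              r < a,

with contact distance a = a_i + a_j (a_i = σ_stokes unless overridden).
The **switch distance** of a pair is
`R_switch = min(cutoff₁ − extent₂, cutoff₂ − extent₁)`, where `extent` is
the largest body-frame distance of an effective charge from the solute
center: the transition happens at the shortest center separation at which
any partner charge could reach a grid boundary.  For d < R_switch the grid
terms are used (no charge is ever masked for centered charge sets); for
d ≥ R_switch the full electrostatic term is *replaced* by w(d) — the two
descriptions are never summed.  With the DH term disabled the
electrostatic interaction is simply zero beyond R_switch, which is the
finite-grid truncation the correction repairs.  The DH tail is truncated
at a cutoff of 4 electrostatic-grid sides, rescaled to half the box when
the box is smaller (self-image avoidance).

For a centrosymmetric test system the residual energy jump at R_switch is
the analytic radius-convention factor
`e^(−κa0)·(1+κ(a_i+a_j))/(1+κa0)·sinhc(κa0)` between the single-sphere
exterior potential and the pair DH form — 2.0% at 5 mM for 6 Å spheres,
vanishing as κa → 0.  `switch_discontinuity()` reports the jump for any
pair; for non-centrosymmetric charge distributions it can be larger, and
no boundary interpolation is applied (a known limitation of the scheme).

### Forces and propagation

Forces and torques are central finite differences of the pair energy
(default δ = 0.1 Å, δθ = 0.01 rad; the defaults are far below the length
scales of the potentials, making the O(δ²) truncation error negligible).
Translation follows the mean-field propagator

    r_i(t+Δt) = r_i(t) + D_t(φ_i) F_i Δt / kT + R_i,
    ⟨R_i⟩ = 0,  Var(R_i) = 2 D_t(φ_i) Δt per component,

and rotations follow the analogous update for a rotation vector about the
lab axes, with the quaternion renormalized each step.  Under the
mean-field replacement the divergence-of-diffusion-tensor term of the full
Ermak-McCammon propagator vanishes identically (the coefficient is
position-independent within a step).

### Mean-field hydrodynamics

φ_i is the occupied fraction of the local sphere of radius R_cut around
solute i (default R_cut = 4 × largest grid side, rescaled to half the box
when smaller).  Neighbors with d < R_cut − σ_j contribute their full
Stokes-sphere volume; partially included neighbors contribute the exact
two-sphere lens volume.  The central solute's own volume is excluded by
default (toggle `include_self`; including it raises every φ_i by
v_i/V_local and slows everything uniformly — the relative DH effects
studied here are insensitive to the choice).  Short-time coefficients:

* translation, Tokuyama model: D_t(φ)/D0 = 1/(1+H(φ)),
  H = 2b²/(1−b) − c/(1+2c) − bc(2+c)/((1+c)(1−b+c)), b = √(9φ/8),
  c = 11φ/16;
* rotation, Cichocki et al. virial series with lubrication:
  D_r(φ)/D0 = 1 − 0.631φ − 0.726φ².

Both are pinned in `bdgrid.hydro` with reference comments and are
dual-transcription-tested.  D0 comes from Stokes-Einstein with σ_stokes
and the solvent viscosity (default 0.89 cP, water at 300 K).  φ is
clamped at 0.6, just below the 0.64 random-close-packing limit of the
Tokuyama expression.  Full diffusion-tensor (Rotne-Prager/Cholesky)
hydrodynamics is out of scope by design.

### Engine

Defaults mirror a production protocol for protein solutions: Δt = 0.5 ps,
frames recorded every 0.5 ns, first fifth of a run discarded as
equilibration, overlap-free random initial placement, uniform random
initial orientations, periodic cubic box with minimum-image convention.
Pair search is brute-force minimum-image O(N²): the DH cutoff defaults to
half the box, where a cell list degenerates to all pairs; the target scale
is ≤ a few hundred solutes.  All randomness flows from a single seed
(numpy PCG64); the same seed reproduces a trajectory bit-for-bit.  Two
force paths exist: the general gridded path (finite-difference forces,
pure Python) and a compiled fast path (numba) for grid-free "DH sphere"
solutes with analytic DH forces plus a pairwise soft core ε(a/d)^n; the
two are cross-checked in the tests.  Recorded energies are instantaneous
values of the recorded configuration.  Trajectories are stored as
compressed npz (positions, quaternions, periodic image counts for exact
unwrapping, per-term energies).

Equilibration is detected by two monitors: stabilization of the total
energy (within k standard deviations of the final-half mean) and
stationarity of g(r).  Because the full-trajectory g(r) is by construction
the mean of equal-length segment g(r)s, the g(r) monitor compares each
segment's bin *counts* with the expectation under the reference g(r) via
normalized deviations z = (counts − expected)/√(expected+1); a segment is
consistent when max|z| is below a threshold (default 6, conservative for
the ~10²–10³ cells tested).

## Second osmotic virial coefficients

Only the long-range contribution is computed: the lower bound lb of the
Mayer integral is placed at the contact distance plus (or at) a multiple
of the Debye length, because the closed form rests on the second-order
expansion of e^(−w/kT), valid only for |w/kT| ≪ 1.  Routes:

* **Closed form** (generic lb ≥ a):
  B22 = 2πCβ e^(−κ(lb−a)) (κ·lb+1)/κ² − πβ²C² e^(−2κ(lb−a))/(2κ), with
  C = z_i z_j e²/(4πε0εr(1+κa)) and β = 1/kBT — the term-by-term
  integral of the second-order expansion with the DH w(r).  A warning is
  issued (and the result flagged) when |w(lb)/kT| ≥ 0.5.
* **Quadrature**: adaptive `scipy.integrate.quad` of the full-exponent or
  second-order integrand; the independent check on the closed form
  (machine-precision agreement at second order).
* **Lattice protocol**: sphere 1 fixed at the center of a 400³ Å box,
  sphere 2 visiting each of 100³ lattice vertices (spacing 4 Å); vertices
  inside the contact distance are excluded as overlaps; the energy at each
  vertex comes from the hybrid pair model (grid term below R_switch, DH
  tail above when enabled, orientations fixed — the spheres are
  isotropic); B22 = −½ Σ_{r_k ≥ lb} (e^(−E_k/kT) − 1)·ΔV.  The DH tail is
  evaluated at every non-grid vertex with no additional cutoff: the
  lattice scan has no periodic images to avoid.  Subset statistics:
  n random subsets of m counted vertices (default 100 × 10⁵), each
  rescaled to the full integration volume — the only subset estimator
  that leaves the mean unbiased; mean and SD are reported.

The test system: two spheres of radius 6 Å, each a quasi-uniform
golden-spiral shell of 180 point charges carrying z/180 e (the spiral is
iteratively recentered so the center of geometry is exact), with the
electrostatic grid filled from the analytic exterior DH solution of a
uniformly charged sphere — exactly what a linearized Poisson-Boltzmann
solver returns for a centrosymmetric charge density, so no external solver
is needed.  Grid spacing 1 Å; sides 100 or 200 Å in the benchmarks.

Expected behavior at 5 mM (reproduced by `scripts/acceptance.py`): a bare
100 Å grid yields exactly 0 beyond lb = a + 1/κ = 55 Å (the inscribed
sphere reaches only 50 Å); adding the DH tail recovers > 90% of the
closed-form value from lb = 1/κ (the shortfall is the part of the
integral beyond the integration box); doubling the grid to 200 Å instead
recovers only about half.  At 300 mM screening confines the interaction
within the small grid and all routes agree — the correction matters at low
ionic strength.

B22 values are reported in Å³.  Published tabulations of this benchmark
use an unstated unit convention that we could not reconstruct (our +1/+1
closed-form value at 5 mM is 5.4 × 10⁴ Å³); every cross-method check here
is therefore a ratio or an exact zero, which is unit-free.

## Solution observables

* **g(r)**: PBC-normalized center-to-center pair histogram,
  counts/(ideal-gas shell counts), default 1 Å bins, r_max = box/2.
* **S(q)**: trapezoidal transform of h = g − 1 truncated at r_max, with an
  optional half-cosine taper over the outer half of the r range to damp
  truncation ringing; sin(x)/x → 1 handles q = 0.  The q → 0 limit is the
  normalized isothermal osmotic compressibility n_p kB T χ_T.  For small
  N the truncated ∫h r² dr estimator of S(0) carries an O(1/N) finite-size
  tail bias amplified by r²; low-q comparisons should read S(q) at the
  smallest q the box resolves (≈ 2π/(box/2)) instead.  A direct Debye
  double-sum S(q) is provided as an independent oracle.
* **P(q)**: orientationally averaged oblate-ellipsoid form factor,
  P(q) = ∫₀^{π/2} [3(sin u − u cos u)/u³]² sin α dα with
  u = q√(a²cos²α + b²sin²α), Gauss-Legendre in cos α (256 nodes ≫
  needed); defaults a = 17.5 Å, b = 47.4 Å (a serum-albumin-like oblate);
  P(0) = 1 exactly.  q grids are nm⁻¹ (0.05–4, 200 points by default).
* **I(q)/(A n_p) = P(q)·S(q)**: the instrument constant A is experiment-
  specific, so only the normalized product is produced.
* **D_long**: least-squares slope/6 of the ensemble MSD on a lag window,
  using exactly unwrapped coordinates (image counts are stored by the
  engine).  Default window is lags 10–50% of the trajectory; for
  free-diffusion calibration checks a short-lag window is preferred since
  the number of independent displacement windows, and hence the precision,
  is largest there.  The MSD is evaluated on at most 200 evenly spaced
  lags.

## Synthetic data and what the tests show

All tests run on generated data: the two-sphere system above and grid-free
"DH sphere" suspensions (point solutes with net charge, Stokes radius and
a pairwise soft core).  These emulate the benchmark geometry of the
method — centrosymmetric charge distributions, additive pair energies,
uniform sizes — and deliberately omit features of real protein solutions:
anisotropic charge distributions (and hence orientation-dependent forces
and the larger switch discontinuities they cause), desolvation
contributions, flexibility, and solvent-structure effects.  Passing tests
therefore validate the numerics of the force model, the propagator and the
estimators, not the biophysical accuracy of any particular protein model.

Problem sizes used by the test suite (chosen to give comfortable
statistical margins): free-diffusion D0 recovery aggregates 200 walkers ×
2×10⁴ steps; the two-particle Boltzmann-sampling check runs 10⁶ steps at
Δt = 5 ps (drift per step ≪ random step at these soft potentials) and
compares 6 equiprobable distance bins by χ²; the DH on/off suspension uses
25 solutes of +10 e and σ_stokes = 19 Å (φ ≈ 0.04, a lysozyme-like charge
at 5 mM) for 10⁶ steps of 0.5 ps with and without the tail, checking the
directional effects: lower low-q S(q), an outward-pushed g(r) rise, and a
lower long-time self-diffusion coefficient with the DH term on.

## Numerical choices & degenerate inputs

* Debye screening: κ = 0 (pure water) is allowed everywhere except the
  closed-form B22 (which diverges without screening and raises).
* dh_pmf returns +∞ below contact; the lattice protocol excludes those
  vertices; the engine's soft core keeps dynamics finite.
* Grid interpolation outside the bounding box raises — callers apply the
  cutoff logic first.
* Ties at the minimum-image boundary use the half-open convention
  [−L/2, L/2).
* The equilibration/convergence thresholds (z = 6, energy 3 SD) are
  conservative defaults for the cell counts involved, exposed as
  parameters.
* εr defaults to 78.5 and T to 300 K; with those values 1/κ = 43.15 Å at
  5 mM and 5.57 Å at 300 mM for a 1:1 electrolyte.

## Known limitations

* No boundary interpolation at the grid/DH switch: force discontinuities
  remain for strongly anisotropic charge distributions (diagnostic
  provided).
* Mean-field hydrodynamics ignores correlated (pairwise) hydrodynamic
  coupling; it reproduces volume-fraction trends, not wavevector-dependent
  hydrodynamic functions.
* The engine targets ≤ 10³ solutes on one core; no cell lists, threading
  or GPU kernels.
* Orientation-resolved (anisotropic) B22 and the short-range B22
  contribution are out of scope: the closed form exists only for the
  long-range DH regime.
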