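import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import constants as si

import bdgrid as bg
from bdgrid.electro import (DHPair, _grid_sum, charge_extent, dh_pmf,
                            dh_force_magnitude, grid_charge_energy,
                            grid_value, pair_energy, pair_forces_torques,
                            softcore_from_atoms, switch_discontinuity,
                            switch_radius)
from bdgrid.model import AtomSet, PotentialGrid, Solute


# ---------------------------------------------------------------------------
# Debye-Hückel
# ---------------------------------------------------------------------------

class TestInverseDebyeLength:
    def test_pure_water(self):
        assert bg.inverse_debye_length(bg.SolventModel()) == 0.0

    def test_si_cross_check(self, solvent_5mm):
        """κ recomputed constant-by-constant in SI units and converted."""
        rho = 2 * 0.005 * si.N_A * 1e3  # ions/m³ for a 1:1 salt at 5 mM
        kappa_si = np.sqrt(si.e**2 * rho / (si.epsilon_0 * 78.5 * si.k * 300.0))
        assert solvent_5mm.kappa == pytest.approx(kappa_si * 1e-10, rel=1e-12)


class TestDHPmf:
    def test_hard_overlap_is_infinite(self, solvent_5mm):
        pair = DHPair(1, 1, 12.0, solvent_5mm.kappa)
        assert dh_pmf(6.0, pair) == np.inf
        pair_attr = DHPair(1, -1, 12.0, solvent_5mm.kappa)
        assert dh_pmf(6.0, pair_attr) == np.inf

    def test_r_nonpositive_rejected(self, solvent_5mm):
        with pytest.raises(ValueError):
            dh_pmf(-1.0, DHPair(1, 1, 12.0, solvent_5mm.kappa))

    def test_unscreened_limit_is_coulomb(self):
        """κ=0, unit charges: w(r) = kB·T·λB/r."""
        solv = bg.SolventModel()
        pair = DHPair(1, 1, 1.0, 0.0)
        for r in (5.0, 20.0, 100.0):
            assert dh_pmf(r, pair) == pytest.approx(solv.kT * solv.bjerrum_length / r,
                                                    rel=1e-12)

    def test_value_from_independent_si_evaluation(self):
        """w at z=+1/+1, a=12 Å, 1/κ=43 Å, r=55 Å recomputed from physical
        constants in SI and converted to kcal/mol."""
        kappa, a, r = 1.0 / 43.0, 12.0, 55.0
        pair = DHPair(1, 1, a, kappa, 78.5, 300.0)
        w_si = (si.e**2 * np.exp(-kappa * 1e10 * (r - a) * 1e-10) /
                (4 * np.pi * si.epsilon_0 * 78.5 * r * 1e-10 * (1 + kappa * a)))
        w_kcal = w_si * si.N_A / (si.calorie * 1000)
        assert dh_pmf(r, pair) == pytest.approx(w_kcal, rel=1e-12)
        # as a reduced ratio: w/kT = λB e^(−κ(r−a)) / (r (1+κa))
        solv = bg.SolventModel.monovalent(0.0)
        lam_b = solv.bjerrum_length
        assert dh_pmf(r, pair) / solv.kT == pytest.approx(
            lam_b * np.exp(-1.0) * np.exp(kappa * a) / (r * (1 + kappa * a)) *
            np.exp(-kappa * a), rel=1e-12)

    def test_sign_follows_charge_product(self, solvent_5mm):
        k = solvent_5mm.kappa
        assert dh_pmf(20.0, DHPair(2, 3, 12.0, k)) > 0
        assert dh_pmf(20.0, DHPair(2, -3, 12.0, k)) < 0

    @given(st.floats(12.0, 200.0), st.floats(12.5, 200.0))
    def test_monotonicity(self, r1, r2):
        """Strictly decreasing in r for like charges, increasing for
        opposite, beyond contact."""
        pair = DHPair(1, 1, 12.0, 0.02)
        lo, hi = sorted((r1, r2))
        if hi - lo > 1e-9:
            assert dh_pmf(lo, pair) > dh_pmf(hi, pair)
            anti = DHPair(1, -1, 12.0, 0.02)
            assert dh_pmf(lo, anti) < dh_pmf(hi, anti)

    def test_screening_ratio_regression(self):
        """Doubling κ at fixed r scales |w| by the analytically predicted
        factor e^(−κ(r−a)) (1+κa)/(1+2κa)."""
        a, r, k = 12.0, 50.0, 0.02
        w1 = dh_pmf(r, DHPair(1, 1, a, k))
        w2 = dh_pmf(r, DHPair(1, 1, a, 2 * k))
        predicted = np.exp(-k * (r - a)) * (1 + k * a) / (1 + 2 * k * a)
        assert w2 / w1 == pytest.approx(predicted, rel=1e-12)


# ---------------------------------------------------------------------------
# grid interpolation
# ---------------------------------------------------------------------------

def _ramp_grid(n=5, spacing=2.0, kind="electrostatic"):
    half = (n - 1) * spacing / 2
    ax = np.arange(n) * spacing - half
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    return PotentialGrid(kind, origin=np.array([-half] * 3), spacing=spacing,
                         values=1.0 * X + 10.0 * Y + 100.0 * Z)


def _trilinear_oracle(grid, p):
    """Independent 8-corner expansion."""
    rel = (np.asarray(p) - grid.origin) / grid.spacing
    i = np.floor(rel).astype(int)
    i = np.minimum(i, np.array(grid.shape) - 2)
    f = rel - i
    val = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0]) *
                     (f[1] if dy else 1 - f[1]) *
                     (f[2] if dz else 1 - f[2]))
                val += w * grid.values[i[0] + dx, i[1] + dy, i[2] + dz]
    return val


class TestGridValue:
    def test_node_identity(self):
        g = _ramp_grid()
        for idx in [(0, 0, 0), (2, 1, 3), (4, 4, 4)]:
            p = g.origin + np.array(idx) * g.spacing
            assert grid_value(g, p) == pytest.approx(
                g.values[idx], abs=1e-12)

    def test_cell_center_is_corner_mean(self, rng):
        vals = rng.normal(size=(2, 2, 2))
        g = PotentialGrid("electrostatic", origin=np.zeros(3), spacing=1.0,
                          values=vals)
        assert grid_value(g, np.array([0.5, 0.5, 0.5])) == pytest.approx(
            vals.mean(), abs=1e-12)

    def test_matches_brute_force_expansion(self, rng):
        g = _ramp_grid(n=6, spacing=1.5)
        vals = rng.normal(size=g.shape)
        g = PotentialGrid("electrostatic", g.origin, g.spacing, vals)
        lo, hi = g.origin[0], g.origin[0] + g.side_lengths[0]
        pts = rng.uniform(lo, hi, size=(50, 3))
        for p in pts:
            assert grid_value(g, p) == pytest.approx(_trilinear_oracle(g, p),
                                                     abs=1e-10)

    def test_outside_box_rejected(self):
        g = _ramp_grid()
        with pytest.raises(ValueError):
            grid_value(g, np.array([100.0, 0, 0]))


class TestGridChargeEnergy:
    def test_all_charges_beyond_cutoff_give_zero(self):
        g = _ramp_grid(n=5, spacing=2.0)  # cutoff radius 4
        charges = AtomSet(np.array([[5.0, 0, 0], [0, -6.0, 0]]),
                          np.array([1.0, 2.0]), np.ones(2))
        assert grid_charge_energy(g, charges, np.zeros(3)) == 0.0

    def test_single_unit_charge_on_node(self):
        g = _ramp_grid(n=5, spacing=1.0)  # nodes at integers in [-2, 2]
        charges = AtomSet(np.array([[1.0, 0.0, -1.0]]), np.array([1.0]),
                          np.ones(1))
        assert grid_charge_energy(g, charges, np.zeros(3)) == pytest.approx(
            1.0 * 1.0 + 0.0 + 100.0 * (-1.0), abs=1e-10)

    def test_mixed_set_matches_masked_loop_oracle(self, rng):
        g = _ramp_grid(n=7, spacing=1.0)  # cutoff 3
        pos = rng.uniform(-4, 4, size=(40, 3))
        q = rng.normal(size=40)
        charges = AtomSet(pos, q, np.ones(40))
        expected = 0.0
        for p, qq in zip(pos, q):
            if np.linalg.norm(p) < g.cutoff_radius:
                expected += qq * _trilinear_oracle(g, p)
        assert grid_charge_energy(g, charges, np.zeros(3)) == pytest.approx(
            expected, abs=1e-9)

    def test_requires_electrostatic_kind(self):
        g = _ramp_grid(kind="softcore")
        with pytest.raises(ValueError):
            grid_charge_energy(g, AtomSet(np.zeros((1, 3)), np.ones(1),
                                          np.ones(1)), np.zeros(3))


# ---------------------------------------------------------------------------
# pair energy / forces
# ---------------------------------------------------------------------------

IDQ = np.array([1.0, 0.0, 0.0, 0.0])


class TestPairEnergy:
    def test_neutral_gridless_pair_is_zero(self, solvent_5mm):
        atoms = AtomSet(np.zeros((1, 3)), np.zeros(1), np.ones(1))
        s = Solute(atoms, stokes_radius=2.0)
        br = pair_energy(s, s, np.zeros(3), IDQ, np.array([10.0, 0, 0]), IDQ,
                         solvent_5mm)
        assert br.total == 0.0
        assert all(v == 0.0 for v in br.as_dict().values())

    def test_breakdown_total_is_component_sum(self, sphere_system_small,
                                               solvent_5mm):
        s1, s2 = sphere_system_small.solute1, sphere_system_small.solute2
        br = pair_energy(s1, s2, np.zeros(3), IDQ, np.array([10.0, 2, 1]), IDQ,
                         solvent_5mm)
        assert br.total == pytest.approx(
            br.electrostatic_grid + br.dh_tail + br.edesolv + br.npdesolv +
            br.softcore, abs=1e-9)

    def test_beyond_grid_total_is_dh_pmf(self, sphere_system_small, solvent_5mm):
        """Past the grid's inscribed sphere only the analytic DH tail acts,
        reproducing the analytic energy-vs-separation curve."""
        sys = sphere_system_small
        for d in (25.0, 40.0, 80.0):
            br = pair_energy(sys.solute1, sys.solute2, np.zeros(3), IDQ,
                             np.array([d, 0, 0]), IDQ, solvent_5mm)
            assert br.electrostatic_grid == 0.0
            assert br.total == pytest.approx(dh_pmf(d, sys.dh_pair()), rel=1e-12)

    def test_symmetry_under_exchange(self, sphere_system_small, solvent_5mm):
        sys = sphere_system_small
        p2 = np.array([15.0, 3.0, -2.0])
        e12 = pair_energy(sys.solute1, sys.solute2, np.zeros(3), IDQ, p2, IDQ,
                          solvent_5mm).total
        e21 = pair_energy(sys.solute2, sys.solute1, p2, IDQ, np.zeros(3), IDQ,
                          solvent_5mm).total
        assert e12 == pytest.approx(e21, abs=1e-9)

    @staticmethod
    def _switch_jump(system, solvent):
        r_sw = switch_radius(system.solute1, system.solute2)
        inside = pair_energy(system.solute1, system.solute2, np.zeros(3), IDQ,
                             np.array([r_sw - 1e-3, 0, 0]), IDQ, solvent).total
        outside = pair_energy(system.solute1, system.solute2, np.zeros(3), IDQ,
                              np.array([r_sw + 1e-3, 0, 0]), IDQ, solvent).total
        return inside, outside

    def test_continuity_across_switch_within_2pct(self):
        """Centrosymmetric sphere system at low screening (κa ≪ 1): the
        grid term just inside the switch radius matches the DH tail just
        outside within 2%."""
        solv = bg.SolventModel.monovalent(0.001)
        system = bg.make_sphere_system(3.0, 3.0, solv, grid_side=40.0)
        inside, outside = self._switch_jump(system, solv)
        assert inside == pytest.approx(outside, rel=0.02)

    def test_switch_jump_is_radius_convention_factor(self, sphere_system_small,
                                                     solvent_5mm):
        """The residual jump at the switch equals the analytic mismatch
        between the single-sphere grid potential (radius a0, shell-averaged
        over the partner's charges) and the pair DH form (contact a = 2a0):
        e^(−κa0)·(1+κa)/(1+κa0)·sinh(κa0)/(κa0)."""
        k = solvent_5mm.kappa
        a0 = 6.0
        inside, outside = self._switch_jump(sphere_system_small, solvent_5mm)
        factor = (np.exp(-k * a0) * (1 + 2 * k * a0) / (1 + k * a0) *
                  np.sinh(k * a0) / (k * a0))
        assert inside / outside == pytest.approx(factor, rel=2e-3)

    def test_dh_cutoff_truncates_tail(self, sphere_system_small, solvent_5mm):
        sys = sphere_system_small
        br = pair_energy(sys.solute1, sys.solute2, np.zeros(3), IDQ,
                         np.array([80.0, 0, 0]), IDQ, solvent_5mm, dh_cutoff=60.0)
        assert br.total == 0.0

    def test_no_dh_beyond_switch_is_zero(self, sphere_system_small, solvent_5mm):
        sys = sphere_system_small
        br = pair_energy(sys.solute1, sys.solute2, np.zeros(3), IDQ,
                         np.array([30.0, 0, 0]), IDQ, solvent_5mm, use_dh=False)
        assert br.total == 0.0

    def test_missing_grid_on_one_side_raises(self, sphere_system_small,
                                             solvent_5mm):
        sys = sphere_system_small
        bare = Solute(sys.solute2.atoms, stokes_radius=6.0)
        with pytest.raises(ValueError, match="electrostatic"):
            pair_energy(sys.solute1, bare, np.zeros(3), IDQ,
                        np.array([10.0, 0, 0]), IDQ, solvent_5mm)

    def test_switch_radius_accounts_for_charge_extent(self, sphere_system_small):
        sys = sphere_system_small
        g = sys.solute1.grids["electrostatic"]
        assert switch_radius(sys.solute1, sys.solute2) == pytest.approx(
            g.cutoff_radius - charge_extent(sys.solute2))


class TestPairForces:
    def test_zero_force_in_flat_region(self, sphere_system_small, solvent_5mm):
        """Beyond the DH cutoff the potential is constant: forces vanish."""
        sys = sphere_system_small
        f1, t1, f2, t2 = pair_forces_torques(
            sys.solute1, sys.solute2, np.zeros(3), IDQ,
            np.array([100.0, 0, 0]), IDQ, solvent_5mm, dh_cutoff=50.0)
        assert np.allclose(f1, 0) and np.allclose(f2, 0)
        assert np.allclose(t1, 0) and np.allclose(t2, 0)

    def test_dh_regime_matches_analytic_derivative(self, sphere_system_small,
                                                   solvent_5mm):
        sys = sphere_system_small
        d = 30.0
        f1, _, f2, _ = pair_forces_torques(sys.solute1, sys.solute2,
                                           np.zeros(3), IDQ,
                                           np.array([d, 0, 0]), IDQ, solvent_5mm,
                                           delta=0.05)
        analytic = dh_force_magnitude(d, sys.dh_pair())
        assert f2[0] == pytest.approx(analytic, rel=1e-4)  # O(δ²) truncation
        assert np.allclose(f1, -f2, atol=1e-12)  # Newton's third law

    def test_invalid_steps_rejected(self, sphere_system_small, solvent_5mm):
        sys = sphere_system_small
        with pytest.raises(ValueError):
            pair_forces_torques(sys.solute1, sys.solute2, np.zeros(3), IDQ,
                                np.array([30.0, 0, 0]), IDQ, solvent_5mm,
                                delta=-1.0)

    def test_discontinuity_diagnostic(self, sphere_system_small, solvent_5mm):
        rep = switch_discontinuity(sphere_system_small.solute1,
                                   sphere_system_small.solute2, solvent_5mm)
        assert rep["switch_radius"] > 0
        # centrosymmetric system: residual jump below 3% of the energy
        assert abs(rep["jump"]) < 0.03 * abs(rep["outside"])


# ---------------------------------------------------------------------------
# soft-core construction
# ---------------------------------------------------------------------------

class TestSoftcore:
    def test_far_field_is_negligible(self):
        atoms = AtomSet(np.zeros((1, 3)), np.zeros(1), np.array([2.0]))
        g = softcore_from_atoms(atoms, side=40.0, spacing=2.0, exponent=6)
        corner = g.origin + 1e-9
        assert grid_value(g, corner) < 1e-3

    def test_power_law_scaling_n1(self):
        """Single atom, n=1: value halves when the distance doubles."""
        atoms = AtomSet(np.zeros((1, 3)), np.zeros(1), np.array([1.0]))
        g = softcore_from_atoms(atoms, side=40.0, spacing=1.0, exponent=1)
        v1 = grid_value(g, np.array([4.0, 0, 0]))
        v2 = grid_value(g, np.array([8.0, 0, 0]))
        assert v1 == pytest.approx(2 * v2, rel=1e-9)

    def test_node_equals_direct_atom_sum(self, rng):
        pos = rng.uniform(-3, 3, size=(7, 3))
        radii = rng.uniform(0.5, 2.0, size=7)
        atoms = AtomSet(pos, np.zeros(7), radii)
        g = softcore_from_atoms(atoms, side=20.0, spacing=1.0, exponent=6,
                                prefactor=0.3, cap=1e9)
        probe = np.array([5.0, -2.0, 1.0])  # on a node (spacing 1, origin -10)
        d = np.linalg.norm(pos - probe, axis=1)
        expected = np.sum(0.3 * (radii / d) ** 6)
        assert grid_value(g, probe) == pytest.approx(expected, rel=1e-9)

    def test_cap_limits_values(self):
        atoms = AtomSet(np.zeros((1, 3)), np.zeros(1), np.array([2.0]))
        g = softcore_from_atoms(atoms, side=10.0, spacing=1.0, cap=5.0)
        assert g.values.max() <= 5.0


def test_grid_sum_masks_outside_cutoff(rng):
    g = _ramp_grid(n=7, spacing=1.0)
    pts = np.array([[0.5, 0.5, 0.5], [10.0, 0, 0]])
    w = np.array([2.0, 5.0])
    expected = 2.0 * _trilinear_oracle(g, pts[0])
    assert _grid_sum(g, w, pts, np.zeros(3)) == pytest.approx(expected, abs=1e-10)
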