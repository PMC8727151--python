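"""Closed-form model pieces: inclination, bond factor, per-root and
per-specimen reinforcement, positional and growing shear zone, extension,
axial stress and stressed length."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import rootshear as rs

positive = st.floats(min_value=0.05, max_value=50.0)


class TestBeta:
    def test_zero_displacement_gives_zero(self):
        assert rs.compute_beta(0.0, 10.0) == 0.0

    def test_closed_form(self):
        assert rs.compute_beta(20.0, 30.0) == pytest.approx(
            math.atan(2.0 / 3.0), abs=1e-15
        )

    def test_strictly_decreasing_in_thickness(self):
        betas = [rs.compute_beta(5.0, z) for z in np.linspace(2.0, 30.0, 15)]
        assert all(b1 > b2 for b1, b2 in zip(betas, betas[1:]))

    def test_degenerate_zone_rejected(self):
        with pytest.raises(ValueError):
            rs.compute_beta(5.0, 0.0)


class TestBondFactor:
    def test_longhand_value(self):
        # 4 * 1.25 kPa * (30 mm / 1 mm) * 200000 kPa = 3.0e7 kPa^2
        assert rs.bond_factor_k(1.25, 30.0, 200.0, 1.0) == pytest.approx(
            math.sqrt(3.0e7), rel=1e-14
        )

    def test_square_root_scaling_in_tau(self):
        k1 = rs.bond_factor_k(1.0, 10.0, 200.0, 1.0)
        k4 = rs.bond_factor_k(4.0, 10.0, 200.0, 1.0)
        assert k4 == pytest.approx(2.0 * k1, rel=1e-14)

    def test_vanishing_bond_limit(self):
        assert rs.bond_factor_k(1e-16, 10.0, 200.0, 1.0) < 1e-4

    @pytest.mark.parametrize("bad", [(-1, 1, 1, 1), (1, 0, 1, 1), (1, 1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            rs.bond_factor_k(*bad)


class TestPerRoot:
    soil = rs.SoilParams(36.0)
    iface = rs.InterfaceParams(1.25)
    root = rs.Root(0.0, 0.0, 1.0, 200.0, "r")

    def test_zero_at_zero_displacement(self):
        assert rs.root_delta_S(self.root, 0.004, 0.0, 10.0, self.soil, self.iface) == 0.0

    def test_linear_in_area_ratio(self):
        one = rs.root_delta_S(self.root, 0.004, 5.0, 10.0, self.soil, self.iface)
        two = rs.root_delta_S(self.root, 0.008, 5.0, 10.0, self.soil, self.iface)
        assert two == pytest.approx(2.0 * one, rel=1e-14)

    @given(u=positive, z=positive, tau=positive)
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_term_by_term_composition(self, u, z, tau):
        """The per-root value equals the literal composition of inclination,
        bond factor and the trigonometric factor."""
        iface = rs.InterfaceParams(tau)
        got = rs.root_delta_S(self.root, 0.004, u, z, self.soil, iface)
        beta = math.atan(u / z)
        k = math.sqrt(4.0 * tau * z * 200.0e3 / 1.0)
        expected = (
            0.004
            * k
            * math.sqrt(1.0 / math.cos(beta) - 1.0)
            * (math.sin(beta) + math.cos(beta) * math.tan(math.radians(36.0)))
        )
        # tolerance reflects the long-hand oracle's own conditioning: its
        # naive 1/cos - 1 cancels digits when beta = atan(u/z) is small
        assert got == pytest.approx(expected, rel=1e-9)

    def test_small_angle_expansion(self):
        """For u/Z -> 0 the contribution approaches
        a_r k (beta^2/2)^0.5 (beta + tan phi)."""
        a_r, z = 0.004, 30.0
        for u in [1e-3, 1e-4, 1e-5]:
            beta = u / z
            k = rs.bond_factor_k(1.25, z, 200.0, 1.0)
            approx = a_r * k * math.sqrt(beta**2 / 2.0) * (beta + self.soil.tan_phi)
            got = rs.root_delta_S(self.root, a_r, u, z, self.soil, self.iface)
            assert got / approx == pytest.approx(1.0, rel=1e-6)


class TestSpecimenAssembly:
    def test_fallow_zero_everywhere(self, fallow_spec):
        for u in [0.0, 1.0, 10.0, 20.0]:
            assert rs.specimen_delta_S(fallow_spec, u) == 0.0

    def test_two_colocated_roots_double_one(self, willow_zone, soil_with_baseline):
        root = rs.Root(10.0, 0.0, 1.5, 200.0, "a")
        twin = rs.Root(10.0, 0.0, 1.5, 200.0, "b")
        iface = rs.InterfaceParams(1.25)
        one = rs.Specimen((root,), soil_with_baseline, iface, willow_zone)
        two = rs.Specimen((root, twin), soil_with_baseline, iface, willow_zone)
        for u in [3.0, 9.0, 18.0]:
            assert rs.specimen_delta_S(two, u) == pytest.approx(
                2.0 * rs.specimen_delta_S(one, u), rel=1e-14
            )

    def test_positional_at_centre_matches_constant_zmax(
        self, willow_zone, soil_with_baseline
    ):
        roots = tuple(
            rs.Root(0.0, 0.0, d, 200.0, f"c{i}") for i, d in enumerate([0.8, 1.2, 2.0])
        )
        spec = rs.Specimen(roots, soil_with_baseline, rs.InterfaceParams(1.25), willow_zone)
        for u in [2.0, 8.0, 15.0]:
            assert rs.specimen_delta_S(spec, u, "positional") == pytest.approx(
                rs.specimen_delta_S(spec, u, "constant", z_const_mm=30.0), rel=1e-14
            )

    def test_root_outside_tube_rejected(self, willow_zone, soil_with_baseline):
        with pytest.raises(ValueError, match="outside the tube"):
            rs.Specimen(
                (rs.Root(60.0, 0.0, 1.0, 200.0, "out"),),
                soil_with_baseline,
                rs.InterfaceParams(1.25),
                willow_zone,
            )


class TestPositionalZone:
    def test_centre_gets_zmax(self, willow_zone):
        assert rs.local_shear_zone(willow_zone, 0.0) == 30.0

    def test_wall_gets_tube_gap(self, willow_zone):
        assert rs.local_shear_zone(willow_zone, 51.5) == pytest.approx(2.0, abs=1e-12)

    def test_quarter_radius_is_midpoint(self, willow_zone):
        assert rs.local_shear_zone(willow_zone, 51.5 / 2.0) == pytest.approx(
            (30.0 + 2.0) / 2.0, rel=1e-14
        )

    def test_outside_tube_rejected(self, willow_zone):
        with pytest.raises(ValueError):
            rs.local_shear_zone(willow_zone, 60.0)


class TestGrowthSchedule:
    def test_anchor_points(self, willow_zone):
        g = willow_zone.growth
        assert g.factor(0.0) == 0.0
        assert g.factor(8.15) == pytest.approx(0.8, abs=1e-15)
        assert g.factor(19.83) == pytest.approx(1.0, abs=1e-15)
        assert g.factor(25.0) == 1.0

    def test_linear_between_anchors(self, willow_zone):
        assert willow_zone.growth.factor(8.15 / 2.0) == pytest.approx(0.4, rel=1e-14)

    def test_continuous_and_nondecreasing(self, willow_zone):
        u = np.linspace(0.0, 25.0, 2001)
        f = np.array([willow_zone.growth.factor(x) for x in u])
        assert np.all(np.diff(f) >= -1e-15)
        assert np.max(np.abs(np.diff(f))) < 0.01  # no jumps at the break points

    def test_floor_at_tube_gap(self, willow_zone):
        assert rs.grown_shear_zone(willow_zone, 30.0, 0.0) == 2.0
        # beyond the floor the schedule applies directly
        assert rs.grown_shear_zone(willow_zone, 30.0, 8.15) == pytest.approx(24.0)

    def test_negative_displacement_rejected(self, willow_zone):
        with pytest.raises(ValueError):
            rs.grown_shear_zone(willow_zone, 30.0, -1.0)


class TestExtensionAndStress:
    def test_zero_inclination_zero_extension(self):
        assert rs.root_extension(30.0, 0.0) == 0.0

    def test_longhand_secant(self):
        beta = math.atan(2.0 / 3.0)
        assert rs.root_extension(30.0, beta) == pytest.approx(
            30.0 * (math.sqrt(13.0) / 3.0 - 1.0), rel=1e-14
        )

    def test_strictly_increasing_in_beta(self):
        betas = np.linspace(0.0, 1.4, 30)
        dl = [rs.root_extension(30.0, b) for b in betas]
        assert all(a < b for a, b in zip(dl, dl[1:]))

    def test_axial_stress_strain_invariance(self):
        assert rs.axial_stress(1.0, 50.0, 200.0) == rs.axial_stress(2.0, 100.0, 200.0)

    @given(dl=positive, l0=positive, e=positive)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_axial_stress_arithmetic(self, dl, l0, e):
        assert rs.axial_stress(dl, l0, e) == pytest.approx(e * dl / l0, rel=1e-14)

    def test_stressed_length_zero_at_zero_inclination(self):
        assert rs.stressed_length(1.25, 30.0, 200.0, 1.0, 0.0) == 0.0

    @given(tau=positive, z=positive, e=positive, d=positive,
           beta=st.floats(min_value=0.05, max_value=1.4))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_stressed_length_algebraic_identity(self, tau, z, e, d, beta):
        """The printed closed form equals its k-composition to 1e-12."""
        direct = rs.stressed_length(tau, z, e, d, beta)
        k = rs.bond_factor_k(tau, z, e, d)
        composed = k * math.sqrt(1.0 / math.cos(beta) - 1.0) * d / (2.0 * tau)
        assert direct == pytest.approx(composed, rel=1e-12)

    def test_stressed_length_inverse_sqrt_tau_scaling(self):
        l1 = rs.stressed_length(1.0, 30.0, 200.0, 1.0, 0.5)
        l4 = rs.stressed_length(4.0, 30.0, 200.0, 1.0, 0.5)
        assert l4 == pytest.approx(l1 / 2.0, rel=1e-13)


class TestPredictCurve:
    def test_fallow_returns_baseline(self, fallow_spec, willow_u_grid):
        pred = rs.predict_stress_curve(fallow_spec, willow_u_grid)
        baseline = fallow_spec.soil.baseline(willow_u_grid)
        np.testing.assert_allclose(pred.record.s_kpa, baseline, rtol=0, atol=1e-14)
        assert np.all(pred.delta_s_kpa == 0.0)

    def test_thin_zone_curve_dominates(self, willow_spec, willow_u_grid):
        """Constant 2 mm zone gives more reinforcement than 30 mm at every
        displacement: strain builds faster across a thinner band."""
        thin = rs.predict_stress_curve(willow_spec, willow_u_grid, "constant", 2.0)
        thick = rs.predict_stress_curve(willow_spec, willow_u_grid, "constant", 30.0)
        u_pos = willow_u_grid > 0
        assert np.all(thin.delta_s_kpa[u_pos] > thick.delta_s_kpa[u_pos])

    def test_growth_policy_is_composition_of_parts(
        self, willow_zone, soil_with_baseline
    ):
        """A symmetric two-root layout under the growing-zone policy equals
        the hand-composed sum of grown per-root contributions."""
        r1 = rs.Root(20.0, 0.0, 1.5, 200.0, "a")
        r2 = rs.Root(-20.0, 0.0, 1.5, 200.0, "b")
        iface = rs.InterfaceParams(1.25)
        spec = rs.Specimen((r1, r2), soil_with_baseline, iface, willow_zone)
        u = 12.0
        by_policy = rs.specimen_delta_S(spec, u, "positional_with_growth")
        manual = 0.0
        for root in (r1, r2):
            z_peak = rs.local_shear_zone(willow_zone, root.d_root_mm)
            z = rs.grown_shear_zone(willow_zone, z_peak, u)
            manual += rs.root_delta_S(
                root, spec.area_ratio(root), u, z, soil_with_baseline, iface
            )
        assert by_policy == pytest.approx(manual, rel=1e-14)

    def test_outside_baseline_domain_needs_explicit_extrapolation(self, willow_spec):
        with pytest.raises(ValueError, match="baseline domain"):
            rs.predict_stress_curve(willow_spec, [0.0, 50.0])
        pred = rs.predict_stress_curve(
            willow_spec, [0.0, 50.0], extrapolate_baseline=True
        )
        assert np.all(np.isfinite(pred.record.s_kpa))

    def test_diagnostics_cover_every_root(self, willow_spec, willow_u_grid):
        pred = rs.predict_stress_curve(willow_spec, willow_u_grid)
        assert len(pred.diagnostics) == len(willow_spec.roots)
        assert (pred.diagnostics["sigma_axial_MPa"] >= 0).all()


@pytest.fixture(scope="module")
def sweep_table():
    return rs.sensitivity_sweep(
        np.linspace(2.0, 30.0, 8), [0.5, 1.0, 2.0, 5.0], np.linspace(0.0, 20.0, 9)
    )


class TestSensitivitySweep:

    def test_zero_displacement_rows_are_zero(self, sweep_table):
        table = sweep_table
        assert (table.loc[table.u_mm == 0.0, "dS_kpa"] == 0.0).all()

    def test_reinforcement_decreases_with_thickness(self, sweep_table):
        """Thinner zones strain the roots harder, so dS falls with Z —
        except at extreme inclinations (u/Z beyond ~5, beta near 80 deg),
        where the friction term cos(beta) tan(phi) dies off and the curves
        cross; the check is restricted to the moderate-inclination range."""
        table = sweep_table
        for (tau, u), grp in table[table.u_mm > 0].groupby(["tau_kpa", "u_mm"]):
            grp = grp.sort_values("Z_mm")
            ds = grp["dS_kpa"].to_numpy()
            z = grp["Z_mm"].to_numpy()
            moderate = u <= 5.0 * z[:-1]
            assert np.all(np.diff(ds)[moderate] < 0)

    def test_reinforcement_increases_with_bond_stress(self, sweep_table):
        table = sweep_table
        for (z, u), grp in table[table.u_mm > 0].groupby(["Z_mm", "u_mm"]):
            ds = grp.sort_values("tau_kpa")["dS_kpa"].to_numpy()
            assert np.all(np.diff(ds) > 0)
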