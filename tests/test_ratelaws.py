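"""Efficiency factors, tiered cost functions, gradients, convexity."""

import numpy as np
import pytest

import ecmkit as ek
from ecmkit.exceptions import InfeasiblePointError, MissingParameterError
from ecmkit.ratelaws import VARIANTS, burdens, eta_kin

from conftest import random_feasible_points

GRADIENT_VARIANTS = [v for v in VARIANTS if v not in ("EMC0", "EMC1")]


def _ab_bundle(kf=2.0, kr=1.0, ks=1.0, kp=1.0, v=1.0):
    net = ek.NetworkModel(["S", "P"], ["R"], np.array([[-1.0], [1.0]]),
                          np.array([False, False]), np.array([np.nan, np.nan]))
    keq = kf * kp / (kr * ks)
    par = ek.KineticParameters([kf], [kr], np.array([[ks], [kp]]),
                               [keq], [-np.log(keq)], [1.0], [np.nan])
    return net, par, ek.FluxProfile([v])


class TestEtaRev:
    def test_zero_at_equilibrium(self):
        assert ek.eta_rev(0.0) == 0.0

    def test_small_force_printed_value(self):
        """At Theta = 0.1 only ~10% of the forward flux survives."""
        val = ek.eta_rev(0.1)
        assert val == pytest.approx(1 - np.exp(-0.1), rel=1e-12)
        assert round(val, 1) == 0.1  # one significant figure

    def test_half_at_ln2(self):
        assert ek.eta_rev(np.log(2)) == pytest.approx(0.5, rel=1e-12)

    def test_properties(self):
        thetas = np.linspace(-1, 20, 500)
        vals = ek.eta_rev(thetas)
        assert np.all(vals >= 0) and np.all(vals < 1)
        pos = thetas > 0
        assert np.all(np.diff(vals[pos]) > 0)  # strictly increasing
        assert np.all(vals[pos] <= thetas[pos])  # 1 - e^-x <= x


class TestEtaKin:
    def test_saturation_limit_1s(self):
        net, par, flux = _ab_bundle()
        x = np.array([np.log(1e9), 0.0])
        assert eta_kin(x, 0, net, par, "EMC3S") == pytest.approx(1.0, rel=1e-6)

    def test_1sp_at_unit_ratios(self):
        """s/K_S = p/K_P = 1 gives S/(1+S+P) = 1/3."""
        net, par, flux = _ab_bundle(ks=1.0, kp=1.0)
        x = np.zeros(2)
        assert eta_kin(x, 0, net, par, "EMC3SP") == pytest.approx(1 / 3, rel=1e-12)

    def test_cm_denominator_at_unit_ratios(self):
        """Common modular law: S / ((1+s/K)(...) + (1+p/K)(...) - 1) = 1/3."""
        net, par, flux = _ab_bundle()
        x = np.zeros(2)
        assert eta_kin(x, 0, net, par, "EMC4CM") == pytest.approx(1 / 3, rel=1e-12)

    def test_cm_equals_3sp_for_one_one_reactions(self, toy_bundle):
        net, par, flux, _, _ = toy_bundle
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, 4)
            for l in range(3):
                assert eta_kin(x, l, net, par, "EMC4CM") == pytest.approx(
                    eta_kin(x, l, net, par, "EMC3SP"), rel=1e-12)

    def test_noncompetitive_inhibitor_halves_at_ki(self):
        net, par, flux = _ab_bundle()
        par.modifiers.append((0, 1, 1.0, "noncompetitive"))  # P inhibits R
        spec = ek.CostFunctionSpec(variant="EMC4CM")
        x = np.array([np.log(4.0), 0.0])  # c_I = K_I = 1 mM
        _, _, bd = ek.enzyme_cost(x, net, par, flux, spec)
        assert bd.eta_reg[0] == pytest.approx(0.5, rel=1e-12)

    def test_stoichiometric_exponents(self):
        """2 S <=> P uses (s/K)^2 in the mass-action term."""
        net = ek.NetworkModel(["S", "P"], ["R"], np.array([[-2.0], [1.0]]),
                              np.array([False, False]), np.array([np.nan, np.nan]))
        par = ek.KineticParameters([1.0], [1.0], np.array([[1.0], [1.0]]),
                                   [100.0], [-np.log(100.0)], [1.0], [np.nan])
        x = np.array([np.log(2.0), np.log(1.0)])
        S, P = 4.0, 1.0
        assert eta_kin(x, 0, net, par, "EMC3SP") == pytest.approx(S / (1 + S + P))


class TestEnzymeDemand:
    def test_direct_evaluation_of_reversible_mm(self):
        """All constants 1, v = 1, s = 2, p = 1: E = (1+2+1)/(2-1) = 4."""
        net, par, flux = _ab_bundle(kf=1.0, kr=1.0)
        x = np.array([np.log(2.0), np.log(1.0)])
        E = ek.enzyme_demand(x, net, par, flux, ek.CostFunctionSpec(variant="EMC4CM"))
        assert E[0] == pytest.approx(4.0, rel=1e-9)

    def test_capacity_limit(self):
        """Saturated substrate, no product: E -> v / kcat+."""
        net, par, flux = _ab_bundle(kf=5.0, v=2.0)
        x = np.array([np.log(1e8), np.log(1e-8)])
        E = ek.enzyme_demand(x, net, par, flux, ek.CostFunctionSpec(variant="EMC4CM"))
        assert E[0] == pytest.approx(2.0 / 5.0, rel=1e-4)

    def test_zero_driving_force_is_infeasible(self):
        net, par, flux = _ab_bundle(kf=1.0, kr=1.0)  # K_eq = 1
        x = np.zeros(2)  # s = p -> Theta = 0
        with pytest.raises(InfeasiblePointError, match="R"):
            ek.enzyme_demand(x, net, par, flux, ek.CostFunctionSpec(variant="EMC3SP"))

    @pytest.mark.parametrize("variant", GRADIENT_VARIANTS)
    def test_inverse_rate_law_roundtrip(self, variant, toy_bundle):
        """E * kcat+ * eta_rev * eta_sat * eta_reg reproduces the flux."""
        net, par, flux, _, _ = toy_bundle
        rng = np.random.default_rng(2)
        spec = ek.CostFunctionSpec(variant=variant)
        poly = ek.build_polytope(net, par, flux,
                                 ek.ConcentrationBounds(np.full(4, 1e-3), np.full(4, 10.0)))
        for xf in random_feasible_points(poly, 10, seed=2):
            x = poly.lift(xf)
            _, _, bd = ek.enzyme_cost(x, net, par, flux, spec)
            v_back = bd.demand * par.kcat_fwd * bd.eta_rev * bd.eta_sat * bd.eta_reg
            np.testing.assert_allclose(v_back, flux.v, rtol=1e-9)


class TestEnzymeCost:
    def test_emc1_toy_value(self, toy_bundle):
        """h = kcat = 1, v = 1 over three reactions: q = 3."""
        net, par, flux, _, _ = toy_bundle
        q, grad, _ = ek.enzyme_cost(np.zeros(4), net, par, flux,
                                    ek.CostFunctionSpec(variant="EMC1"))
        assert q == pytest.approx(3.0)
        np.testing.assert_allclose(grad, 0.0)

    def test_emc0_is_sum_of_fluxes(self, toy_bundle):
        net, par, flux, _, _ = toy_bundle
        q, grad, _ = ek.enzyme_cost(np.zeros(4), net, par, flux,
                                    ek.CostFunctionSpec(variant="EMC0"))
        assert q == pytest.approx(np.sum(flux.v))
        np.testing.assert_allclose(grad, 0.0)

    def test_emc2s_at_equal_forces(self, toy_bundle):
        """Equal split of ln 100: q = 3 / (1 - e^(-ln(100)/3))."""
        net, par, flux, _, _ = toy_bundle
        theta = np.log(100) / 3
        x = np.array([0.0, -theta, -2 * theta, np.log(0.01)])
        q, _, _ = ek.enzyme_cost(x, net, par, flux,
                                 ek.CostFunctionSpec(variant="EMC2S"))
        assert q == pytest.approx(3 / (1 - np.exp(-theta)), rel=1e-9)
        assert q == pytest.approx(3.824, abs=5e-4)

    @pytest.mark.parametrize("variant", GRADIENT_VARIANTS)
    def test_gradient_matches_finite_differences(self, variant, toy_polytope, toy_bundle):
        net, par, flux, _, _ = toy_bundle
        par = ek.KineticParameters(par.kcat_fwd, par.kcat_rev, par.K_M, par.K_eq,
                                   par.dG0_over_RT, par.burden, par.protein_mass,
                                   modifiers=[(0, 2, 0.5, "noncompetitive")])
        spec = ek.CostFunctionSpec(variant=variant)
        h = 1e-6
        for xf in random_feasible_points(toy_polytope, 5, seed=4):
            x = toy_polytope.lift(xf)
            _, grad, _ = ek.enzyme_cost(x, net, par, flux, spec)
            for i in range(4):
                dx = np.zeros(4)
                dx[i] = h
                qp, _, _ = ek.enzyme_cost(x + dx, net, par, flux, spec)
                qm, _, _ = ek.enzyme_cost(x - dx, net, par, flux, spec)
                fd = (qp - qm) / (2 * h)
                assert grad[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_tier_hierarchy_at_random_feasible_points(self, toy_bundle, toy_polytope):
        """EMC1 <= EMC2 <= EMC3 <= EMC4 pointwise: each tier lower-bounds
        the next (within its S/SP family)."""
        net, par, flux, _, _ = toy_bundle
        chains = [("EMC1", "EMC2S", "EMC3S"), ("EMC1", "EMC2SP", "EMC3SP", "EMC4CM")]
        for xf in random_feasible_points(toy_polytope, 50, seed=5):
            x = toy_polytope.lift(xf)
            for chain in chains:
                qs = [ek.enzyme_cost(x, net, par, flux,
                                     ek.CostFunctionSpec(variant=v),
                                     with_breakdown=False)[0]
                      for v in chain]
                assert np.all(np.diff(qs) >= -1e-9)

    def test_factorization_matches_direct_rate_law(self):
        """Eq-style direct reversible MM rate equals E kcat+ eta_rev eta_kin."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            kf, kr, ks, kp = np.exp(rng.normal(0, 1, 4))
            net, par, flux = _ab_bundle(kf=kf, kr=kr, ks=ks, kp=kp)
            s, p = np.exp(rng.normal(0, 1, 2))
            theta = np.log(par.K_eq[0] * s / p)
            if theta <= 1e-6:
                continue
            direct = (kf * s / ks - kr * p / kp) / (1 + s / ks + p / kp)
            x = np.log([s, p])
            erev = ek.eta_rev(theta)
            ekin = eta_kin(x, 0, net, par, "EMC3SP")
            assert direct == pytest.approx(kf * erev * ekin, rel=1e-12)

    def test_emc2sp_depends_only_on_driving_force(self):
        net, par, flux = _ab_bundle(kf=3.0, kr=1.5, ks=2.0, kp=0.7)
        spec = ek.CostFunctionSpec(variant="EMC2SP")
        x1 = np.log([4.0, 1.0])
        x2 = x1 + 0.7  # same Theta (1:1 stoichiometry preserves the difference)
        q1, _, _ = ek.enzyme_cost(x1, net, par, flux, spec)
        q2, _, _ = ek.enzyme_cost(x2, net, par, flux, spec)
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_missing_km_rejected_for_saturation_tiers(self, toy_bundle):
        net, par, flux, _, _ = toy_bundle
        km = par.K_M.copy()
        km[1, 0] = np.nan
        par2 = ek.KineticParameters(par.kcat_fwd, par.kcat_rev, km, par.K_eq,
                                    par.dG0_over_RT, par.burden, par.protein_mass)
        from ecmkit.ratelaws import validate_spec
        with pytest.raises(MissingParameterError):
            validate_spec(ek.CostFunctionSpec(variant="EMC3SP"), net, par2, flux)
        validate_spec(ek.CostFunctionSpec(variant="EMC2S"), net, par2, flux)


class TestConvexity:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_midpoint_convexity_on_random_segments(self, variant, toy_bundle,
                                                   toy_polytope):
        net, par, flux, _, _ = toy_bundle
        spec = ek.CostFunctionSpec(variant=variant)
        pts = random_feasible_points(toy_polytope, 60, seed=8)
        for xa, xb in zip(pts[::2], pts[1::2]):
            qa = ek.enzyme_cost(toy_polytope.lift(xa), net, par, flux, spec,
                                with_breakdown=False)[0]
            qb = ek.enzyme_cost(toy_polytope.lift(xb), net, par, flux, spec,
                                with_breakdown=False)[0]
            qm = ek.enzyme_cost(toy_polytope.lift((xa + xb) / 2), net, par, flux,
                                spec, with_breakdown=False)[0]
            assert qm <= (qa + qb) / 2 + 1e-9


class TestFluxBurden:
    def test_ideal_conditions(self, toy_bundle):
        net, par, flux, _, _ = toy_bundle
        a_v, a_cat = ek.flux_burden(np.zeros(4), net, par, flux,
                                    ek.CostFunctionSpec(variant="EMC1"))
        np.testing.assert_allclose(a_v, par.burden / par.kcat_fwd)
        np.testing.assert_allclose(a_v, a_cat)

    def test_small_force_penalty(self):
        """h = kcat = 1, Theta = 0.1, full saturation: a_v = 1/(1-e^-0.1)."""
        net, par, flux = _ab_bundle(kf=1.0, kr=1.0)
        # K_eq = 1; choose s/p = e^0.1 -> Theta = 0.1
        x = np.array([0.1, 0.0])
        a_v, _ = ek.flux_burden(x, net, par, flux, ek.CostFunctionSpec(variant="EMC2S"))
        assert a_v[0] == pytest.approx(1 / (1 - np.exp(-0.1)), rel=1e-9)
        assert a_v[0] == pytest.approx(10.5, abs=0.01)

    def test_lower_bound_and_cost_identity(self, toy_bundle, toy_polytope):
        net, par, flux, _, _ = toy_bundle
        spec = ek.CostFunctionSpec(variant="EMC4CM")
        for xf in random_feasible_points(toy_polytope, 10, seed=9):
            x = toy_polytope.lift(xf)
            a_v, a_cat = ek.flux_burden(x, net, par, flux, spec)
            assert np.all(a_v >= a_cat - 1e-12)
            q, _, _ = ek.enzyme_cost(x, net, par, flux, spec, with_breakdown=False)
            assert np.sum(a_v * flux.v[flux.active_mask]) == pytest.approx(q, rel=1e-12)


class TestPathwaySpecificActivity:
    def test_doubling_enzyme_halves_activity(self):
        assert (ek.pathway_specific_activity(1.0, 2.0)
                == pytest.approx(ek.pathway_specific_activity(1.0, 4.0) * 2))

    def test_dimensional_oracle(self, toy_bundle):
        """m = 40 kDa, E = 1 mM each, v = 1 mM/s: A = v / sum(m E) in
        mmol/s per mg enzyme."""
        net, par, flux, _, _ = toy_bundle
        E = np.ones(3)
        # oracle computed from first principles: mass conc of one enzyme is
        # (1 mmol/L) * (40000 g/mol) = 40000 mg/L; three enzymes: 120000 mg/L
        q_mass = float(np.sum(par.protein_mass * E))
        assert q_mass == pytest.approx(120000.0)
        assert ek.pathway_specific_activity(1.0, q_mass) == pytest.approx(1 / 120000.0)

    def test_zero_flux(self):
        assert ek.pathway_specific_activity(0.0, 5.0) == 0.0

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError):
            ek.pathway_specific_activity(1.0, 0.0)


def test_burden_modes(toy_bundle):
    net, par, flux, _, _ = toy_bundle
    np.testing.assert_allclose(burdens(ek.CostFunctionSpec(burden_mode="uniform"), par), 1.0)
    np.testing.assert_allclose(burdens(ek.CostFunctionSpec(burden_mode="custom"), par),
                               par.burden)
    np.testing.assert_allclose(
        burdens(ek.CostFunctionSpec(burden_mode="protein_mass"), par), par.protein_mass)
    np.testing.assert_allclose(
        burdens(ek.CostFunctionSpec(burden_mode="chain_length"), par), 1.0)
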