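"""Analytic Pennes solution: particular terms, boundary conditions, oracles."""

import math
from dataclasses import replace

import numpy as np
import pytest

from mmwskin.bioheat_analytic import (
    assemble_and_solve,
    boundary_residuals,
    delta_T,
    particular_term,
)
from mmwskin.bioheat_fd import build_grid, delta_T_fd
from mmwskin.dielectrics import ETA0, PropagationTriple
from mmwskin.em_solver import LayerWave, sar_at, solve_stack_em
from mmwskin.layer_models import LayerStack, TissueLayer, fixture_stack

from conftest import TEST_TISSUES, make_stack, random_stack


def _layer(**over):
    base = dict(
        name="probe", thickness=1e-3, kappa=1.0, rho=1000.0,
        metabolic_rate=0.0, perfusion_term=0.0, dielectric_ref="skin",
    )
    base.update(over)
    return TissueLayer(**base)


def _wave(tau=1.0 + 0j, upsilon=0j, alpha=500.0, beta=800.0, sigma=0.03, d=1e-3):
    return LayerWave(
        tau=tau, upsilon=upsilon,
        prop=PropagationTriple(alpha=alpha, beta=beta, eta=100.0 + 10.0j),
        sigma=sigma, z_top=0.0, thickness=d, gamma_bot=0j,
    )


def _ode_residual(src, layer, n_points=100):
    """Max |kappa S'' - B S + rho SAR| over interior points, by central
    differences of the closed-form S (independent of the kernel algebra)."""
    d = layer.thickness
    zz = np.linspace(0.05 * d, 0.95 * d, n_points)
    h = min(3e-7, d / 64.0)
    s_mid = src.value(zz)
    s2 = (src.value(zz + h) - 2.0 * s_mid + src.value(zz - h)) / h**2
    res = layer.kappa * s2 - layer.perfusion_term * s_mid + src.rho_sar(zz)
    peak = np.max(np.abs(src.rho_sar(np.linspace(0.0, d, 400))))
    return float(np.max(np.abs(res))), float(peak)


class TestParticularTerm:
    def test_lossless_layer_gives_zero_source(self):
        src = particular_term(_layer(), _wave(sigma=0.0), 1000.0)
        assert src.terms == ()
        assert src.value(5e-4) == 0.0
        assert src.slope(5e-4) == 0.0

    def test_zero_state_anchor(self):
        src = particular_term(
            _layer(perfusion_term=4000.0), _wave(upsilon=0.2 - 0.1j), 1000.0
        )
        assert src.value(0.0) == pytest.approx(0.0, abs=1e-18)
        assert src.slope(0.0) == pytest.approx(0.0, abs=1e-14)

    def test_pure_exponential_closed_form(self):
        """B=0, SAR = S0 e^{-2 a z}, kappa=1:
        S(z) = -rho S0/(4 a^2) (e^{-2 a z} - 1 + 2 a z)."""
        alpha, rho, s0, p = 500.0, 1000.0, 10.0, 1000.0
        sigma = rho * s0 / (p * ETA0)
        layer = _layer(rho=rho)
        src = particular_term(layer, _wave(alpha=alpha, sigma=sigma), p)
        for z in (1e-4, 4e-4, 9e-4):
            expected = -rho * s0 / (4 * alpha**2) * (
                math.exp(-2 * alpha * z) - 1.0 + 2 * alpha * z
            )
            assert src.value(z) == pytest.approx(expected, rel=1e-12)

    def test_symbolic_double_integration_oracle(self):
        """Independent sympy evaluation of S = -(1/kappa) int (z-u) rho SAR du
        for the B=0 exponential case."""
        sympy = pytest.importorskip("sympy")
        alpha, rho, s0, p = 500.0, 1000.0, 10.0, 1000.0
        sigma = rho * s0 / (p * ETA0)
        src = particular_term(_layer(rho=rho), _wave(alpha=alpha, sigma=sigma), p)
        z, u = sympy.symbols("z u", positive=True)
        s_sym = -sympy.integrate(
            (z - u) * rho * s0 * sympy.exp(-2 * alpha * u), (u, 0, z)
        )
        for zz in (2e-4, 7e-4):
            expected = float(s_sym.subs(z, zz))
            assert src.value(zz) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("part", ["rat_head", "rat_dorsal", "human_forearm"])
    def test_ode_residual_fixture_layers(self, part):
        """kappa S'' - B S + rho SAR vanishes to 1e-6 of the layer's peak
        heating over 100 interior points, at 30 GHz."""
        st = fixture_stack(part)
        em = solve_stack_em(st, 30e9, 1000.0)
        for layer, wave in zip(st.layers, em.waves):
            src = particular_term(layer, wave, em.p)
            res, peak = _ode_residual(src, layer)
            assert res < 1e-6 * peak

    def test_degenerate_denominator_limit(self):
        """At B = 4 a^2 kappa the resonant closed form stays finite, anchored
        and ODE-consistent, and joins the regular branch continuously."""
        alpha, kappa = 100.0, 0.5
        b_res = 4.0 * alpha**2 * kappa
        layer = _layer(kappa=kappa, perfusion_term=b_res)
        wave = _wave(tau=1.0 + 0.2j, upsilon=0.1 - 0.05j, alpha=alpha)
        src = particular_term(layer, wave, 1000.0)
        res, peak = _ode_residual(src, layer)
        assert res < 1e-6 * peak
        # continuity across the series switch
        near = particular_term(
            replace(layer, perfusion_term=b_res * (1.0 + 1e-7)), wave, 1000.0
        )
        z = 8e-4
        assert near.value(z) == pytest.approx(src.value(z), rel=1e-5)


class TestBoundaryConditions:
    def test_two_resistor_conduction_profile(self):
        """No sources: the baseline is the textbook series-resistance
        solution between the Robin surface and the clamped core."""
        st = make_stack(
            [
                (2e-3, 0.3, 1000.0, 0.0, 0.0, "mild"),
                (5e-3, 0.6, 1000.0, 0.0, 0.0, "mild"),
            ],
            h=10.0,
        )
        sol = assemble_and_solve(st, None)
        r_tot = 1.0 / st.h + 2e-3 / 0.3 + 5e-3 / 0.6
        q = (st.T_body - st.T_air) / r_tot  # heat flux toward the surface
        assert sol.temperature(0.0) == pytest.approx(st.T_air + q / st.h, rel=1e-12)
        assert sol.temperature(2e-3) == pytest.approx(
            st.T_air + q / st.h + q * 2e-3 / 0.3, rel=1e-12
        )
        assert sol.temperature(7e-3) == pytest.approx(st.T_body, rel=1e-12)

    def test_source_free_maximum_principle(self, rat_head):
        """With metabolism switched off the baseline surface temperature lies
        strictly between the air and core temperatures."""
        stripped = LayerStack(
            name="head_no_A",
            layers=tuple(replace(la, metabolic_rate=0.0) for la in rat_head.layers),
            h=rat_head.h, T_air=rat_head.T_air,
            T_blood=rat_head.T_blood, T_body=rat_head.T_body,
        )
        sol = assemble_and_solve(stripped, None)
        assert rat_head.T_air < sol.surface_temperature < rat_head.T_body

    def test_metabolic_heat_can_exceed_core(self, rat_head):
        """With the packaged metabolic rates the brain equilibrium
        T_blood + A/B sits above the core, so the baseline surface does too:
        the pure maximum principle applies only to the source-free problem."""
        sol = assemble_and_solve(rat_head, None)
        t_eq_max = max(
            la.metabolic_rate / la.perfusion_term
            for la in rat_head.layers if la.perfusion_term > 0
        ) + rat_head.T_blood
        assert rat_head.T_body < sol.surface_temperature < t_eq_max

    @pytest.mark.parametrize("part", ["rat_head", "rat_dorsal", "human_forearm"])
    @pytest.mark.parametrize("exposed", [False, True])
    def test_interface_and_boundary_residuals(self, part, exposed):
        """T and kappa dT/dz continuity plus Robin/Dirichlet residuals at
        machine-precision scale."""
        st = fixture_stack(part)
        em = solve_stack_em(st, 30e9, 1000.0) if exposed else None
        res = boundary_residuals(assemble_and_solve(st, em))
        assert abs(res["robin"]) < 1e-9
        assert abs(res["dirichlet"]) < 1e-9
        assert np.max(np.abs(res["temperature_jumps"])) < 1e-9
        assert np.max(np.abs(res["flux_jumps"])) < 1e-9


class TestDeltaT:
    def test_zero_power_means_zero_elevation(self, rat_head):
        prof = delta_T(rat_head, 30e9, 0.0)
        z = np.linspace(0, rat_head.total_thickness, 40)
        assert np.max(np.abs(prof(z))) < 1e-12

    def test_linearity_in_power(self, rat_dorsal):
        p1 = delta_T(rat_dorsal, 60e9, 500.0)
        p2 = delta_T(rat_dorsal, 60e9, 1000.0)
        z = np.linspace(0, rat_dorsal.total_thickness, 60)
        assert np.allclose(p2(z), 2.0 * p1(z), rtol=1e-11, atol=1e-13)

    def test_nonnegative_and_clamped_at_core(self, rat_head):
        prof = delta_T(rat_head, 30e9, 1000.0)
        z = np.linspace(0, rat_head.total_thickness, 200)
        assert np.all(prof(z) > -1e-10)
        assert prof(rat_head.total_thickness) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("part", ["rat_head", "rat_dorsal", "human_forearm"])
    def test_fd_oracle_agreement_fixtures(self, part):
        """Closed-form Delta T matches the independent finite-difference
        solve to well under 0.5% of the peak at 30 GHz."""
        st = fixture_stack(part)
        prof = delta_T(st, 30e9, 1000.0)
        z, dt_fd = delta_T_fd(st, prof.em)
        err = np.max(np.abs(prof(z) - dt_fd)) / np.max(np.abs(dt_fd))
        assert err < 5e-3

    @pytest.mark.parametrize("seed", range(3))
    def test_fd_oracle_agreement_random_stacks(self, seed):
        rng = np.random.default_rng(9000 + seed)
        st = random_stack(rng)
        f = float(rng.choice([6e9, 30e9, 60e9, 100e9]))
        em = solve_stack_em(st, f, 1000.0, tissues=TEST_TISSUES)
        prof = delta_T(st, f, 1000.0, tissues=TEST_TISSUES, em=em)
        z, dt_fd = delta_T_fd(st, em)
        err = np.max(np.abs(prof(z) - dt_fd)) / max(np.max(np.abs(dt_fd)), 1e-12)
        assert err < 5e-3

    def test_mismatched_em_solution_rejected(self, rat_head):
        em = solve_stack_em(rat_head, 30e9, 1000.0)
        with pytest.raises(ValueError, match="match"):
            delta_T(rat_head, 60e9, 1000.0, em=em)
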