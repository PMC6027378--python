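"""Scalar balances: conservation, budgets, positivity, growth dynamics."""

import numpy as np
import pytest

from conftest import empty_duct
from scaffoldsim import transport as tr
from scaffoldsim.flow import StokesSolver, MU_FLUID, solve_flow
from scaffoldsim.geometry import UnitDesign, voxelize
from scaffoldsim.kinetics import KineticParams, growth_rate


@pytest.fixture
def p():
    return KineticParams()


class TestConservation:
    def test_closed_box_mass_conserved(self, p):
        """No reaction, no flow: diffusion conserves total mass ~exactly."""
        dom = empty_duct(8, 8, 8)
        st = tr.ScalarTransport(dom, closed=True)
        rng = np.random.default_rng(7)
        c = rng.random(dom.shape)
        theta = np.ones(dom.shape)
        D = np.full(dom.shape, p.Dgf)
        m0 = c.sum()
        for _ in range(5):
            c, _ = st.step(c, theta, D, None, 3600.0, key="s")
            assert abs(c.sum() - m0) / m0 < 1e-10
        assert c.min() >= 0

    def test_uniform_field_is_steady(self, p):
        dom = empty_duct(8, 8, 8)
        st = tr.ScalarTransport(dom, closed=True)
        c = np.full(dom.shape, 2.5)
        c1, _ = st.step(c, np.ones(dom.shape), np.full(dom.shape, p.Dgf),
                        None, 3600.0, key="s")
        assert np.allclose(c1, 2.5, rtol=1e-12)

    def test_two_sided_dirichlet_linear_profile(self, p):
        """1-D steady diffusion between fixed concentrations is linear."""
        dom = empty_duct(32, 4, 4)
        st = tr.ScalarTransport(dom)
        c = np.zeros(dom.shape)
        D = np.full(dom.shape, p.Dgf)
        theta = np.ones(dom.shape)
        # iterate to steady state with large dt
        for _ in range(60):
            c, _ = st.step(c, theta, D, None, 1e7, inlet_value=1.0,
                           outlet_value=0.0, key="s")
        prof = c[:, 2, 2]
        x = (np.arange(32) + 0.5) / 32
        expected = 1.0 - x
        assert np.abs(prof - expected).max() < 1e-3
        # flux = D * dc/L through any face
        L = 200e-6
        flux_exact = p.Dgf * 1.0 / L
        grad = (prof[0] - prof[1]) / (L / 32)
        assert p.Dgf * grad == pytest.approx(flux_exact, rel=0.05)


class TestBudgets:
    def test_closed_box_sink_budget(self, p):
        """Glucose decrease equals the integrated uptake sink."""
        dom = voxelize(UnitDesign(r=100, delta_y=50, delta_z=0), 16)
        state = tr.init_state(dom, p, 5e7, 4.5)
        st = tr.ScalarTransport(dom, closed=True)
        theta0 = np.where(state.shell,
                          (1 - state.eps_c) + p.Keq * state.eps_c, 1.0)
        m0 = (theta0 * state.c_gf)[st.F].sum() * st.V
        s1 = tr.step_glucose(state, None, p, 600.0, st, glin=4.5)
        m1 = (theta0 * s1.c_gf)[st.F].sum() * st.V
        assert m0 - m1 == pytest.approx(s1.glucose_consumed, rel=0.01)
        assert s1.glucose_consumed > 0

    def test_lactate_stoichiometry(self, p):
        """Cumulative lactate produced = 2 x glucose consumed."""
        dom = voxelize(UnitDesign(r=100, delta_y=50, delta_z=0), 16)
        state = tr.init_state(dom, p, 5e7, 4.5)
        st = tr.ScalarTransport(dom, closed=True)
        for _ in range(5):
            state = tr.step_glucose(state, None, p, 3600.0, st, glin=4.5)
            state = tr.step_lactate(state, None, p, 3600.0, st)
        assert state.lactate_produced == pytest.approx(
            2.0 * state.glucose_consumed, rel=1e-9)

    def test_advective_steady_outflux_matches_production(self, p):
        """At steady state the outlet lactate flux equals total Rl."""
        dom = voxelize(UnitDesign(r=100, delta_y=40, delta_z=0), 16)
        state = tr.init_state(dom, p, 5e7, 4.5)
        from scaffoldsim.flow import viscosity_from_cell_fraction
        mu = viscosity_from_cell_fraction(
            np.where(dom.biomass, state.eps_c, 0.0))
        flow = StokesSolver(dom).solve(mu, 1e-3)
        st = tr.ScalarTransport(dom)
        for _ in range(40):
            state = tr.step_glucose(state, flow, p, 3600.0, st, glin=4.5)
            state = tr.step_lactate(state, flow, p, 3600.0, st)
        # steady: production rate = outlet advective flux
        prod = 2.0 * state.last_uptake.sum() * st.V  # kg/s
        hy, hz = dom.spacing_m[1:]
        out_flux = (np.maximum(flow.u[-1], 0) * hy * hz *
                    state.c_l[-1]).sum()
        assert out_flux == pytest.approx(prod, rel=0.02)


class TestBiomass:
    def test_no_rates_no_change(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 0.0)
        p0 = p.replace(Kg0=0.0, rd=0.0)
        tau = np.zeros(small_domain.shape)
        s1 = tr.step_biomass(state, tau, p0, 3600.0, small_domain)
        assert np.array_equal(s1.eps_c, state.eps_c)

    def test_exponential_growth_oracle(self, p):
        """Constant-rate growth matches exp(rg t) over 10 hourly steps."""
        p2 = p.replace(Kc=0.0)  # saturated: rg = Kg(tau) exactly
        dom = voxelize(UnitDesign(r=100, delta_y=50, delta_z=0), 16)
        s = tr.init_state(dom, p2, 5e7, 4.5)
        eps0 = s.eps_c.copy()
        tau = np.full(dom.shape, 0.3)
        rg = growth_rate(p2.Keq * 4.5, 0.1, 0.3, p2)
        for _ in range(10):
            s = tr.step_biomass(s, tau, p2, 3600.0, dom,
                                max_area_density=np.inf)
        m = s.shell
        expected = eps0[m] * np.exp(rg * 36000.0)
        assert np.abs(s.eps_c[m] / expected - 1).max() < 5e-3

    def test_acidic_collapse_removes_population(self, p, small_domain):
        """pH below threshold wipes the population in literal gate mode."""
        state = tr.init_state(small_domain, p, 5e7, 4.5)
        state.c_l[:] = 20.0  # pH = 7.4 - 0.812 < 6.8 everywhere
        tau = np.zeros(small_domain.shape)
        s1 = tr.step_biomass(state, tau, p, 3600.0, small_domain)
        assert s1.eps_c.max() == 0.0

    def test_freeze_gate_keeps_population(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 4.5)
        state.c_l[:] = 20.0
        tau = np.zeros(small_domain.shape)
        s1 = tr.step_biomass(state, tau, p, 3600.0, small_domain,
                             gate_mode="freeze")
        assert np.array_equal(s1.eps_c, state.eps_c)

    def test_lethal_shear_stops_growth(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 4.5)
        tau = np.full(small_domain.shape, 1.5)
        s1 = tr.step_biomass(state, tau, p, 3600.0, small_domain)
        assert np.allclose(s1.eps_c, state.eps_c)

    def test_area_cap_bounds_column_density(self, p):
        """The per-column cell count never exceeds the attachment cap."""
        dom = voxelize(UnitDesign(r=100, delta_y=0, delta_z=0,
                                  cultured_surfaces=("bottom",)), 16)
        p2 = p.replace(Kc=0.0)
        s = tr.init_state(dom, p2, 5e7, 4.5)
        tau = np.full(dom.shape, 0.3)
        for _ in range(40):
            s = tr.step_biomass(s, tau, p2, 3600.0, dom)
        vvol = dom.voxel_volume_m3()
        vcell = tr.cell_volume_m3(p2)
        n_col = s.eps_c.sum(axis=2) * vvol / vcell
        hx, hy, _ = dom.spacing_m
        cap = (1.0 / p2.dc ** 2) * hx * hy
        assert n_col.max() <= cap * (1 + 1e-9)


class TestIntegrate:
    def test_zero_steps_returns_initial(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 4.5)
        final, diag = tr.integrate(state, small_domain, p, 3600.0, 0,
                                   3e-3, 4.5)
        assert final is state and len(diag) == 0

    def test_no_substrate_no_growth(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 0.0)
        final, diag = tr.integrate(state, small_domain, p, 3600.0, 4,
                                   3e-3, 0.0)
        assert final.mean_shell_density_cm3(p) <= \
            state.mean_shell_density_cm3(p) * (1 + 1e-12)

    def test_positivity_and_budgets(self, p, small_domain):
        state = tr.init_state(small_domain, p, 5e7, 4.5)
        final, diag = tr.integrate(state, small_domain, p, 3600.0, 6,
                                   3e-3, 4.5)
        assert final.c_gf.min() >= 0 and final.c_l.min() >= 0
        assert 0 <= final.eps_c.max() <= 1
        assert final.lactate_produced == pytest.approx(
            2 * final.glucose_consumed, rel=1e-9)
        assert (diag["mean_density_cm3"] > 0).all()

    def test_time_step_independence(self, p):
        """Halving dt changes the final mean density by < 1%."""
        dom = voxelize(UnitDesign(r=100, delta_y=30, delta_z=30), 16)
        s0 = tr.init_state(dom, p, 5e7, 4.5)
        f1, _ = tr.integrate(s0.copy(), dom, p, 3600.0, 12, 3e-3, 4.5)
        f2, _ = tr.integrate(s0.copy(), dom, p, 1800.0, 24, 3e-3, 4.5)
        d1 = f1.mean_shell_density_cm3(p)
        d2 = f2.mean_shell_density_cm3(p)
        assert abs(d1 - d2) / d2 < 0.01
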