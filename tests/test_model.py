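"""Model core: flux terms, delay chains, fixed point, conservation laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipoflux import (
    ModelParameters,
    SolverSettings,
    atl_rate,
    delay_chain_rhs,
    delay_chain_step_response,
    glucose_flux,
    initial_state,
    simulate,
    spill_fraction,
    tg_flux,
)
from adipoflux.exceptions import (
    DegenerateDelayError,
    InitializationError,
    ParameterError,
)
from adipoflux.model import STATE_NAMES, _make_rhs


class TestFluxTerms:
    def test_tg_flux_product(self):
        # baseline LPL rate constant times TG and delayed insulin
        assert tg_flux(0.0096, 1.0, 20.0) == pytest.approx(0.192)
        assert tg_flux(0.0096, 1.0, 0.0) == 0.0
        assert tg_flux(0.0096, 2.0, 20.0) == pytest.approx(2 * 0.192)

    def test_spill_fraction_definition(self):
        assert spill_fraction(30.0, 8.0, 8.0) == pytest.approx(0.30)
        assert spill_fraction(30.0, 8.0, 16.0) == pytest.approx(0.15)

    def test_spill_fraction_clamped(self):
        # 130% would be unphysical; clamp to 1
        assert spill_fraction(130.0, 8.0, 8.0) == 1.0

    def test_spill_fraction_guards_zero_insulin(self):
        with pytest.raises(ParameterError):
            spill_fraction(30.0, 8.0, 0.0)

    def test_glucose_flux_arithmetic(self):
        assert glucose_flux(0.1, 0.01, 5.0, 20.0) == pytest.approx(1.5)
        assert glucose_flux(0.1, 0.0, 5.0, 20.0) == pytest.approx(0.5)
        assert glucose_flux(0.1, 0.01, 0.0, 20.0) == 0.0

    def test_atl_rate_shape(self):
        assert atl_rate(0.05, 0.35, 10.0, 0.0) == pytest.approx(0.40)
        assert atl_rate(0.05, 0.35, 10.0, 10.0) == pytest.approx(0.05 + 0.175)
        assert atl_rate(0.05, 0.35, 10.0, 1e9) == pytest.approx(0.05, abs=1e-8)

    def test_atl_rate_requires_k(self):
        with pytest.raises(ParameterError):
            atl_rate(0.05, 0.35, 0.0, 5.0)

    @settings(deadline=None, max_examples=50)
    @given(i1=st.floats(0.0, 200.0), i2=st.floats(0.0, 400.0))
    def test_atl_monotone_decreasing_in_insulin(self, i1, i2):
        lo, hi = sorted((i1, i2))
        assert atl_rate(0.05, 0.35, 10.0, hi) <= atl_rate(0.05, 0.35, 10.0, lo)
        # strictly decreasing once the gap is resolvable in float arithmetic
        if hi > lo * (1 + 1e-9) + 1e-9:
            assert atl_rate(0.05, 0.35, 10.0, hi) < atl_rate(0.05, 0.35, 10.0, lo)

    @settings(deadline=None, max_examples=50)
    @given(i1=st.floats(1.0, 200.0), i2=st.floats(1.0, 400.0))
    def test_spill_monotone_decreasing_in_insulin(self, i1, i2):
        lo, hi = sorted((i1, i2))
        if hi > lo:
            assert spill_fraction(10.0, 8.0, hi) <= spill_fraction(10.0, 8.0, lo)


class TestDelayChain:
    def test_steady_state(self):
        assert delay_chain_rhs((7.0, 7.0, 7.0), 7.0, 30.0) == (0.0, 0.0, 0.0)

    def test_zero_tau_rejected(self):
        with pytest.raises(DegenerateDelayError):
            delay_chain_rhs((1.0, 1.0, 1.0), 5.0, 0.0)

    @pytest.mark.parametrize("tau", [17.13, 21.19, 112.76, 156.92])
    def test_step_response_matches_closed_form(self, tau):
        """Numerical chain vs the analytic Erlang(3) cumulative response."""
        from scipy.integrate import solve_ivp

        i0 = 10.0
        sol = solve_ivp(
            lambda t, y: delay_chain_rhs(y, i0, tau), (0.0, 600.0),
            [0.0, 0.0, 0.0], rtol=1e-10, atol=1e-12, dense_output=True,
        )
        t = np.linspace(1.0, 600.0, 120)
        numeric = sol.sol(t)[2]
        analytic = delay_chain_step_response(t, i0, tau)
        assert np.max(np.abs(numeric - analytic) / np.abs(analytic)) < 1e-6


class TestInitialState:
    def test_fixed_point_has_zero_derivatives(self, truth_params, clean_forcing):
        from adipoflux.forcing import ForcingSet

        y0 = initial_state(truth_params, clean_forcing)
        # freeze forcings at fasting values
        nodes = {a: (xp, np.full_like(xp, clean_forcing.fasting[a]))
                 for a, (xp, _) in clean_forcing.nodes.items()}
        frozen = ForcingSet(nodes=nodes,
                            basal_insulin=clean_forcing.basal_insulin,
                            fasting=dict(clean_forcing.fasting))
        rhs = _make_rhs(truth_params, frozen)
        dy = np.abs(np.array(rhs(0.0, y0)))
        assert np.all(dy < 1e-8)

    def test_fasting_glycerol_closed_form(self, truth_params, clean_forcing):
        p, fc = truth_params, clean_forcing
        y0 = initial_state(p, fc)
        i_b = fc.basal_insulin
        lpl = p.k_ad * fc.fasting["tg"] * i_b
        atl = p.b_atl + p.atl_max / (1 + i_b / p.k_atl)
        expected = fc.fasting["glycerol"] + lpl + atl / p.p_gly
        assert y0[STATE_NAMES.index("GLY_AT")] == pytest.approx(expected)

    def test_pure_diffusion_equilibrium(self, clean_forcing):
        """With all lipolysis/uptake shut off the adipose pools equal plasma."""
        p = ModelParameters.baseline().replace(
            k_ad=0.0, b_atl=0.0, atl_max=0.0, glut1=0.0, glut4=0.0,
            k_reester=0.0)
        y0 = initial_state(p, clean_forcing)
        assert y0[STATE_NAMES.index("GLY_AT")] == pytest.approx(
            clean_forcing.fasting["glycerol"])
        assert y0[STATE_NAMES.index("NEFA_AT")] == pytest.approx(
            clean_forcing.fasting["nefa"])

    def test_no_fixed_point_raises(self, clean_forcing):
        # G-3-P is produced but can never be consumed
        p = ModelParameters.baseline().replace(k_reester=0.0)
        with pytest.raises(InitializationError):
            initial_state(p, clean_forcing)


class TestSimulate:
    def test_null_model_all_fluxes_zero(self, clean_forcing):
        p = ModelParameters.baseline().replace(
            k_ad=0.0, b_atl=0.0, atl_max=0.0, glut1=0.0, glut4=0.0,
            k_reester=0.0, p_gly=0.0, p_nefa=0.0, d_spill=0.0)
        sim = simulate(p, clean_forcing)
        for s in ("tg", "glucose", "glycerol", "nefa"):
            np.testing.assert_allclose(sim.fluxes[s], 0.0, atol=1e-12)

    def test_constant_forcing_stays_at_fixed_point(self, truth_params,
                                                   clean_forcing):
        frozen = clean_forcing
        nodes = {a: (xp, np.full_like(xp, frozen.fasting[a]))
                 for a, (xp, _) in frozen.nodes.items()}
        from adipoflux.forcing import ForcingSet
        fc = ForcingSet(nodes=nodes, basal_insulin=frozen.basal_insulin,
                        fasting=dict(frozen.fasting))
        sim = simulate(truth_params, fc)
        y0 = initial_state(truth_params, fc)
        for i, name in enumerate(STATE_NAMES):
            np.testing.assert_allclose(sim.states[name], y0[i], rtol=1e-6,
                                       atol=1e-9)

    def test_tg_flux_peaks_after_insulin(self, truth_params, clean_forcing):
        """The delay chain makes the LPL response lag arterial insulin."""
        sim = simulate(truth_params, clean_forcing)
        t = sim.t
        i_art = clean_forcing("insulin", t)
        t_peak_insulin = t[np.argmax(i_art)]
        t_peak_tg = t[np.argmax(sim.fluxes["tg"])]
        assert t_peak_tg > t_peak_insulin + 30.0

    def test_fatty_acid_conservation_at_lpl_node(self, baseline_sim):
        r = baseline_sim.rates
        err = np.abs(r["nefa_spill"] + r["nefa_lpl_influx"]
                     - 3.0 * r["lpl_hydrolysis"])
        assert np.max(err) < 1e-9

    def test_glycerol_stoichiometry_at_lpl_node(self, baseline_sim):
        err = np.abs(baseline_sim.rates["gly_lpl_release"]
                     - baseline_sim.rates["lpl_hydrolysis"])
        assert np.max(err) < 1e-12

    def test_states_nonnegative(self, baseline_sim):
        for name, vals in baseline_sim.states.items():
            assert np.min(vals) >= -1e-10, name

    def test_solver_convergence(self, truth_params, clean_forcing):
        """Halving tolerances changes the flux curves by < 1e-6 relative."""
        s1 = simulate(truth_params, clean_forcing)
        tight = SolverSettings(rtol=5e-9, atol=5e-11)
        s2 = simulate(truth_params, clean_forcing, solver=tight)
        for name in s1.fluxes:
            a, b = s1.fluxes[name], s2.fluxes[name]
            scale = np.max(np.abs(a)) or 1.0
            assert np.max(np.abs(a - b)) / scale < 1e-6, name

    def test_no_delay_bypass(self, clean_forcing):
        """The bypass flag makes the LPL insulin signal instantaneous."""
        p = ModelParameters.baseline().replace(lpl_no_delay=True)
        sim = simulate(p, clean_forcing, t_grid=np.array([0.0, 60.0, 120.0]))
        i_art = clean_forcing("insulin", sim.t)
        np.testing.assert_allclose(
            sim.fluxes["tg"], p.k_ad * clean_forcing("tg", sim.t) * i_art,
            rtol=1e-9)

    def test_zero_tau_requires_bypass(self):
        with pytest.raises(DegenerateDelayError):
            ModelParameters.baseline().replace(tau_lpl=0.0)


class TestParameterValidation:
    def test_negative_parameter_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters.baseline().replace(k_ad=-0.1)

    def test_fraction_above_one_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters.baseline().replace(frac_use=1.2)

    def test_vector_round_trip(self, truth_params):
        v = truth_params.to_vector()
        assert ModelParameters.from_vector(v).to_vector() == pytest.approx(v)
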