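"""Whole-body model: fluxes, derivatives, conservation, limits, rebound."""
import math
from dataclasses import replace

import numpy as np
import pytest

import dialsim as ds
from dialsim.errors import AccuracyError, DialsimUserError
from dialsim.patient import (
    CapillaryParams,
    PhaseContext,
    SolutePatientParams,
    capillary_exchange,
    osmolarities,
)


def closed_system_params(params):
    """Disable osmotic and capillary water exchange for fixed-volume checks."""
    return replace(
        params,
        k_f=1e-12,
        capillary=replace(params.capillary, conductance_a=0.0),
    )


class TestOsmoticWaterFlux:
    def test_equilibrium_gives_zero(self):
        assert ds.osmotic_water_flux(285.0, 285.0, 0.24) == 0.0

    def test_linearity_in_kf(self):
        f1 = ds.osmotic_water_flux(290.0, 285.0, 0.24)
        f2 = ds.osmotic_water_flux(290.0, 285.0, 0.48)
        assert f2 == pytest.approx(2 * f1)

    def test_water_moves_toward_higher_osmolarity(self):
        assert ds.osmotic_water_flux(290.0, 285.0, 0.24) > 0  # into cells
        assert ds.osmotic_water_flux(280.0, 285.0, 0.24) < 0  # out of cells

    def test_extracellular_osmole_step_shrinks_cells_monotonically(self, patient):
        params, state = patient
        # add solute-free osmoles to the extracellular pool
        params = replace(params, background_osmoles_ex=params.background_osmoles_ex + 100.0)
        traj = ds.integrate(state, params, [(60.0, PhaseContext())], dt=0.1)
        v_ic = traj.volumes[:, 0]
        assert np.all(np.diff(v_ic) < 1e-12)
        assert v_ic[-1] < v_ic[0]
        # equilibrium: osmolarities re-equalise while total osmoles conserved
        o_ic, o_is = osmolarities(traj.final_state(), params)
        assert o_ic == pytest.approx(o_is, rel=1e-4)


class TestCapillaryExchange:
    def test_baseline_is_balanced(self, patient):
        params, state = patient
        f_a, r_v = capillary_exchange(state, params)
        assert f_a == pytest.approx(r_v, rel=1e-12)
        assert f_a > 0

    def test_plasma_depletion_drives_net_refill(self, patient):
        params, state = patient
        depleted = replace(state, v_pl=state.v_pl - 0.4)
        f_a, r_v = capillary_exchange(depleted, params)
        assert r_v > f_a  # net flow interstitium -> plasma

    def test_zero_conductance_decouples(self, patient):
        params, state = patient
        params = replace(params, capillary=replace(params.capillary, conductance_a=0.0))
        assert capillary_exchange(state, params) == (0.0, 0.0)

    def test_refilling_buffers_plasma_volume_during_uf(self, patient):
        """4-h UF session: plasma volume falls by less than the fluid removed."""
        params, state = patient
        ctx = PhaseContext(fluid_removal=500.0 / 60.0)  # 0.5 L/h, no clearance
        traj = ds.integrate(state, params, [(240.0, ctx)], dt=0.2)
        removed_l = 2.0
        dv_pl = state.v_pl - traj.volumes[-1, 2]
        assert 0 < dv_pl < removed_l
        # the balance came out of the other compartments
        assert traj.v_total()[0] - traj.v_total()[-1] == pytest.approx(removed_l, rel=1e-6)


class TestCellularSoluteFlux:
    def test_equilibrium(self):
        assert ds.cellular_solute_flux(1.0, 1.0, 0.77, 1.0) == 0.0

    def test_urea_flux_is_10x_b2m_at_equal_gradient(self):
        f_urea = ds.cellular_solute_flux(2.0, 1.0, 0.77, 1.0)
        f_b2m = ds.cellular_solute_flux(2.0, 1.0, 0.077, 1.0)
        assert f_urea == pytest.approx(10 * f_b2m)

    def test_two_pool_exponential_relaxation(self, patient):
        """Closed system: the gradient decays at rate eta*(1/V_ic + beta/V_ex)."""
        params, state = patient
        params = closed_system_params(params)
        params = replace(
            params,
            solutes={
                "urea": replace(params.solutes["urea"], g=0.0),
                "b2m": replace(params.solutes["b2m"], g=0.0),
            },
        )
        # impose a step gradient in urea
        state = replace(
            state,
            m_ic={**state.m_ic, "urea": state.m_ic["urea"] * 1.5},
        )
        traj = ds.integrate(state, params, [(120.0, PhaseContext())], dt=0.1)
        eta = params.solutes["urea"].eta
        rate = eta * (1 / state.v_ic + 1 / state.v_ex)
        d0 = state.c_ic("urea") - state.c_ex("urea")
        d_end = traj.c_ic("urea")[-1] - traj.c_ex("urea")[-1]
        assert d_end == pytest.approx(d0 * math.exp(-rate * 120.0), rel=1e-3)


class TestDialyserRemovalRate:
    def test_zero_concentration(self):
        assert ds.dialyser_removal_rate(200.0, 1.0, 0.94, 0.0) == 0.0

    def test_product_form(self):
        # K = 200 mL/min, alpha = 1, r = 0.94, C = 1 mg/mL = 1000 mg/L
        assert ds.dialyser_removal_rate(200.0, 1.0, 0.94, 1000.0) == pytest.approx(188.0)

    def test_linearity_in_clearance(self):
        j1 = ds.dialyser_removal_rate(100.0, 1.0, 0.94, 800.0)
        j2 = ds.dialyser_removal_rate(200.0, 1.0, 0.94, 800.0)
        assert j2 == pytest.approx(2 * j1)


class TestStateDerivatives:
    def test_equilibrated_state_without_generation_is_fixed_point(self, patient):
        params, state = patient
        params = replace(
            params,
            solutes={s: replace(p, g=0.0) for s, p in params.solutes.items()},
        )
        d = ds.state_derivatives(state, params, PhaseContext())
        for key, val in d.items():
            assert val == pytest.approx(0.0, abs=1e-12), key

    def test_urea_mass_grows_at_generation_rate_without_dialysis(self, patient):
        params, state = patient
        d = ds.state_derivatives(state, params, PhaseContext())
        assert d["m_ic:urea"] + d["m_ex:urea"] == pytest.approx(6.24)

    def test_mass_rate_identity_along_a_session(self, patient, fixture_session_clearances):
        """d(M_ic + M_ex)/dt - G + J = 0 by construction of the assembly."""
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        d = ds.state_derivatives(state, params, ctx)
        for s in ("urea", "b2m"):
            g = params.solutes[s].g
            assert d[f"m_ic:{s}"] + d[f"m_ex:{s}"] - g + d[f"j:{s}"] == pytest.approx(
                0.0, abs=1e-12
            )


class TestIntegrate:
    def test_single_pool_limit(self):
        """eta -> large: C(240)/C(0) -> exp(-K t / V) for K = 200, V = 40 L."""
        params, state = ds.default_patient(weight_kg=40.0 / 0.58)
        params = replace(
            params,
            r=1.0,
            solutes={
                s: replace(p, eta=100.0, g=0.0) for s, p in params.solutes.items()
            },
        )
        ctx = PhaseContext(clearances={"urea": 200.0, "b2m": 0.0})
        traj = ds.integrate(state, params, [(240.0, ctx)], dt=0.1)
        ratio = traj.c_ex("urea")[-1] / traj.c_ex("urea")[0]
        assert ratio == pytest.approx(math.exp(-1.2), rel=0.01)

    def test_step_halving_convergence_contract(self, patient, fixture_session_clearances):
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        a = ds.integrate(state, params, [(240.0, ctx)], dt=0.2)
        b = ds.integrate(state, params, [(240.0, ctx)], dt=0.1)
        for s in ("urea", "b2m"):
            assert a.c_ex(s)[-1] == pytest.approx(b.c_ex(s)[-1], rel=1e-6)
        # the built-in check accepts this dt
        ds.integrate(state, params, [(240.0, ctx)], dt=0.2, check=True)

    def test_check_flags_too_coarse_dt(self, patient, fixture_session_clearances):
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        with pytest.raises(AccuracyError, match="smaller dt"):
            ds.integrate(state, params, [(240.0, ctx)], dt=0.25, check=True,
                         check_rtol=1e-12)

    def test_rebound_after_fixture_session(self, patient, fixture_session_clearances):
        """Plasma urea rises after the session while C_ic stays above C_ex.

        The rebound window is the ~30 min of two-pool re-equilibration after
        session end (the cell-to-plasma gradient decays with time constant
        1/(eta*(1/V_ic + 1/V_ex)) ~ 12 min); beyond it, urea generation into
        the extracellular pool restores the pre-dialysis gradient sign.
        """
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        traj = ds.integrate(
            state, params, [(240.0, ctx), (60.0, PhaseContext())], dt=0.2
        )
        i_end = int(np.searchsorted(traj.times, 240.0 - 1e-9))
        i_reb = int(np.searchsorted(traj.times, 270.0 - 1e-9))
        c_ex = traj.c_ex("urea")
        assert c_ex[-1] > c_ex[i_end]                         # rebound
        assert np.all(np.diff(c_ex[i_end:]) > -1e-12)         # non-decreasing
        assert np.all(traj.c_ic("urea")[i_end:i_reb] > c_ex[i_end:i_reb])

    def test_mass_conservation_over_fixture_session(
        self, patient, fixture_session_clearances
    ):
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        traj = ds.integrate(state, params, [(240.0, ctx)], dt=0.2)
        for s in ("urea", "b2m"):
            total0 = state.m_ic[s] + state.m_ex[s]
            total1 = traj.m_ic[s][-1] + traj.m_ex[s][-1]
            generated = params.solutes[s].g * 240.0
            removed = traj.removed[s][-1]
            assert total1 - total0 == pytest.approx(generated - removed, rel=1e-6)

    def test_volume_conservation_over_fixture_session(
        self, patient, fixture_session_clearances
    ):
        params, state = patient
        ctx = PhaseContext(
            clearances={s: fixture_session_clearances.k(s) for s in ("urea", "b2m")},
            fluid_removal=fixture_session_clearances.net_uf,
        )
        traj = ds.integrate(state, params, [(240.0, ctx)], dt=0.2)
        dv = traj.v_total()[-1] - traj.v_total()[0]
        assert dv == pytest.approx(-traj.fluid_loss[-1], rel=1e-9)

    def test_invalid_dt_and_stride_rejected(self, patient):
        params, state = patient
        with pytest.raises(DialsimUserError):
            ds.integrate(state, params, [(10.0, PhaseContext())], dt=-1.0)
        with pytest.raises(DialsimUserError):
            ds.integrate(state, params, [(10.0, PhaseContext())], dt=0.2, output_stride=0)

    def test_segment_not_multiple_of_dt_rejected(self, patient):
        params, state = patient
        with pytest.raises(DialsimUserError, match="multiple of dt"):
            ds.integrate(state, params, [(10.1, PhaseContext())], dt=0.2)


class TestParamValidation:
    def test_bad_solute_params(self):
        with pytest.raises(DialsimUserError):
            SolutePatientParams(eta=0.0)
        with pytest.raises(DialsimUserError):
            SolutePatientParams(eta=0.77, g=-1.0)

    def test_capillary_calibration_needs_positive_gradients(self):
        with pytest.raises(DialsimUserError):
            CapillaryParams(pi_pl0=60.0)  # oncotic dominates: no filtration

    def test_state_rejects_nonpositive_volumes(self):
        with pytest.raises(DialsimUserError):
            ds.PatientState(v_ic=0.0, v_is=12.0, v_pl=3.0, m_ic={}, m_ex={})
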