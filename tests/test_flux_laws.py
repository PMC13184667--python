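"""Membrane transport laws: closed forms, limits and chord identities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings
from hypothesis import strategies as st

from proxtubule.core_types import PhysicalConstants, Sglt1Parameters, CarrierParameters, PumpParameters
from proxtubule.flux_laws import (
    cell_membrane_water_flow,
    convective_neutral_flux,
    epump_from_dg,
    ghk_chord_conductance,
    ghk_flux,
    glut1_flux,
    junction_water_flow,
    lp_to_pf,
    pf_to_lp,
    nak2cl_flux,
    pump_current,
    pump_fluxes,
    sglt1_conductance,
    sglt1_fluxes,
    sglt1_reversal_potential,
    solvent_drag_ion_flux,
)

C = PhysicalConstants()
RT_F = C.RT / C.F
ATM1 = 101325.0


# ---------------------------------------------------------------------------
# GHK electrodiffusion


class TestGhkFlux:
    def test_fick_limit_at_zero_potential(self):
        assert ghk_flux(1.0, 1, 0.0, 2.0, 1.0, C) == pytest.approx(1.0)

    def test_symmetric_concentration_closed_form(self):
        # cI = cII = c gives J = P*u*c exactly
        v = RT_F
        assert ghk_flux(1.0, 1, v, 1.0, 1.0, C) == pytest.approx(1.0, rel=1e-12)

    def test_zero_flux_at_nernst_potential(self):
        v = RT_F * math.log(10.0)
        assert ghk_flux(1.0, 1, v, 1.0, 10.0, C) == pytest.approx(0.0, abs=1e-15)

    def test_continuity_across_the_taylor_switch(self):
        # both branches agree with the three-term series around |u| = 1e-6
        a, b = 2.0, 1.0
        for u in (0.8e-6, 0.999e-6, 1.001e-6, 1.2e-6, -0.999e-6, -1.001e-6):
            j = ghk_flux(1.0, 1, u * RT_F, a, b, C)
            series = (a - b) + 0.5 * u * (a + b) + u * u * (a - b) / 12.0
            # the exact branch carries ~1e-10 relative roundoff at |u|~1e-6
            # from the 1 - exp(-u) cancellation; the switch must be seamless
            # at that level
            assert j == pytest.approx(series, rel=5e-9)

    def test_monotone_in_potential_for_cation(self, rng):
        cI, cII = 10.0, 140.0
        vs = np.linspace(-0.15, 0.15, 31)
        js = [ghk_flux(1e-7, 1, v, cI, cII, C) for v in vs]
        assert np.all(np.diff(js) > 0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            ghk_flux(1.0, 1, math.nan, 1.0, 1.0, C)


class TestGhkChordConductance:
    def test_chord_identity_over_random_states(self, rng):
        for _ in range(1000):
            z = int(rng.choice([-1, 1]))
            cI, cII = rng.uniform(0.5, 200.0, 2)
            v = rng.uniform(-0.1, 0.1)
            ej = RT_F / z * math.log(cII / cI)
            if abs(v - ej) < 1e-4:
                continue
            P = 10.0 ** rng.uniform(-9, -6)
            g = ghk_chord_conductance(P, z, v, cI, cII, C)
            current = z * C.F * ghk_flux(P, z, v, cI, cII, C)
            assert current == pytest.approx(g * (v - ej), rel=1e-10)
            assert g >= 0

    def test_small_signal_limit(self):
        # cI = cII = c, V -> 0: G -> z^2 F^2 P c / RT
        c0 = 5.0
        g = ghk_chord_conductance(1e-7, -1, 1e-9, c0, c0, C)
        assert g == pytest.approx(C.F**2 * 1e-7 * c0 / C.RT, rel=1e-6)

    def test_zero_permeability(self):
        assert ghk_chord_conductance(0.0, 1, 0.05, 1.0, 2.0, C) == 0.0

    def test_rejects_vanishing_concentrations(self):
        with pytest.raises(ValueError):
            ghk_chord_conductance(1.0, 1, 0.0, 0.0, 0.0, C)


# ---------------------------------------------------------------------------
# cotransporters and GLUT1


class TestNaK2Cl:
    def test_equilibrium(self):
        j = nak2cl_flux(1e-12, 10.0, 10.0, 10.0, 100.0, 1.0, 10.0)
        assert j == pytest.approx((0.0, 0.0, 0.0))

    @given(
        st.tuples(*[st.floats(0.1, 200.0) for _ in range(6)]),
        st.floats(1e-14, 1e-11),
    )
    @hsettings(max_examples=50, derandomize=True, deadline=None)
    def test_stoichiometry_and_electroneutrality(self, concs, k):
        jna, jk, jcl = nak2cl_flux(k, *concs)
        assert jcl == pytest.approx(2.0 * jna, rel=1e-12)
        assert jna == pytest.approx(jk, rel=1e-12)
        # net charge flux +1 +1 -2 = 0
        assert jna + jk - jcl == pytest.approx(0.0, abs=1e-25)

    def test_direct_evaluation(self):
        jna, _, _ = nak2cl_flux(1e-12, 146.0, 4.0, 150.0, 10.0, 140.0, 16.0)
        assert jna == pytest.approx(1e-12 * 12_781_600, rel=1e-12)


class TestGlut1:
    PAR = CarrierParameters(glut1Jmax=2e-5, glut1K=5.0)

    def test_no_gradient_no_flux(self):
        assert glut1_flux(self.PAR, 3.0, 3.0) == 0.0

    def test_saturation_limit(self):
        assert glut1_flux(self.PAR, 1e9, 0.0) == pytest.approx(2e-5, rel=1e-6)
        assert abs(glut1_flux(self.PAR, 123.0, 4.0)) <= 2e-5

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0))
    @hsettings(max_examples=50, derandomize=True, deadline=None)
    def test_antisymmetry(self, a, b):
        assert glut1_flux(self.PAR, a, b) == pytest.approx(
            -glut1_flux(self.PAR, b, a), abs=1e-20
        )


# ---------------------------------------------------------------------------
# SGLT1


class TestSglt1:
    PAR = Sglt1Parameters(pmax=1e-10, km=1.0, nW=264.0)

    def test_reversal_potential_closed_form(self):
        v = sglt1_reversal_potential(6.0, 8.0, 146.0, 10.0, C)
        assert v * 1e3 == pytest.approx(67.78, abs=0.05)

    def test_reversal_symmetry_and_scale_invariance(self):
        assert sglt1_reversal_potential(5.0, 5.0, 30.0, 30.0, C) == 0.0
        a = sglt1_reversal_potential(6.0, 8.0, 146.0, 10.0, C)
        b = sglt1_reversal_potential(6.0, 8.0, 2 * 146.0, 2 * 10.0, C)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_flux_at_reversal(self):
        vrev = sglt1_reversal_potential(6.0, 8.0, 146.0, 10.0, C)
        jna, jg, jw = sglt1_fluxes(self.PAR, 6.0, 8.0, 146.0, 10.0, vrev, C)
        assert jna == pytest.approx(0.0, abs=1e-18)
        assert (jg, jw) == (pytest.approx(0.0, abs=1e-18),) * 2

    def test_stoichiometry(self, rng):
        for _ in range(100):
            cgo, cgc = rng.uniform(0.2, 10.0, 2)
            cno, cnc = rng.uniform(2.0, 150.0, 2)
            v = rng.uniform(-0.12, 0.02)
            jna, jg, jw = sglt1_fluxes(self.PAR, cgo, cgc, cno, cnc, v, C)
            assert jna == pytest.approx(2.0 * jg, rel=1e-12)
            assert jw == pytest.approx(264.0 * jg * C.Vw, rel=1e-12)

    def test_hyperpolarization_drives_influx(self):
        jna, _, _ = sglt1_fluxes(self.PAR, 6.0, 8.0, 146.0, 10.0, -0.060, C)
        assert jna > 0

    def test_conductance_chord_identity(self, rng):
        for _ in range(200):
            cgo, cgc = rng.uniform(0.2, 10.0, 2)
            cno, cnc = rng.uniform(2.0, 150.0, 2)
            v = rng.uniform(-0.12, 0.02)
            vrev = sglt1_reversal_potential(cgo, cgc, cno, cnc, C)
            if abs(v - vrev) < 1e-4:
                continue
            jna, _, _ = sglt1_fluxes(self.PAR, cgo, cgc, cno, cnc, v, C)
            g = sglt1_conductance(self.PAR, cgo, cgc, cno, cnc, v, C)
            assert g >= 0
            # carrier current on the apical (cell-minus-lumen) convention
            assert -2.0 * C.F * jna == pytest.approx(g * (v - vrev), rel=1e-10)

    def test_zero_pmax_gives_zero_conductance(self):
        par = Sglt1Parameters(pmax=0.0, km=1.0)
        assert sglt1_conductance(par, 6.0, 8.0, 146.0, 10.0, -0.06, C) == 0.0

    @staticmethod
    def _fig2_carrier():
        # saturating glucose flux of 530 pmol/cm^2/s at Vam = -60 mV,
        # cNaO = 146 mM (luminal-glucose saturation limit)
        w = -2 * C.F * (-0.060) / C.RT
        lim = w * (146.0**2 * math.exp(w)) / (math.exp(w) - 1.0)
        return Sglt1Parameters(pmax=2 * 5.3e-6 / lim, km=1.0, nW=0.0)

    def test_saturation_curve_tracks_michaelis_menten(self):
        """Self-inhibition via the glucose-dependent permeability reproduces
        saturating uptake kinetics close to the hyperbolic fit
        530·c/(0.6 + c) pmol·cm⁻²·s⁻¹ over the physiological 0-6 mM range."""
        par = self._fig2_carrier()
        cs = np.linspace(0.05, 6.0, 60)
        jg = np.array([
            sglt1_fluxes(par, c0, 8.0, 146.0, 10.0, -0.060, C)[1] for c0 in cs
        ])
        mm = 5.3e-6 * cs / (0.6 + cs)
        # saturating, monotone, and graphically close to the hyperbola
        assert np.all(np.diff(jg) > 0)
        assert jg[-1] < 5.3e-6
        assert np.max(np.abs(jg - mm)) / 5.3e-6 < 0.14

    def test_near_linear_current_voltage_relation(self):
        """The carrier current is near-linear between -100 and -40 mV: the
        midpoint deviates from the secant by a small fraction."""
        par = self._fig2_carrier()

        def current(v):
            jna, _, _ = sglt1_fluxes(par, 6.0, 8.0, 146.0, 10.0, v, C)
            return 2 * C.F * jna

        i100, i70, i40 = current(-0.100), current(-0.070), current(-0.040)
        secant_mid = 0.5 * (i100 + i40)
        assert abs(i70 - secant_mid) / abs(i70) < 0.03


# ---------------------------------------------------------------------------
# Na/K pump


class TestPump:
    PAR = PumpParameters(ppump=1.5e-4, kNa=3.4, kK=0.75, epump=0.2)

    def test_reversal_at_minus_epump(self):
        assert pump_fluxes(self.PAR, 10.0, 4.0, -0.2) == pytest.approx((0.0, 0.0))
        i, _ = pump_current(self.PAR, 10.0, 4.0, -0.2, C)
        assert i == pytest.approx(0.0, abs=1e-18)

    def test_half_saturation_algebra(self):
        # cNa = K_Na and cK = K_K: each saturation term is 1/2, so
        # J = ppump (V+E) / 32
        vlm = -0.07
        jna, _ = pump_fluxes(self.PAR, 3.4, 0.75, vlm)
        assert jna == pytest.approx(1.5e-4 * (vlm + 0.2) / 32.0, rel=1e-12)

    def test_stoichiometry(self, rng):
        for _ in range(100):
            jna, jk = pump_fluxes(
                self.PAR, rng.uniform(0.5, 50), rng.uniform(0.2, 10),
                rng.uniform(-0.12, 0.0),
            )
            assert jk == pytest.approx(-2.0 / 3.0 * jna, rel=1e-14)

    def test_forward_above_reversal(self):
        jna, _ = pump_fluxes(self.PAR, 10.0, 4.0, -0.07)
        assert jna > 0

    def test_current_chord_identity(self, rng):
        for _ in range(100):
            cna, ck = rng.uniform(0.5, 50), rng.uniform(0.2, 10)
            v = rng.uniform(-0.12, 0.0)
            i, g = pump_current(self.PAR, cna, ck, v, C)
            assert i == pytest.approx(g * (v + 0.2), rel=1e-10)
            jna, _ = pump_fluxes(self.PAR, cna, ck, v)
            assert i == pytest.approx(C.F * jna / 3.0, rel=1e-12)

    def test_flux_step_current_conversion(self):
        """A 541 -> 726 pmol·cm⁻²·s⁻¹ jump of the active Na⁺ flux carries
        F·ΔJ/3 = 5.95 µA·cm⁻² of inward pump current."""
        dj = (726.0 - 541.0) * 1e-12  # mol per cm^2 per s
        di = C.F * dj / 3.0 * 1e6  # µA/cm^2
        assert di == pytest.approx(5.95, abs=0.01)


class TestEpumpFromDg:
    @pytest.mark.parametrize(
        "dg_kj, vrev_mv", [(-58.0, -200.0), (-29.0, -100.0), (-40.6, -140.0)]
    )
    def test_printed_mapping_to_nearest_10mv(self, dg_kj, vrev_mv):
        epump, vrev = epump_from_dg(dg_kj * 1e3, C)
        assert round(vrev * 1e3 / 10.0) * 10.0 == vrev_mv
        assert epump == -vrev

    def test_zero_and_linearity(self):
        assert epump_from_dg(0.0, C) == (0.0, 0.0)
        _, v1 = epump_from_dg(-1e4, C)
        _, v2 = epump_from_dg(-2e4, C)
        assert v2 == pytest.approx(2 * v1, rel=1e-14)

    def test_rejects_positive_free_energy(self):
        with pytest.raises(ValueError):
            epump_from_dg(+100.0, C)


# ---------------------------------------------------------------------------
# paracellular drag


class TestSolventDrag:
    def test_reduces_to_ghk_without_water_flow(self, rng):
        for _ in range(300):
            z = int(rng.choice([-1, 1]))
            cI, cII = rng.uniform(0.5, 200.0, 2)
            v = rng.uniform(-0.1, 0.1)
            P = 10.0 ** rng.uniform(-8, -5)
            sigma = rng.uniform(0.0, 1.0)
            j = solvent_drag_ion_flux(P, z, sigma, v, 0.0, cI, cII, C)
            assert j == pytest.approx(ghk_flux(P, z, v, cI, cII, C), rel=1e-12)

    def test_reduces_to_convection_without_field(self, rng):
        for _ in range(300):
            cI, cII = rng.uniform(0.5, 200.0, 2)
            P = 10.0 ** rng.uniform(-8, -5)
            sigma = rng.uniform(0.0, 0.99)
            jv = rng.uniform(-1e-7, 1e-7)
            j = solvent_drag_ion_flux(P, 1, sigma, 0.0, jv, cI, cII, C)
            assert j == pytest.approx(
                convective_neutral_flux(P, sigma, jv, cI, cII), rel=1e-9
            )

    def test_full_reflection_recovers_ghk(self):
        j = solvent_drag_ion_flux(1e-6, 1, 1.0, 0.02, 5e-8, 146.0, 140.0, C)
        assert j == pytest.approx(ghk_flux(1e-6, 1, 0.02, 146.0, 140.0, C),
                                  rel=1e-12)

    def test_rejects_drag_through_impermeable_barrier(self):
        with pytest.raises(ValueError):
            solvent_drag_ion_flux(0.0, 1, 0.5, 0.0, 1e-8, 1.0, 1.0, C)


class TestConvectiveNeutralFlux:
    def test_uniform_solution_is_pure_drag(self):
        c0, jv, sigma = 5.0, 3e-8, 0.8
        j = convective_neutral_flux(1e-7, sigma, jv, c0, c0)
        assert j == pytest.approx(jv * (1 - sigma) * c0, rel=1e-12)

    def test_diffusive_limit(self):
        assert convective_neutral_flux(1.0, 0.5, 0.0, 2.0, 1.0) == pytest.approx(1.0)

    def test_full_reflection_blocks_convection(self):
        assert convective_neutral_flux(1e-7, 1.0, 5e-8, 2.0, 1.0) == pytest.approx(
            1e-7, rel=1e-12
        )


# ---------------------------------------------------------------------------
# water


class TestWaterFlows:
    def test_equilibrium(self):
        assert cell_membrane_water_flow(1e-10, 300.0, 300.0, ATM1, ATM1, C) == 0.0

    def test_unit_osmotic_response(self):
        # 1 mosM excess on side II at equal pressure drives Lp*RT toward II
        j = cell_membrane_water_flow(1e-10, 300.0, 301.0, ATM1, ATM1, C)
        assert j == pytest.approx(1e-10 * C.RT, rel=1e-12)
        assert j > 0

    def test_linearity_in_lp(self):
        a = cell_membrane_water_flow(1e-10, 300.0, 305.0, ATM1, ATM1 + 40, C)
        b = cell_membrane_water_flow(2e-10, 300.0, 305.0, ATM1, ATM1 + 40, C)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_junction_flow_zero_sigma_is_pressure_driven(self):
        sig = dict(na=0.0, k=0.0, cl=0.0, gluc=0.0)
        cI = dict(na=10.0, k=1.0, cl=11.0, gluc=0.0)
        cII = dict(na=200.0, k=5.0, cl=205.0, gluc=10.0)
        j = junction_water_flow(1e-10, sig, cI, cII, ATM1 + 100.0, ATM1, C)
        assert j == pytest.approx(1e-10 * 100.0, rel=1e-12)

    def test_junction_flow_equilibrium(self):
        sig = dict(na=0.7, k=0.7, cl=0.45, gluc=0.8)
        c0 = dict(na=146.0, k=4.0, cl=150.0, gluc=6.0)
        assert junction_water_flow(1e-10, sig, c0, dict(c0), ATM1, ATM1, C) == 0.0

    def test_junction_species_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match"):
            junction_water_flow(
                1e-10, dict(na=0.5), dict(na=1.0, k=1.0), dict(na=1.0), ATM1,
                ATM1, C,
            )

    def test_hyperosmotic_hyperbaric_lis_drives_ibm_efflux(self):
        # +0.9 mosM and +0.001 atm in the lis vs serosa, sigma = 0.03: the
        # pressure term beats the small reflected osmotic back-pull
        sig = dict(na=0.03, k=0.03, cl=0.03, gluc=0.03)
        lis = dict(na=146.3, k=4.1, cl=150.4, gluc=6.1)
        ser = dict(na=146.0, k=4.0, cl=150.0, gluc=6.0)
        j = junction_water_flow(1e-9, sig, lis, ser, ATM1 + 101.325, ATM1, C)
        assert j > 0


class TestLpPfConversion:
    def test_zero_and_round_trip(self):
        assert lp_to_pf(0.0, C) == 0.0
        assert pf_to_lp(lp_to_pf(3.7e-10, C), C) == pytest.approx(3.7e-10,
                                                                  rel=1e-12)

    def test_linear_in_temperature(self):
        hot = PhysicalConstants(T=620.0)
        assert lp_to_pf(1e-10, hot) == pytest.approx(2 * lp_to_pf(1e-10, C),
                                                     rel=1e-12)

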