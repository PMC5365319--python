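"""Solute/water budget: flows, diffusion, Patlak coupling, osmotic relations."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phloemflow import (
    PDGeometry,
    SapProperties,
    TubeGeometry,
    convective_flux,
    membrane_water_pressure,
    pd_diffusive_permeability,
    peclet,
    required_concentration_difference,
    scenario_report,
    solute_flux,
    vant_hoff_concentration,
    vant_hoff_pressure,
    volumetric_flow,
)

FL = 1e-18
UM3 = 1e-18


class TestVolumetricFlow:
    def test_base_tube_gives_230_fl_s(self, tube):
        q = volumetric_flow(tube)
        assert q / UM3 == pytest.approx(230.0, abs=0.5)
        assert q == pytest.approx(math.pi / 4 * (3.6e-6) ** 2 * 22.6e-6)

    def test_zero_velocity(self):
        tube = TubeGeometry(flow_velocity_um_s=0.0)
        assert volumetric_flow(tube) == 0.0

    def test_quadratic_in_diameter(self, tube):
        doubled = replace(tube, diameter_um=7.2)
        assert volumetric_flow(doubled) == pytest.approx(4.0 * volumetric_flow(tube))

    def test_nonpositive_diameter_rejected(self):
        with pytest.raises(ValueError, match="diameter_um"):
            TubeGeometry(diameter_um=-3.6)


class TestSoluteFlux:
    def test_base_flux(self, tube, sap):
        i = solute_flux(volumetric_flow(tube), sap.concentration_mol_m3)
        assert i == pytest.approx(1.15e-13, rel=0.01)

    def test_zero_concentration(self):
        assert solute_flux(230 * FL, 0.0) == 0.0

    def test_unit_arithmetic(self):
        # 100 fl/s x 100 mM = 1e-13 L/s x 0.1 mol/L
        assert solute_flux(100 * FL, 100.0) == pytest.approx(1.0e-14)


class TestDiffusivePermeability:
    def test_zero_diffusivity_gives_zero(self, simple_pd):
        sap = SapProperties(diffusivity_m2_s=0.0)
        assert pd_diffusive_permeability(simple_pd, sap) == 0.0

    def test_simple_pd_reduces_to_DA_over_L(self, simple_pd, sap):
        area = math.pi * ((10.3e-9) ** 2 - (7.5e-9) ** 2)
        expected = sap.diffusivity_m2_s * area / 500e-9
        assert pd_diffusive_permeability(simple_pd, sap) == pytest.approx(expected)

    def test_funnel_exceeds_simple(self, simple_pd, funnel_pd, sap):
        assert pd_diffusive_permeability(funnel_pd, sap) > pd_diffusive_permeability(
            simple_pd, sap
        )

    def test_hindrance_scales_linearly(self, funnel_pd, sap):
        hindered = replace(sap, hindrance=0.5)
        assert pd_diffusive_permeability(funnel_pd, hindered) == pytest.approx(
            0.5 * pd_diffusive_permeability(funnel_pd, sap), rel=1e-9
        )

    def test_open_cone_mode_exceeds_full_span(self, sap):
        full = PDGeometry.funnel(desmotubule_mode="full_span")
        neck = PDGeometry.funnel(desmotubule_mode="neck_only")
        assert pd_diffusive_permeability(neck, sap) > pd_diffusive_permeability(
            full, sap
        )


class TestRequiredConcentrationDifference:
    def test_division(self):
        assert required_concentration_difference(1e-15, 1e-18) == pytest.approx(1000.0)

    def test_zero_flux(self):
        assert required_concentration_difference(0.0, 1e-18) == 0.0

    def test_zero_permeability_rejected(self):
        with pytest.raises(ValueError, match="permeability"):
            required_concentration_difference(1e-15, 0.0)


class TestConvectiveFlux:
    def test_pure_diffusion_limit(self):
        p = 1e-18
        i = convective_flux(1e-30, p, 500.0, 100.0)
        assert i == pytest.approx(p * 400.0, rel=1e-9)

    def test_pure_advection_limit(self):
        q = 1e-12  # Pe = 1e6
        assert convective_flux(q, 1e-18, 500.0, 100.0) == pytest.approx(q * 500.0)

    def test_peclet_one(self):
        q = 2e-18
        i = convective_flux(q, q, 1.0, 0.0)
        assert i == pytest.approx(q / (1.0 - math.exp(-1.0)), rel=1e-12)

    def test_uniform_solution_advects_exactly(self):
        for pe in (1e-12, 1e-6, 0.1, 5.0):
            q, p = pe * 1e-18, 1e-18
            assert convective_flux(q, p, 500.0, 500.0) == pytest.approx(q * 500.0,
                                                                        rel=1e-9)

    def test_continuous_across_series_branch(self):
        p = 1e-18
        below = convective_flux(0.99e-8 * p, p, 300.0, 100.0)
        above = convective_flux(1.01e-8 * p, p, 300.0, 100.0)
        assert below == pytest.approx(above, rel=1e-7)

    @given(
        c_up=st.floats(min_value=0.0, max_value=1000.0),
        c_dn=st.floats(min_value=0.0, max_value=1000.0),
        pe=st.floats(min_value=1e-6, max_value=50.0),
    )
    def test_monotone_in_concentrations(self, c_up, c_dn, pe):
        p = 1e-18
        q = pe * p
        base = convective_flux(q, p, c_up, c_dn)
        assert convective_flux(q, p, c_up + 10.0, c_dn) >= base
        assert convective_flux(q, p, c_up, c_dn + 10.0) <= base

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            peclet(-1.0, 1.0)


class TestMembraneWaterPressure:
    def test_reported_bounds(self, tube):
        q = volumetric_flow(tube)
        high_lp = membrane_water_pressure(q, tube, 1e-12)
        low_lp = membrane_water_pressure(q, tube, 1e-14)
        assert high_lp / 1e6 == pytest.approx(0.059, rel=0.02)
        assert low_lp / 1e6 == pytest.approx(5.9, rel=0.02)

    def test_zero_flow(self, tube):
        assert membrane_water_pressure(0.0, tube, 1e-12) == 0.0

    @given(scale=st.floats(min_value=0.1, max_value=10.0))
    def test_inverse_in_lp_and_zone_length(self, scale):
        tube = TubeGeometry()
        q = volumetric_flow(tube)
        base = membrane_water_pressure(q, tube, 1e-13)
        assert membrane_water_pressure(q, tube, scale * 1e-13) == pytest.approx(
            base / scale, rel=1e-12
        )
        longer = replace(tube, unloading_zone_length_um=scale * 350.0)
        assert membrane_water_pressure(q, longer, 1e-13) == pytest.approx(
            base / scale, rel=1e-12
        )


class TestVantHoff:
    def test_pressure_to_concentration(self):
        assert vant_hoff_concentration(0.2e6, 298.0) == pytest.approx(80.7, rel=1e-3)
        assert vant_hoff_concentration(1e6, 298.0) == pytest.approx(403.5, rel=1e-3)
        assert vant_hoff_concentration(0.0) == 0.0

    @given(dp=st.floats(min_value=0.0, max_value=1e7))
    def test_round_trip_exact(self, dp):
        back = vant_hoff_pressure(vant_hoff_concentration(dp, 298.0), 298.0)
        assert back == pytest.approx(dp, rel=1e-12, abs=1e-12)


class TestScenarioReport:
    def test_internal_consistency(self, tube, sap, census):
        result = scenario_report(tube, sap, census)
        assert result.i_mol_s == solute_flux(volumetric_flow(tube),
                                             sap.concentration_mol_m3)
        assert result.osmotic_equivalent_mol_m3[0] == pytest.approx(
            vant_hoff_concentration(result.dp_funnel_pa[0], sap.temperature_k)
        )

    def test_all_zero_flow(self, sap, census):
        still = TubeGeometry(flow_velocity_um_s=0.0)
        result = scenario_report(still, sap, census)
        assert result.q_m3_s == 0.0
        assert result.dp_simple_pa == 0.0
        assert result.dp_funnel_pa == (0.0, 0.0)
        assert result.dc_diffusive_mol_m3 == 0.0
        assert result.dp_membrane_pa == (0.0, 0.0)

    def test_placement_extremes_ordered(self, tube, sap, census):
        result = scenario_report(tube, sap, census)
        full_span, neck_only = result.dp_funnel_pa
        assert neck_only < full_span < result.dp_simple_pa

    def test_unit_system_invariance(self, census, sap):
        # the same physical tube stated in different native units
        tube_um = TubeGeometry(diameter_um=3.6, flow_velocity_um_s=22.6)
        tube_scaled = TubeGeometry(diameter_um=3600e-3, flow_velocity_um_s=22600e-3)
        a = scenario_report(tube_um, sap, census)
        b = scenario_report(tube_scaled, sap, census)
        assert a.q_m3_s == pytest.approx(b.q_m3_s, rel=1e-12)
        assert a.dp_simple_pa == pytest.approx(b.dp_simple_pa, rel=1e-12)
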