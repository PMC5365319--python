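"""Solute and water budget of the phloem unloading zone.

The measured quantities — sieve-tube diameter, flow velocity, unloading-zone
length and the PD census — fix the volumetric flow ``Q = (pi/4) d^2 u`` that
a single protophloem sieve-element (PSE) file must unload, and with the sap
concentration the solute flux ``I = Q c``.  Each candidate unloading
mechanism then implies a driving requirement:

* bulk flow through the PD population -> pressure differential ``Q / G``;
* pure diffusion through the PDs -> concentration difference ``I / P``;
* membrane water removal -> membrane pressure ``Q / (Lp A)``;

with ``G`` the population hydraulic conductance, ``P`` the population
diffusive permeability and ``A`` the lateral membrane area of the unloading
zone.  The Patlak convection-diffusion expression couples the first two
routes through the pore Peclet number ``Pe = Q_pd / P_pd``, and the van 't
Hoff relation ``dPi = R T dc`` converts pressure requirements into osmotic
equivalents.  Everything is steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.constants import R as GAS_CONSTANT
from scipy.integrate import quad

from .geometry import PDCensus, PDGeometry, interface_counts
from .hydraulics import (
    NM,
    SapProperties,
    pd_resistance,
    population_pressure,
)

__all__ = [
    "TubeGeometry",
    "ScenarioResult",
    "volumetric_flow",
    "solute_flux",
    "pd_diffusive_permeability",
    "population_permeability",
    "required_concentration_difference",
    "peclet",
    "convective_flux",
    "membrane_water_pressure",
    "vant_hoff_concentration",
    "vant_hoff_pressure",
    "default_populations",
    "scenario_report",
]

UM = 1e-6  # metres per micrometre

#: Reported range of plant plasma-membrane hydraulic permeability (m/s/Pa).
DEFAULT_LP_BOUNDS = (1e-14, 1e-12)


@dataclass(frozen=True)
class TubeGeometry:
    """Protophloem sieve tube and unloading-zone dimensions.

    Defaults are the FRAP-derived means: diameter 3.6 um, plateau flow
    velocity 22.6 um/s, unloading-zone length 350 um.
    ``membrane_permeability_m_s_pa`` is the (low, high) range of plasma
    membrane hydraulic permeability Lp considered for water removal.
    """

    diameter_um: float = 3.6
    flow_velocity_um_s: float = 22.6
    unloading_zone_length_um: float = 350.0
    membrane_permeability_m_s_pa: tuple[float, float] = DEFAULT_LP_BOUNDS

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be strictly positive")
        if self.flow_velocity_um_s < 0:
            raise ValueError("flow_velocity_um_s must be non-negative")
        if not self.unloading_zone_length_um > 0:
            raise ValueError("unloading_zone_length_um must be strictly positive")
        lp = self.membrane_permeability_m_s_pa
        if len(lp) != 2 or not 0 < lp[0] <= lp[1]:
            raise ValueError(
                "membrane_permeability_m_s_pa must be an increasing positive pair"
            )

    @property
    def cross_section_m2(self) -> float:
        return math.pi / 4.0 * (self.diameter_um * UM) ** 2

    @property
    def lateral_membrane_area_m2(self) -> float:
        """Lateral area of the unloading-zone cylinder, ``pi d L``."""
        return math.pi * self.diameter_um * UM * self.unloading_zone_length_um * UM


def volumetric_flow(tube: TubeGeometry) -> float:
    """Volumetric flow ``Q = (pi/4) d^2 u`` of one PSE file (m^3/s)."""
    return tube.cross_section_m2 * tube.flow_velocity_um_s * UM


def solute_flux(q_m3_s: float, concentration_mol_m3: float) -> float:
    """Solute flux ``I = Q c`` (mol/s) carried by the unloading flow."""
    if q_m3_s < 0 or concentration_mol_m3 < 0:
        raise ValueError("flow and concentration must be non-negative")
    return q_m3_s * concentration_mol_m3


# ---------------------------------------------------------------------------
# Diffusion through PDs
# ---------------------------------------------------------------------------


def _open_area_m2(geom: PDGeometry, x_m: float, length_m: float) -> float:
    """Open (lumen minus desmotubule) cross-sectional area at axial x."""
    r_mouth = geom.mouth_radius_nm * NM
    r_neck = geom.neck_outer_radius_nm * NM
    ro = r_mouth + (r_neck - r_mouth) * x_m / length_m
    ri = geom.desmotubule_radius_nm * NM
    if geom.kind == "funnel" and geom.desmotubule_mode == "neck_only":
        if x_m < (1.0 - geom.neck_fraction) * length_m:
            ri = 0.0
    area = math.pi * (ro**2 - ri**2)
    if area <= 0:
        raise ValueError("PD has zero open area along its profile")
    return area


def pd_diffusive_permeability(geom: PDGeometry, sap: SapProperties) -> float:
    """Diffusive permeability of one PD (m^3/s per unit mol/m^3 difference).

    For a uniform channel this is ``D_eff A / L``; for a tapered channel the
    series form ``[integral dx / (D_eff A(x))]^-1``.  Zero when the
    effective diffusivity is zero.
    """
    d_eff = sap.effective_diffusivity_m2_s
    if d_eff == 0:
        return 0.0
    length = geom.wall_length_nm * NM
    if geom.kind == "simple":
        return d_eff * _open_area_m2(geom, 0.0, length) / length
    x_neck = (1.0 - geom.neck_fraction) * length
    pts = [x_neck] if geom.desmotubule_mode == "neck_only" and 0 < x_neck < length else None
    integral, _ = quad(
        lambda x: 1.0 / _open_area_m2(geom, x, length),
        0.0,
        length,
        points=pts,
        epsrel=1e-10,
        limit=400,
    )
    return d_eff / integral


def population_permeability(
    population: Sequence[tuple[PDGeometry, int]], sap: SapProperties
) -> float:
    """Summed diffusive permeability (m^3/s) of a parallel PD population."""
    if not population:
        raise ValueError("population must contain at least one PD")
    return sum(count * pd_diffusive_permeability(geom, sap) for geom, count in population)


def required_concentration_difference(
    i_mol_s: float, population_permeability_m3_s: float
) -> float:
    """Concentration difference ``dc = I / P`` (mol/m^3) for pure diffusion."""
    if i_mol_s < 0:
        raise ValueError("solute flux must be non-negative")
    if not population_permeability_m3_s > 0:
        raise ValueError("population permeability must be strictly positive")
    return i_mol_s / population_permeability_m3_s


# ---------------------------------------------------------------------------
# Convection-diffusion coupling
# ---------------------------------------------------------------------------


def peclet(q_pd_m3_s: float, p_pd_m3_s: float) -> float:
    """Pore Peclet number ``Pe = Q_pd / P_pd`` (advection vs diffusion)."""
    if q_pd_m3_s < 0 or not p_pd_m3_s > 0:
        raise ValueError("require Q_pd >= 0 and P_pd > 0")
    return q_pd_m3_s / p_pd_m3_s


def convective_flux(
    q_pd_m3_s: float, p_pd_m3_s: float, c_up_mol_m3: float, c_down_mol_m3: float
) -> float:
    """Steady solute flux through one pore with both bulk flow and diffusion.

    Patlak expression: ``I = Q (c_up - c_down e^-Pe) / (1 - e^-Pe)`` with
    ``Pe = Q/P``.  Reduces to ``P (c_up - c_down)`` as Pe -> 0 and to
    ``Q c_up`` as Pe -> inf; for a uniform solution it is exactly ``Q c``.
    """
    pe = peclet(q_pd_m3_s, p_pd_m3_s)
    if pe < 1e-8:
        # second-order small-Pe expansion: diffusion plus advection of the mean
        return (
            p_pd_m3_s * (c_up_mol_m3 - c_down_mol_m3)
            + q_pd_m3_s * (c_up_mol_m3 + c_down_mol_m3) / 2.0
        )
    emp = math.exp(-pe)
    return q_pd_m3_s * (c_up_mol_m3 - c_down_mol_m3 * emp) / (-math.expm1(-pe))


# ---------------------------------------------------------------------------
# Membrane water removal and osmotic equivalence
# ---------------------------------------------------------------------------


def membrane_water_pressure(
    q_m3_s: float, tube: TubeGeometry, lp_m_s_pa: float
) -> float:
    """Pressure (Pa) to drive ``Q`` across the unloading-zone membrane.

    ``dp = Q / (Lp A)`` with ``A`` the lateral area of a cylinder of the
    tube diameter over the unloading-zone length.
    """
    if q_m3_s < 0:
        raise ValueError("q_m3_s must be non-negative")
    if not lp_m_s_pa > 0:
        raise ValueError("membrane permeability must be strictly positive")
    area = tube.lateral_membrane_area_m2
    if not area > 0:
        raise ValueError("membrane area must be strictly positive")
    return q_m3_s / (lp_m_s_pa * area)


def vant_hoff_concentration(dp_pa: float, temperature_k: float = 298.0) -> float:
    """Osmotic concentration difference (mol/m^3) equivalent to ``dp`` (Pa)."""
    if not temperature_k > 0:
        raise ValueError("temperature must be strictly positive")
    return dp_pa / (GAS_CONSTANT * temperature_k)


def vant_hoff_pressure(dc_mol_m3: float, temperature_k: float = 298.0) -> float:
    """Osmotic pressure difference (Pa) of a concentration difference."""
    if not temperature_k > 0:
        raise ValueError("temperature must be strictly positive")
    return dc_mol_m3 * GAS_CONSTANT * temperature_k


# ---------------------------------------------------------------------------
# Scenario report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioResult:
    """All derived quantities of one unloading scenario (SI units).

    ``dp_funnel_pa`` holds the mixed-population pressures under the
    (full_span, neck_only) desmotubule placements; ``dp_membrane_pa`` the
    membrane pressures at the (high, low) Lp bound — i.e. (best, worst)
    case; ``osmotic_equivalent_mol_m3`` the van 't Hoff equivalents of
    ``dp_funnel_pa``.  ``peclet_funnel`` is the per-funnel-PD Peclet number
    when the mixed population carries the full flow (full_span placement).
    """

    q_m3_s: float
    i_mol_s: float
    dp_simple_pa: float
    dp_funnel_pa: tuple[float, float]
    dc_diffusive_mol_m3: float
    dp_membrane_pa: tuple[float, float]
    peclet_funnel: float
    osmotic_equivalent_mol_m3: tuple[float, float]


def default_populations(
    census: PDCensus,
    simple_geom: PDGeometry,
    funnel_geom_full: PDGeometry,
    funnel_geom_neck: PDGeometry,
    simple_fraction: float = 0.10,
) -> dict[str, list[tuple[PDGeometry, int]]]:
    """Base PD populations at the PSE-PPP interface.

    Only the PSE-PPP PDs are assigned unloading flux.  The interface count
    is the census PPP count rounded to the nearest ten (the resolution the
    census is quoted at); ``simple_fraction`` of them (10% observed) are
    simple, the rest funnels.
    """
    n_ppp = interface_counts(census).ppp_nearest_ten
    n_simple = int(round(simple_fraction * n_ppp))
    n_funnel = n_ppp - n_simple
    return {
        "simple_only": [(simple_geom, n_ppp)],
        "mixed_full_span": [(simple_geom, n_simple), (funnel_geom_full, n_funnel)],
        "mixed_neck_only": [(simple_geom, n_simple), (funnel_geom_neck, n_funnel)],
    }


def scenario_report(
    tube: TubeGeometry,
    sap: SapProperties,
    census: PDCensus,
    simple_geom: PDGeometry | None = None,
    funnel_geom: PDGeometry | None = None,
    annulus_model: Literal["annulus", "slit"] = "annulus",
) -> ScenarioResult:
    """Evaluate every unloading mechanism for one parameter set.

    ``funnel_geom`` may be in either desmotubule mode; both placement
    extremes are always evaluated.  The diffusive requirement uses the
    full_span (conservative) placement.
    """
    from dataclasses import replace

    if simple_geom is None:
        simple_geom = PDGeometry.simple()
    if funnel_geom is None:
        funnel_geom = PDGeometry.funnel()
    funnel_full = replace(funnel_geom, desmotubule_mode="full_span")
    funnel_neck = replace(funnel_geom, desmotubule_mode="neck_only")

    q = volumetric_flow(tube)
    i = solute_flux(q, sap.concentration_mol_m3)
    pops = default_populations(census, simple_geom, funnel_full, funnel_neck)

    if q == 0.0:
        dp_simple = 0.0
        dp_funnel = (0.0, 0.0)
        dp_membrane = (0.0, 0.0)
        dc = 0.0
        pe = 0.0
    else:
        dp_simple = population_pressure(q, pops["simple_only"], sap, annulus_model)
        dp_full = population_pressure(q, pops["mixed_full_span"], sap, annulus_model)
        dp_neck = population_pressure(q, pops["mixed_neck_only"], sap, annulus_model)
        dp_funnel = (dp_full, dp_neck)
        lp_low, lp_high = tube.membrane_permeability_m_s_pa
        dp_membrane = (
            membrane_water_pressure(q, tube, lp_high),
            membrane_water_pressure(q, tube, lp_low),
        )
        dc = required_concentration_difference(
            i, population_permeability(pops["mixed_full_span"], sap)
        )
        # per-funnel flow under the common full_span differential
        q_funnel = dp_full / pd_resistance(funnel_full, sap).value
        pe = peclet(q_funnel, pd_diffusive_permeability(funnel_full, sap))

    osm = (
        vant_hoff_concentration(dp_funnel[0], sap.temperature_k),
        vant_hoff_concentration(dp_funnel[1], sap.temperature_k),
    )
    return ScenarioResult(
        q_m3_s=q,
        i_mol_s=i,
        dp_simple_pa=dp_simple,
        dp_funnel_pa=dp_funnel,
        dc_diffusive_mol_m3=dc,
        dp_membrane_pa=dp_membrane,
        peclet_funnel=pe,
        osmotic_equivalent_mol_m3=osm,
    )
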