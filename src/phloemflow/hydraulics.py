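"""Low-Reynolds-number hydraulics of plasmodesmal pores.

Flow through a plasmodesma is creeping (Re ~ 1e-6), so each channel is a
linear hydraulic resistor: ``dP = Q * R``.  Simple PDs are concentric
annuli; funnel PDs are tapered channels treated in the lubrication
approximation, i.e. as a series integral of the local fully developed
cross-sectional resistance along the taper.

Per-unit-length resistance of the two cross-section families:

* open circle of radius ``r``:       ``dR/dx = 8 mu / (pi r^4)``
* concentric annulus ``r_i < r_o``:  ``dR/dx = 8 mu / (pi k)`` with
  ``k = r_o^4 - r_i^4 - (r_o^2 - r_i^2)^2 / ln(r_o / r_i)``

Resistances add in series along a channel and combine reciprocally across a
parallel PD population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
from scipy.integrate import quad

from .geometry import PDGeometry

__all__ = [
    "NM",
    "SapProperties",
    "HydraulicResistance",
    "annulus_k",
    "annular_resistance",
    "tapered_tube_resistance",
    "integrate_series_resistance",
    "funnel_resistance",
    "pd_resistance",
    "population_conductance",
    "population_pressure",
]

#: metres per nanometre
NM = 1e-9

#: Calibrated phloem sap viscosity (Pa*s).  Chosen so that the base simple-PD
#: scenario (240 annular PDs, 230 fl/s) requires an 8.14 MPa differential;
#: consistent with ~500 mM sucrose sap at 20-25 C.  Flagged as an assumption
#: in every report.
DEFAULT_VISCOSITY_PA_S = 1.740e-3

#: Sucrose free diffusivity in water at 25 C (m^2/s).
DEFAULT_DIFFUSIVITY_M2_S = 5.2e-10


@dataclass(frozen=True)
class SapProperties:
    """Bulk properties of phloem sap.

    ``concentration_mol_m3`` is the osmotically active solute concentration
    (mol/m^3, numerically equal to mM); the 500 default is the literature
    consensus for phloem sucrose.  ``hindrance`` multiplies the free
    diffusivity to give the effective in-pore diffusivity
    ``D_eff = hindrance * diffusivity`` (1 = unhindered).
    """

    viscosity_pa_s: float = DEFAULT_VISCOSITY_PA_S
    diffusivity_m2_s: float = DEFAULT_DIFFUSIVITY_M2_S
    concentration_mol_m3: float = 500.0
    temperature_k: float = 298.0
    hindrance: float = 1.0

    def __post_init__(self) -> None:
        if not self.viscosity_pa_s > 0:
            raise ValueError("viscosity_pa_s must be strictly positive")
        if self.diffusivity_m2_s < 0:
            raise ValueError("diffusivity_m2_s must be non-negative")
        if self.concentration_mol_m3 < 0:
            raise ValueError("concentration_mol_m3 must be non-negative")
        if not self.temperature_k > 0:
            raise ValueError("temperature_k must be strictly positive")
        if not 0 <= self.hindrance <= 1:
            raise ValueError("hindrance must lie in [0, 1]")

    @property
    def effective_diffusivity_m2_s(self) -> float:
        return self.hindrance * self.diffusivity_m2_s


@dataclass(frozen=True)
class HydraulicResistance:
    """Pressure drop per unit volumetric flow through one channel (Pa*s/m^3)."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("hydraulic resistance must be strictly positive")

    def series(self, other: "HydraulicResistance") -> "HydraulicResistance":
        return HydraulicResistance(self.value + other.value)

    def parallel(self, other: "HydraulicResistance") -> "HydraulicResistance":
        return HydraulicResistance(1.0 / (1.0 / self.value + 1.0 / other.value))


def annulus_k(r_outer_m: float, r_inner_m: float) -> float:
    """Geometric factor k (m^4) of Poiseuille flow in a concentric annulus.

    ``Q = pi * dP * k / (8 mu L)``.
    """
    if not 0 < r_inner_m < r_outer_m:
        raise ValueError("annulus requires 0 < r_inner < r_outer")
    ro2, ri2 = r_outer_m**2, r_inner_m**2
    return ro2**2 - ri2**2 - (ro2 - ri2) ** 2 / np.log(r_outer_m / r_inner_m)


def annular_resistance(
    geom: PDGeometry,
    sap: SapProperties,
    model: Literal["annulus", "slit"] = "annulus",
) -> HydraulicResistance:
    """Hydraulic resistance of a simple (constant-annulus) PD.

    ``model="annulus"`` is the exact concentric-annulus solution;
    ``model="slit"`` unrolls the sleeve into a planar slit of width equal to
    the mean circumference (``R = 12 mu L / (w h^3)``), a thin-gap
    approximation useful as a cross-check.
    """
    if geom.kind != "simple":
        raise ValueError("annular_resistance requires a simple PD")
    if not geom.sleeve_width_nm > 0:
        raise ValueError("sleeve_width_nm must be strictly positive")
    ri = geom.desmotubule_radius_nm * NM
    ro = geom.neck_outer_radius_nm * NM
    length = geom.wall_length_nm * NM
    mu = sap.viscosity_pa_s
    if model == "annulus":
        value = 8.0 * mu * length / (np.pi * annulus_k(ro, ri))
    elif model == "slit":
        h = geom.sleeve_width_nm * NM
        w = np.pi * (ro + ri)  # mean circumference
        value = 12.0 * mu * length / (w * h**3)
    else:
        raise ValueError(f"unknown annulus model {model!r}")
    return HydraulicResistance(value)


def tapered_tube_resistance(
    r1_m: float, r2_m: float, length_m: float, viscosity_pa_s: float
) -> float:
    """Closed-form lubrication resistance of an open cone (Pa*s/m^3).

    For a circular tube whose radius varies linearly from ``r1`` to ``r2``
    over ``length``:  ``R = (8 mu L / 3 pi) (r1^2 + r1 r2 + r2^2) / (r1^3 r2^3)``.
    """
    if min(r1_m, r2_m, length_m, viscosity_pa_s) <= 0:
        raise ValueError("all arguments must be strictly positive")
    return (
        8.0 * viscosity_pa_s * length_m / (3.0 * np.pi)
        * (r1_m**2 + r1_m * r2_m + r2_m**2) / (r1_m**3 * r2_m**3)
    )


def integrate_series_resistance(
    outer_radius_m: Callable[[float], float],
    inner_radius_m: Callable[[float], float] | None,
    length_m: float,
    viscosity_pa_s: float,
    breakpoints_m: Sequence[float] = (),
    epsrel: float = 1e-10,
) -> float:
    """Series (lubrication) resistance of a channel of varying cross-section.

    Integrates the local per-length resistance of the cross-section at each
    axial position: annular where ``inner_radius_m`` is given and returns a
    positive radius, open-circular where it is ``None`` or returns 0.
    ``breakpoints_m`` marks discontinuities (e.g. where a desmotubule ends)
    for the adaptive quadrature.
    """

    def per_length(x: float) -> float:
        ro = outer_radius_m(x)
        ri = inner_radius_m(x) if inner_radius_m is not None else 0.0
        k = annulus_k(ro, ri) if ri > 0 else ro**4
        return 8.0 * viscosity_pa_s / (np.pi * k)

    pts = [p for p in breakpoints_m if 0.0 < p < length_m] or None
    value, _ = quad(per_length, 0.0, length_m, points=pts, epsrel=epsrel, limit=400)
    return value


def funnel_resistance(geom: PDGeometry, sap: SapProperties) -> HydraulicResistance:
    """Hydraulic resistance of a funnel PD under the lubrication approximation.

    The outer wall tapers linearly from the mouth to the neck.  In
    ``full_span`` mode the desmotubule obstructs the whole length (every
    cross-section annular); in ``neck_only`` mode only the final
    ``neck_fraction`` of the length is annular and the wide region is an
    open cone.  Always at most the resistance of the matching simple PD.
    """
    if geom.kind != "funnel":
        raise ValueError("funnel_resistance requires a funnel PD")
    length = geom.wall_length_nm * NM
    ri = geom.desmotubule_radius_nm * NM
    r_mouth = geom.mouth_radius_nm * NM
    r_neck = geom.neck_outer_radius_nm * NM

    def outer(x: float) -> float:
        return r_mouth + (r_neck - r_mouth) * x / length

    if geom.desmotubule_mode == "full_span":
        inner: Callable[[float], float] | None = lambda x: ri
        breakpoints: tuple[float, ...] = ()
    else:  # neck_only
        x_neck = (1.0 - geom.neck_fraction) * length

        def inner(x: float) -> float:
            return ri if x >= x_neck else 0.0

        breakpoints = (x_neck,)

    value = integrate_series_resistance(
        outer, inner, length, sap.viscosity_pa_s, breakpoints_m=breakpoints
    )
    return HydraulicResistance(value)


def pd_resistance(
    geom: PDGeometry,
    sap: SapProperties,
    annulus_model: Literal["annulus", "slit"] = "annulus",
) -> HydraulicResistance:
    """Resistance of a single PD of either kind."""
    if geom.kind == "simple":
        return annular_resistance(geom, sap, model=annulus_model)
    return funnel_resistance(geom, sap)


def population_conductance(
    population: Sequence[tuple[PDGeometry, int]],
    sap: SapProperties,
    annulus_model: Literal["annulus", "slit"] = "annulus",
) -> float:
    """Total hydraulic conductance (m^3/s/Pa) of parallel PDs."""
    if not population:
        raise ValueError("population must contain at least one PD")
    total = 0.0
    for geom, count in population:
        if count < 0:
            raise ValueError("PD counts must be non-negative")
        total += count / pd_resistance(geom, sap, annulus_model).value
    if total == 0:
        raise ValueError("population must contain at least one PD")
    return total


def population_pressure(
    q_total_m3_s: float,
    population: Sequence[tuple[PDGeometry, int]],
    sap: SapProperties,
    annulus_model: Literal["annulus", "slit"] = "annulus",
) -> float:
    """Pressure differential (Pa) driving ``q_total`` through parallel PDs.

    All PDs see the same differential, so the flow partitions in proportion
    to each channel's conductance: ``dP = Q / sum(count_i / R_i)``.
    """
    if q_total_m3_s < 0:
        raise ValueError("q_total_m3_s must be non-negative")
    return q_total_m3_s / population_conductance(population, sap, annulus_model)
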