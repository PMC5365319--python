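"""Run configuration: schema, defaults, YAML round trip.

One dialect (YAML), schema-validated with unknown keys rejected.  Every
field has a documented default equal to the base study value, so an empty
configuration reproduces the base scenario.  Fields whose defaults are
modelling assumptions rather than measurements are tracked so that reports
can flag them.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .geometry import DEFAULT_NECK_FRACTION, PDCensus, PDGeometry
from .hydraulics import (
    DEFAULT_DIFFUSIVITY_M2_S,
    DEFAULT_VISCOSITY_PA_S,
    SapProperties,
)
from .transport import DEFAULT_LP_BOUNDS, TubeGeometry

__all__ = ["RunConfig", "ASSUMED_DEFAULTS", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration file fails schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class TubeConfig(_Strict):
    """Sieve tube and unloading-zone dimensions (measured defaults)."""

    diameter_um: float = Field(3.6, gt=0)
    flow_velocity_um_s: float = Field(22.6, ge=0)
    unloading_zone_length_um: float = Field(350.0, gt=0)
    membrane_permeability_m_s_pa: Tuple[float, float] = DEFAULT_LP_BOUNDS


class SapConfig(_Strict):
    """Phloem sap properties; viscosity/diffusivity/temperature are assumptions."""

    viscosity_pa_s: float = Field(DEFAULT_VISCOSITY_PA_S, gt=0)
    diffusivity_m2_s: float = Field(DEFAULT_DIFFUSIVITY_M2_S, ge=0)
    concentration_mol_m3: float = Field(500.0, ge=0)
    temperature_k: float = Field(298.0, gt=0)
    hindrance: float = Field(1.0, gt=0, le=1)


class PDConfig(_Strict):
    """Plasmodesma geometry shared by the simple and funnel classes."""

    desmotubule_diameter_nm: float = Field(15.0, gt=0)
    sleeve_width_nm: float = Field(2.8, gt=0)
    wall_length_nm: float = Field(500.0, gt=0)
    funnel_mouth_diameter_nm: float = Field(150.0, gt=0)
    neck_fraction: float = Field(DEFAULT_NECK_FRACTION, gt=0, le=1)


class CensusConfig(_Strict):
    """PD census per protophloem unloading domain."""

    total_mean: float = Field(527.0, gt=0)
    total_sd: float = Field(58.0, ge=0)
    n_domains: int = Field(4, ge=1)
    fractions: Tuple[float, float, float] = (0.453, 0.408, 0.139)

    @model_validator(mode="after")
    def _fractions_sum(self):
        if abs(sum(self.fractions) - 1.0) > 0.005:
            raise ValueError("census fractions must sum to 1 within 0.005")
        return self


class RunConfig(_Strict):
    """Complete, resolved configuration of one scenario run."""

    tube: TubeConfig = TubeConfig()
    sap: SapConfig = SapConfig()
    pd: PDConfig = PDConfig()
    census: CensusConfig = CensusConfig()
    simple_pd_fraction: float = Field(
        0.10, ge=0, le=1,
        description="fraction of PSE-PPP PDs that are simple in the mixed population",
    )
    annulus_model: Literal["annulus", "slit"] = "annulus"
    leak_law: Literal["uniform", "exponential"] = "uniform"
    seed: int = Field(0, ge=0)

    # -- domain-object builders -------------------------------------------

    def to_tube(self) -> TubeGeometry:
        return TubeGeometry(
            diameter_um=self.tube.diameter_um,
            flow_velocity_um_s=self.tube.flow_velocity_um_s,
            unloading_zone_length_um=self.tube.unloading_zone_length_um,
            membrane_permeability_m_s_pa=tuple(self.tube.membrane_permeability_m_s_pa),
        )

    def to_sap(self) -> SapProperties:
        return SapProperties(
            viscosity_pa_s=self.sap.viscosity_pa_s,
            diffusivity_m2_s=self.sap.diffusivity_m2_s,
            concentration_mol_m3=self.sap.concentration_mol_m3,
            temperature_k=self.sap.temperature_k,
            hindrance=self.sap.hindrance,
        )

    def to_simple_geometry(self) -> PDGeometry:
        return PDGeometry.simple(
            desmotubule_diameter_nm=self.pd.desmotubule_diameter_nm,
            sleeve_width_nm=self.pd.sleeve_width_nm,
            wall_length_nm=self.pd.wall_length_nm,
        )

    def to_funnel_geometry(
        self, mode: Literal["full_span", "neck_only"] = "full_span"
    ) -> PDGeometry:
        return PDGeometry.funnel(
            mouth_diameter_nm=self.pd.funnel_mouth_diameter_nm,
            desmotubule_diameter_nm=self.pd.desmotubule_diameter_nm,
            sleeve_width_nm=self.pd.sleeve_width_nm,
            wall_length_nm=self.pd.wall_length_nm,
            desmotubule_mode=mode,
            neck_fraction=self.pd.neck_fraction,
        )

    def to_census(self) -> PDCensus:
        return PDCensus(
            total_mean=self.census.total_mean,
            total_sd=self.census.total_sd,
            n_domains=self.census.n_domains,
            fractions=tuple(self.census.fractions),
        )

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"configuration root must be a mapping, got {type(raw).__name__}")
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            lines = [
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors()
            ]
            raise ConfigError(
                "invalid configuration:\n  " + "\n  ".join(lines)
            ) from exc

    def assumed_defaults(self) -> dict[str, str]:
        """Fields still at an *assumed* (non-measured) default, with notes."""
        current = {
            "sap.viscosity_pa_s": self.sap.viscosity_pa_s,
            "sap.diffusivity_m2_s": self.sap.diffusivity_m2_s,
            "sap.temperature_k": self.sap.temperature_k,
            "sap.hindrance": self.sap.hindrance,
            "pd.neck_fraction": self.pd.neck_fraction,
        }
        return {
            key: note
            for key, note in ASSUMED_DEFAULTS.items()
            if current[key] == _ASSUMED_VALUES[key]
        }


#: Assumed (non-measured) defaults and why they hold, keyed by config path.
ASSUMED_DEFAULTS = {
    "sap.viscosity_pa_s": (
        f"{DEFAULT_VISCOSITY_PA_S:g} Pa*s: sap viscosity calibrated so the "
        "base simple-PD scenario requires 8.14 MPa; consistent with ~500 mM "
        "sucrose sap at 20-25 C"
    ),
    "sap.diffusivity_m2_s": (
        f"{DEFAULT_DIFFUSIVITY_M2_S:g} m^2/s: sucrose free diffusivity in "
        "water at 25 C (literature value)"
    ),
    "sap.temperature_k": "298 K: assumed room temperature for van 't Hoff",
    "sap.hindrance": "1: no steric/hydrodynamic hindrance applied in-pore",
    "pd.neck_fraction": (
        f"{DEFAULT_NECK_FRACTION:g}: obstructed neck fraction of the "
        "favourable desmotubule placement, calibrated so the mixed "
        "population requires 0.05 MPa"
    ),
}

_ASSUMED_VALUES = {
    "sap.viscosity_pa_s": DEFAULT_VISCOSITY_PA_S,
    "sap.diffusivity_m2_s": DEFAULT_DIFFUSIVITY_M2_S,
    "sap.temperature_k": 298.0,
    "sap.hindrance": 1.0,
    "pd.neck_fraction": DEFAULT_NECK_FRACTION,
}


def load_config(path=None) -> RunConfig:
    """Load a YAML configuration, or the all-defaults configuration."""
    if path is None:
        return RunConfig()
    return RunConfig.from_yaml(path)
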