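"""Scenario reports: CSV, aligned-text table, config echo and run log.

``run_scenario`` is the top-level entry point behind the CLI.  It resolves
a configuration, evaluates every unloading mechanism, and writes a small
bundle of deterministic (timestamp-free) artifacts so that re-running the
echoed configuration reproduces the report byte for byte.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import pandas as pd

from .config import RunConfig, load_config
from .geometry import census_to_csv, interface_counts
from .transport import ScenarioResult, scenario_report

__all__ = ["run_scenario", "scenario_frame", "format_table"]

logger = logging.getLogger("phloemflow")

MPA = 1e6
FL = 1e-18  # m^3 per femtolitre


def _sig3(value: float) -> str:
    return f"{value:.3g}"


def scenario_frame(result: ScenarioResult, config: RunConfig) -> pd.DataFrame:
    """Machine-readable scenario report (one row per quantity, SI + display)."""
    counts = interface_counts(config.to_census())
    n_ppp = counts.ppp_nearest_ten
    n_simple = int(round(config.simple_pd_fraction * n_ppp))
    n_funnel = n_ppp - n_simple
    rows = [
        ("volumetric_flow", result.q_m3_s, "m^3/s", _sig3(result.q_m3_s / FL), "fl/s"),
        ("solute_flux", result.i_mol_s, "mol/s", _sig3(result.i_mol_s), "mol/s"),
        ("pressure_simple_pd", result.dp_simple_pa, "Pa",
         _sig3(result.dp_simple_pa / MPA), "MPa"),
        ("pressure_mixed_full_span", result.dp_funnel_pa[0], "Pa",
         _sig3(result.dp_funnel_pa[0] / MPA), "MPa"),
        ("pressure_mixed_neck_only", result.dp_funnel_pa[1], "Pa",
         _sig3(result.dp_funnel_pa[1] / MPA), "MPa"),
        ("diffusive_concentration_difference", result.dc_diffusive_mol_m3,
         "mol/m^3", _sig3(result.dc_diffusive_mol_m3), "mM"),
        ("membrane_pressure_high_Lp", result.dp_membrane_pa[0], "Pa",
         _sig3(result.dp_membrane_pa[0] / MPA), "MPa"),
        ("membrane_pressure_low_Lp", result.dp_membrane_pa[1], "Pa",
         _sig3(result.dp_membrane_pa[1] / MPA), "MPa"),
        ("peclet_per_funnel_pd", result.peclet_funnel, "-",
         _sig3(result.peclet_funnel), "-"),
        ("osmotic_equiv_full_span", result.osmotic_equivalent_mol_m3[0],
         "mol/m^3", _sig3(result.osmotic_equivalent_mol_m3[0]), "mM"),
        ("osmotic_equiv_neck_only", result.osmotic_equivalent_mol_m3[1],
         "mol/m^3", _sig3(result.osmotic_equivalent_mol_m3[1]), "mM"),
        ("n_pd_simple_scenario", float(n_ppp), "count", str(n_ppp), "count"),
        ("n_pd_mixed_simple", float(n_simple), "count", str(n_simple), "count"),
        ("n_pd_mixed_funnel", float(n_funnel), "count", str(n_funnel), "count"),
    ]
    return pd.DataFrame(
        rows, columns=["quantity", "value_si", "unit_si", "display", "unit_display"]
    )


def format_table(result: ScenarioResult, config: RunConfig) -> str:
    """Aligned-text report mirroring the base-parameter table layout."""
    c = config
    counts = interface_counts(c.to_census())
    n_ppp = counts.ppp_nearest_ten
    n_simple = int(round(c.simple_pd_fraction * n_ppp))
    n_funnel = n_ppp - n_simple
    q_fl = _sig3(result.q_m3_s / FL)
    rows = [
        ("", "Assuming transport through simple PD at PSE/PPP interface",
         "Transport through PD at PSE/PPP interface"),
        ("Length of unloading zone",
         f"{_sig3(c.tube.unloading_zone_length_um)} um",
         f"{_sig3(c.tube.unloading_zone_length_um)} um"),
        ("Desmotubule Diameter",
         f"{_sig3(c.pd.desmotubule_diameter_nm)} nm",
         f"{_sig3(c.pd.desmotubule_diameter_nm)} nm"),
        ("Cytoplasmic Sleeve Diameter",
         f"{_sig3(c.pd.sleeve_width_nm)} nm", f"{_sig3(c.pd.sleeve_width_nm)} nm"),
        ("Cell Wall Thickness",
         f"{_sig3(c.pd.wall_length_nm)} nm", f"{_sig3(c.pd.wall_length_nm)} nm"),
        ("Phloem Sap Osmotic Potential",
         f"{_sig3(c.sap.concentration_mol_m3)} mM",
         f"{_sig3(c.sap.concentration_mol_m3)} mM"),
        ("Funnel opening towards PSE", "-",
         f"{_sig3(c.pd.funnel_mouth_diameter_nm)} nm"),
        ("# of PD available for Unloading", f"{n_ppp} simple PD",
         f"{n_simple} simple PD, {n_funnel} funnel PD"),
        ("Total Sap Volume", f"{q_fl} fl/s", f"{q_fl} fl/s"),
        ("Required Pressure Differential",
         f"{_sig3(result.dp_simple_pa / MPA)} MPa",
         f"{_sig3(result.dp_funnel_pa[1] / MPA)}-"
         f"{_sig3(result.dp_funnel_pa[0] / MPA)} MPa"),
    ]
    derived = [
        ("Diffusive unloading requires dc",
         f"{_sig3(result.dc_diffusive_mol_m3)} mM"),
        ("Membrane water removal requires",
         f"{_sig3(result.dp_membrane_pa[0] / MPA)}-"
         f"{_sig3(result.dp_membrane_pa[1] / MPA)} MPa"),
        ("Osmotic equivalent of bulk-flow dP",
         f"{_sig3(result.osmotic_equivalent_mol_m3[1])}-"
         f"{_sig3(result.osmotic_equivalent_mol_m3[0])} mM"),
        ("Peclet number per funnel PD", _sig3(result.peclet_funnel)),
    ]
    w0 = max(len(r[0]) for r in rows + derived) + 2
    w1 = max(len(r[1]) for r in rows) + 2
    lines = [f"{r[0]:<{w0}}{r[1]:<{w1}}{r[2]}".rstrip() for r in rows]
    lines.append("")
    lines.append("Derived quantities")
    lines.extend(f"{r[0]:<{w0}}{r[1]}" for r in derived)
    return "\n".join(lines) + "\n"


def run_scenario(config_path=None, outdir="phloemflow_out") -> ScenarioResult:
    """Run the full scenario for a configuration file and write the report.

    Writes, under ``outdir``: ``resolved_config.yaml`` (the complete
    configuration echo), ``scenario.csv`` and ``scenario.txt`` (machine and
    human reports), ``census.csv``, and ``run.log`` listing every assumed
    default exactly once.  All outputs are deterministic.
    """
    config = load_config(config_path)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log_lines: list[str] = []

    def log(line: str) -> None:
        log_lines.append(line)
        logger.info(line)

    log(f"config: {'defaults' if config_path is None else str(config_path)}")
    for key, note in config.assumed_defaults().items():
        log(f"assumption: {key} = {note}")

    result = scenario_report(
        tube=config.to_tube(),
        sap=config.to_sap(),
        census=config.to_census(),
        simple_geom=config.to_simple_geometry(),
        funnel_geom=config.to_funnel_geometry(),
        annulus_model=config.annulus_model,
    )

    config.to_yaml(outdir / "resolved_config.yaml")
    scenario_frame(result, config).to_csv(outdir / "scenario.csv", index=False)
    (outdir / "scenario.txt").write_text(format_table(result, config))
    census_to_csv(config.to_census(), outdir / "census.csv")
    log(f"wrote scenario report to {outdir / 'scenario.txt'}")
    (outdir / "run.log").write_text(
        "\n".join(line for line in log_lines if not line.startswith("wrote ")) + "\n"
    )
    return result


def configure_logging(verbose: bool = False) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
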