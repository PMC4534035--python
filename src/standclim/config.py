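"""Simulation configuration: defaults, YAML loading, validation.

A :class:`SimulationConfig` bundles everything a run needs: the climate
source (synthetic generator, CSV file, or a delta-method scenario on
top of the reference), the soil profile, per-species parameter blocks,
the response curves, the reference (calibration) period, stand
initialization and the run length.  :func:`default_config` builds the
fully populated default; :func:`load_config` deep-merges a YAML file
over it, so a config file only needs to name what it changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any

import yaml

from . import defaults
from .climate import ScenarioDeltas, SyntheticClimateParams
from .co2 import CO2Params
from .curves import ResponseCurve
from .hydrology import SoilLayerSpec
from .stand import SpeciesGrowthParams, SpeciesPools


@dataclass
class SimulationConfig:
    """Everything one simulation needs.  Build via :func:`default_config`."""

    species: list[str]
    growth_params: dict[str, SpeciesGrowthParams]
    soil: list[SoilLayerSpec]
    t_curves: dict[str, ResponseCurve]
    s_curves: dict[str, ResponseCurve]
    m_curves: dict[str, ResponseCurve]         # by layer kind
    canopy: dict[str, dict[str, float]]        # albedo, r_can_ref, max_root_depth
    co2_params: CO2Params
    synthetic: SyntheticClimateParams
    scenario: ScenarioDeltas | None = None
    climate_source: str = "synthetic"          # synthetic | file | scenario
    climate_file: str | None = None
    reference_years: int = 30
    run_years: int = 100
    established: bool = False
    seed: int = 42
    calibration_lai: float = defaults.CALIBRATION_LAI
    latitude: float = defaults.SITE["latitude"]
    elevation: float = defaults.SITE["elevation"]
    n_deposition: float = defaults.N_DEPOSITION
    write_daily: bool = False

    def __post_init__(self):
        if self.reference_years < 1:
            raise ValueError("reference period must cover at least 1 year")
        if self.climate_source not in ("synthetic", "file", "scenario"):
            raise ValueError(f"unknown climate source {self.climate_source!r}")
        if self.climate_source == "file" and not self.climate_file:
            raise ValueError("climate source 'file' needs climate_file")
        if self.climate_source == "scenario" and self.scenario is None:
            raise ValueError("climate source 'scenario' needs a scenario block")
        for sp in self.species:
            for table, label in ((self.growth_params, "growth parameters"),
                                 (self.t_curves, "temperature curve"),
                                 (self.s_curves, "water-stress curve"),
                                 (self.canopy, "canopy parameters")):
                if sp not in table:
                    raise ValueError(f"species {sp!r} missing {label}")

    def initial_stand(self) -> dict[str, SpeciesPools]:
        return {sp: defaults.initial_pools(sp, self.established) for sp in self.species}


def default_config(species: str | list[str] = "douglas_fir", **overrides: Any
                   ) -> SimulationConfig:
    """The fully populated default configuration (pure single-species stand)."""
    names = [species] if isinstance(species, str) else list(species)
    cfg = SimulationConfig(
        species=names,
        growth_params={sp: defaults.default_species_params(sp) for sp in names},
        soil=defaults.default_soil_profile(),
        t_curves={sp: defaults.temperature_growth_curve(sp) for sp in names},
        s_curves={sp: defaults.water_stress_growth_curve(sp) for sp in names},
        m_curves=defaults.moisture_decomp_curves(),
        canopy={sp: dict(defaults.CANOPY[sp]) for sp in names},
        co2_params=CO2Params(),
        synthetic=SyntheticClimateParams(),
    )
    return replace(cfg, **overrides) if overrides else cfg


# -- YAML --------------------------------------------------------------


def _curve_from_cfg(pairs, name):
    return ResponseCurve.from_pairs([(float(a), float(b)) for a, b in pairs], name=name)


def load_config(path) -> SimulationConfig:
    """Build a configuration from a YAML file merged over the defaults.

    Recognized top-level keys: ``species`` (name or list), ``site``
    (latitude/elevation), ``seed``, ``run`` (years / established /
    write_daily), ``reference`` (years / calibration_lai), ``co2``
    (c_a0 / compensation_ppm), ``climate`` (source / file / synthetic
    parameter overrides), ``scenario`` (anchor periods with 12 monthly
    ``t_offsets`` and ``p_ratios`` each, plus a ``co2`` trajectory), and
    ``curves`` (per-species ``t_growth`` / ``s_growth`` / ``mortality``
    breakpoint lists).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = default_config(raw.get("species", "douglas_fir"))

    if "site" in raw:
        cfg.latitude = float(raw["site"].get("latitude", cfg.latitude))
        cfg.elevation = float(raw["site"].get("elevation", cfg.elevation))
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    run = raw.get("run", {})
    cfg.run_years = int(run.get("years", cfg.run_years))
    cfg.established = bool(run.get("established", cfg.established))
    cfg.write_daily = bool(run.get("write_daily", cfg.write_daily))
    ref = raw.get("reference", {})
    cfg.reference_years = int(ref.get("years", cfg.reference_years))
    cfg.calibration_lai = float(ref.get("calibration_lai", cfg.calibration_lai))
    if "co2" in raw:
        cfg.co2_params = CO2Params(
            c_a0=float(raw["co2"].get("c_a0", cfg.co2_params.c_a0)),
            r_prime=float(raw["co2"].get("compensation_ppm", cfg.co2_params.r_prime)),
        )
    clim = raw.get("climate", {})
    cfg.climate_source = clim.get("source", cfg.climate_source)
    cfg.climate_file = clim.get("file", cfg.climate_file)
    if "synthetic" in clim:
        cfg.synthetic = replace(cfg.synthetic, **{
            k: (int(v) if k in ("t_peak_doy", "start_year") else float(v))
            for k, v in clim["synthetic"].items()
        })
    if "scenario" in raw:
        sc = raw["scenario"]
        anchors = {int(y): (block["t_offsets"], block["p_ratios"])
                   for y, block in sc.get("anchors", {}).items()}
        co2 = {int(y): float(v) for y, v in sc.get("co2", {}).items()}
        cfg.scenario = ScenarioDeltas(anchors=anchors, co2=co2)
        if cfg.climate_source == "synthetic" and "source" not in clim:
            cfg.climate_source = "scenario"
    for sp, block in raw.get("curves", {}).items():
        if "t_growth" in block:
            cfg.t_curves[sp] = _curve_from_cfg(block["t_growth"], f"T_growth[{sp}]")
        if "s_growth" in block:
            cfg.s_curves[sp] = _curve_from_cfg(block["s_growth"], f"S_growth[{sp}]")
        if "mortality" in block:
            cfg.growth_params[sp] = replace(
                cfg.growth_params[sp],
                mortality_curve=_curve_from_cfg(block["mortality"], f"mortality[{sp}]"),
            )
    # re-run validation with the merged values
    cfg.__post_init__()
    return cfg
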