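"""Default parameter tables: site, soils, species, response curves.

Soil-profile and canopy hydrology values reproduce the published
parameterization for an Interior Douglas-fir dry cool subzone site
(silt-loam mineral horizons under a 12.5 cm humus layer; species albedo,
reference canopy resistance, wilting points and rooting depths for
interior Douglas-fir and lodgepole pine).  Growth-engine values
(allocation, turnover, tissue N concentrations, radiation-use
efficiency, litter quality) and the exact breakpoints of the response
curves are this package's own editable defaults, chosen to be realistic
for montane interior conifer stands; the curve *shapes* (dormancy break
near 5 degC, species-specific optima, drought-tolerance ordering with
Douglas-fir slightly more tolerant than lodgepole pine) follow the
published qualitative forms.
"""

from __future__ import annotations

from .curves import ResponseCurve
from .hydrology import SoilLayerSpec
from .stand import SpeciesGrowthParams, SpeciesPools

SITE = {"latitude": 50.93, "elevation": 1162.0}

#: DRI layer names: a virtual litter layer shares the humus layer's
#: moisture but has its own moisture response curve.
DRI_LAYERS = {
    "litter": ("humus", "litter"),      # (profile layer supplying moisture, curve kind)
    "humus": ("humus", "humus"),
    "mineral_a": ("mineral_a", "mineral"),
    "mineral_b": ("mineral_b", "mineral"),
    "mineral_c": ("mineral_c", "mineral"),
}


def default_soil_profile() -> list[SoilLayerSpec]:
    """Humus over three silt-loam mineral horizons."""
    wp_trees_humus = {"douglas_fir": 0.08, "lodgepole_pine": 0.10}
    wp_trees_mineral = {"douglas_fir": 0.12, "lodgepole_pine": 0.13}
    return [
        SoilLayerSpec("humus", "organic", 0.0, 12.5, 0.32,
                      wilting_point=wp_trees_humus, kind="humus"),
        SoilLayerSpec("mineral_a", "silt loam", 25.0, 40.0, 0.25,
                      wilting_point=wp_trees_mineral, kind="mineral"),
        SoilLayerSpec("mineral_b", "silt loam", 25.0, 45.0, 0.25,
                      wilting_point=wp_trees_mineral, kind="mineral"),
        SoilLayerSpec("mineral_c", "silt loam", 25.0, 50.0, 0.25,
                      wilting_point=wp_trees_mineral, kind="mineral"),
    ]


# canopy hydrology parameters per species (albedo, reference resistance,
# max rooting depth in cm)
CANOPY = {
    "douglas_fir": {"albedo": 0.12, "r_can_ref": 0.30, "max_root_depth": 100.0},
    "lodgepole_pine": {"albedo": 0.12, "r_can_ref": 0.24, "max_root_depth": 100.0},
}


def temperature_growth_curve(species: str) -> ResponseCurve:
    """Daily temperature response of growth.

    Both species break dormancy sharply around 5 degC; Douglas-fir has a
    slightly warmer, broader optimum while lodgepole pine peaks cooler
    and declines faster at high temperature.
    """
    shapes = {
        "douglas_fir": [(2, 0.0), (5, 0.15), (10, 0.8), (15, 1.0), (19, 1.0),
                        (26, 0.6), (33, 0.2), (40, 0.0)],
        "lodgepole_pine": [(2, 0.0), (5, 0.2), (10, 0.9), (14, 1.0), (17, 1.0),
                           (24, 0.55), (32, 0.15), (40, 0.0)],
    }
    return ResponseCurve.from_pairs(shapes[species], name=f"T_growth[{species}]")


def water_stress_growth_curve(species: str) -> ResponseCurve:
    """Daily water-stress response of growth (declining in TDI)."""
    shapes = {
        "douglas_fir": [(0.0, 1.0), (0.2, 0.95), (0.4, 0.75), (0.6, 0.45),
                        (0.8, 0.15), (1.0, 0.0)],
        "lodgepole_pine": [(0.0, 1.0), (0.2, 0.9), (0.4, 0.68), (0.6, 0.38),
                           (0.8, 0.1), (1.0, 0.0)],
    }
    return ResponseCurve.from_pairs(shapes[species], name=f"S_growth[{species}]")


def mortality_curve(species: str) -> ResponseCurve:
    """Annual drought mortality vs two-year running mean TDI.

    Zero below a stress threshold; Douglas-fir (the more drought-tolerant
    species here) sits at or below lodgepole pine at every stress level.
    The thresholds were placed by the usual iterative procedure: run the
    reference climate, inspect the stress distribution (growing-season
    mean TDI ~0.65-0.70 on this summer-dry site), and set the ramp so
    reference-climate drought mortality stays in the sub-percent range
    while drier-than-reference years climb steeply.
    """
    shapes = {
        "douglas_fir": [(0.0, 0.0), (0.60, 0.0), (0.70, 0.005), (0.80, 0.02),
                        (0.90, 0.06), (1.0, 0.15)],
        "lodgepole_pine": [(0.0, 0.0), (0.55, 0.002), (0.70, 0.012), (0.80, 0.035),
                           (0.90, 0.10), (1.0, 0.22)],
    }
    return ResponseCurve.from_pairs(shapes[species], name=f"mortality[{species}]")


def moisture_decomp_curves() -> dict[str, ResponseCurve]:
    """Moisture decomposition responses for litter, humus and mineral soil.

    Drivers are relative water content (fraction of field capacity);
    each curve rises from a dry minimum to a plateau of 1 approaching
    field capacity, with the mineral soil the most moisture-demanding.
    """
    return {
        "litter": ResponseCurve.from_pairs(
            [(0.0, 0.05), (0.3, 0.5), (0.7, 1.0), (1.0, 1.0)], name="M_decomp[litter]"),
        "humus": ResponseCurve.from_pairs(
            [(0.0, 0.02), (0.25, 0.45), (0.65, 1.0), (1.0, 1.0)], name="M_decomp[humus]"),
        "mineral": ResponseCurve.from_pairs(
            [(0.0, 0.0), (0.2, 0.4), (0.6, 1.0), (1.0, 1.0)], name="M_decomp[mineral]"),
    }


#: base annual mass-loss fraction per litter type (litter-quality ladder:
#: foliage and fine roots fast, branches slower, stem snags slowest)
LITTER_BDR = {
    "foliage_litter": 0.25,
    "fine_root_litter": 0.30,
    "branch_litter": 0.10,
    "stem_snag": 0.04,
    "coarse_root_litter": 0.08,
}


def default_species_params(species: str) -> SpeciesGrowthParams:
    if species not in CANOPY:
        raise KeyError(f"unknown species {species!r}")
    sla = {"douglas_fir": 5.5, "lodgepole_pine": 4.5}[species]
    return SpeciesGrowthParams(
        name=species,
        sla=sla,
        rue=0.3,
        allocation={"foliage": 0.25, "sapwood": 0.35, "branches": 0.10,
                    "fine_roots": 0.20, "coarse_roots": 0.10},
        turnover={"foliage": 0.15, "sapwood": 0.0, "branches": 0.03,
                  "fine_roots": 0.5, "coarse_roots": 0.02},
        n_concentration={"foliage": 10.0, "sapwood": 1.0, "branches": 3.0,
                         "fine_roots": 8.0, "coarse_roots": 2.0},
        litter_bdr=dict(LITTER_BDR),
        mortality_curve=mortality_curve(species),
        background_mortality=0.005,
    )


def initial_pools(species: str, established: bool) -> SpeciesPools:
    """Starting biomass: a newly planted (age 1) or 60-year-old stand."""
    if established:
        pools = {"foliage": 8.0, "sapwood": 140.0, "branches": 18.0,
                 "fine_roots": 4.0, "coarse_roots": 28.0}
        stems = 900.0
    else:
        pools = {"foliage": 0.2, "sapwood": 0.1, "branches": 0.05,
                 "fine_roots": 0.1, "coarse_roots": 0.05}
        stems = 1600.0
    return SpeciesPools(species=species, pools=pools, stems=stems)


#: initial dead organic matter (tons / kg ha-1): a partly decayed fine
#: litter store plus active and passive humus
INITIAL_LITTER = {"mass": 14.0, "original": 28.0, "nitrogen": 140.0,
                  "litter_type": "initial_fine_litter", "layer": "litter",
                  "bdr": 0.2}
INITIAL_HUMUS = {"active": {"mass": 60.0, "nitrogen": 700.0},
                 "passive": {"mass": 100.0, "nitrogen": 800.0}}

#: annual atmospheric N deposition (kg ha-1 y-1)
N_DEPOSITION = 2.0

#: fraction of unused mineral N carried into the next year; the rest
#: leaches below the rooting zone
N_CARRYOVER = 0.5

#: fixed leaf area per species used for the calibration (index
#: normalization) runs: a closed mid-rotation canopy
CALIBRATION_LAI = 2.5
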