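"""Daily forest water balance and the transpiration deficit index.

The soil is a stack of layers (humus over mineral horizons), each a
bucket with a capacity set by field capacity, depth and coarse-fragment
content.  Each day, in fixed order: precipitation is split rain/snow,
rain is intercepted by the canopy up to a storage capacity (and lost to
evaporation the same day), the snowpack melts by a degree-day rule,
throughfall plus melt infiltrates the top layer, each species extracts
water against its energy-driven transpiration demand, the soil surface
evaporates from the humus layer, and water above field capacity cascades
downward with the bottom-layer excess leaving as deep drainage.

Transpiration demand is Priestley-Taylor potential evapotranspiration of
the shortwave radiation each canopy intercepts, divided by
``1 + R_canopy`` (the CO2-adjustable canopy resistance).  The daily
transpiration deficit index for a species is

    TDI = (demand - actual) / demand,

zero when soil water is non-limiting (and by convention when demand is
zero, i.e. winter) and one when no uptake is possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# fixed process parameters (documented stand-in defaults, exposed here)
PRIESTLEY_TAYLOR_ALPHA = 1.26
CANOPY_STORAGE_PER_LAI = 0.2    # mm of interception storage per unit LAI
SNOWMELT_DEGREE_DAY = 3.0       # mm per degC per day above 0 degC
SOIL_EVAP_SHAPE = 3.0           # exponential supply curve steepness
LIGHT_EXTINCTION_K = 0.5        # Beer-Lambert canopy extinction coefficient
SOIL_ALBEDO = 0.1

_LATENT_HEAT = 2.45             # MJ kg-1
_PSYCHROMETRIC = 0.066          # kPa degC-1


@dataclass(frozen=True)
class SoilLayerSpec:
    """One soil layer: geometry, texture and water-retention parameters.

    ``wilting_point`` maps a layer *kind* dependent value per species
    name to the volumetric moisture content below which that species
    cannot extract water.  Capacities are volumetric fractions of the
    fine-earth volume; coarse fragments reduce the water-holding volume.
    """

    name: str
    texture: str
    coarse_frag: float          # % by volume
    depth: float                # cm
    field_capacity: float       # volumetric fraction
    wilting_point: dict[str, float] = field(default_factory=dict)
    kind: str = "mineral"       # "humus" | "mineral"

    def __post_init__(self):
        if not (0 <= self.coarse_frag < 100):
            raise ValueError(f"{self.name}: coarse fragment % outside [0, 100)")
        if self.depth <= 0:
            raise ValueError(f"{self.name}: depth must be > 0")
        if not (0 < self.field_capacity <= 1):
            raise ValueError(f"{self.name}: field capacity outside (0, 1]")
        for sp, wp in self.wilting_point.items():
            if not (0 <= wp < self.field_capacity):
                raise ValueError(f"{self.name}: wilting point for {sp} not in "
                                 f"[0, field capacity)")

    @property
    def capacity_mm(self) -> float:
        """Plant-relevant water storage at field capacity (mm)."""
        return self.field_capacity * self.depth * (1.0 - self.coarse_frag / 100.0) * 10.0

    def wilting_mm(self, species: str) -> float:
        wp = self.wilting_point.get(species, 0.0)
        return wp * self.depth * (1.0 - self.coarse_frag / 100.0) * 10.0


@dataclass
class SpeciesCanopySpec:
    """Per-species canopy state the water balance needs for one year."""

    name: str
    albedo: float
    r_can: float                # canopy resistance (possibly CO2-adjusted)
    max_root_depth: float       # cm
    lai: float                  # m2 m-2
    stratum: str = "tree"       # "tree" | "understory"

    def __post_init__(self):
        if not (0 <= self.albedo <= 1):
            raise ValueError("albedo outside [0, 1]")
        if self.r_can < 0 or self.max_root_depth <= 0 or self.lai < 0:
            raise ValueError("invalid canopy parameters")


@dataclass
class WaterState:
    """Water stores: snowpack (mm SWE), canopy (mm) and per-layer soil (mm)."""

    snow: float
    canopy: float
    layer_water: np.ndarray

    def copy(self) -> "WaterState":
        return WaterState(self.snow, self.canopy, self.layer_water.copy())

    def total(self) -> float:
        return self.snow + self.canopy + float(np.sum(self.layer_water))

    @classmethod
    def at_field_capacity(cls, profile) -> "WaterState":
        return cls(0.0, 0.0, np.array([l.capacity_mm for l in profile]))


@dataclass
class DailyFlux:
    """One day's water fluxes (mm) and per-species stress indices."""

    precip: float = 0.0
    interception_loss: float = 0.0
    snowmelt: float = 0.0
    infiltration: float = 0.0
    soil_evaporation: float = 0.0
    drainage: float = 0.0
    demand: dict[str, float] = field(default_factory=dict)
    actual: dict[str, float] = field(default_factory=dict)
    tdi: dict[str, float] = field(default_factory=dict)
    absorbed: dict[str, float] = field(default_factory=dict)  # MJ m-2
    balance_residual: float = 0.0


# -- component operations ----------------------------------------------


def saturation_slope(t_mean: float) -> float:
    """Slope of the saturation vapour pressure curve (kPa degC-1)."""
    es = 0.6108 * math.exp(17.27 * t_mean / (t_mean + 237.3))
    return 4098.0 * es / (t_mean + 237.3) ** 2


def priestley_taylor_pet(net_shortwave: float, t_mean: float,
                         alpha: float = PRIESTLEY_TAYLOR_ALPHA) -> float:
    """Energy-limited potential evapotranspiration (mm day-1).

    ``PET = alpha * Delta/(Delta + gamma) * R_net / lambda`` with Delta
    the saturation vapour-pressure slope at the daily mean temperature,
    gamma the psychrometric constant (0.066 kPa/degC) and lambda the
    latent heat of vaporization (2.45 MJ/kg, so 1 MJ m-2 evaporates
    1/2.45 mm).
    """
    if net_shortwave < 0:
        raise ValueError("net shortwave must be >= 0")
    if not (-50.0 <= t_mean <= 60.0):
        raise ValueError("t_mean outside plausible range [-50, 60] degC")
    delta = saturation_slope(t_mean)
    return alpha * (delta / (delta + _PSYCHROMETRIC)) * net_shortwave / _LATENT_HEAT


def partition_radiation(incoming: float, vegetation: list[SpeciesCanopySpec]
                        ) -> tuple[dict[str, float], float]:
    """Beer-Lambert partition of shortwave through canopy strata.

    Trees shade the understory which shades the soil.  Within a stratum
    the intercepted fraction ``1 - exp(-k * LAI_total)`` is shared among
    species in proportion to their LAI; each species absorbs its share
    times ``1 - albedo``.  Returns per-species absorbed radiation and the
    net radiation reaching the soil surface (after soil albedo).  Energy
    is conserved: absorbed + reflected + soil net + soil reflected equals
    the incoming flux.
    """
    if incoming < 0:
        raise ValueError("incoming radiation must be >= 0")
    absorbed: dict[str, float] = {}
    flux = incoming
    for stratum in ("tree", "understory"):
        members = [v for v in vegetation if v.stratum == stratum]
        if any(v.lai < 0 for v in members):
            raise ValueError("negative LAI")
        lai_total = sum(v.lai for v in members)
        if lai_total <= 0:
            for v in members:
                absorbed[v.name] = 0.0
            continue
        intercepted = flux * (1.0 - math.exp(-LIGHT_EXTINCTION_K * lai_total))
        for v in members:
            share = intercepted * (v.lai / lai_total)
            absorbed[v.name] = share * (1.0 - v.albedo)
        flux -= intercepted
    soil_net = flux * (1.0 - SOIL_ALBEDO)
    return absorbed, soil_net


def transpiration_demand(intercepted: float, t_mean: float, canopy_resistance: float,
                         alpha: float = PRIESTLEY_TAYLOR_ALPHA) -> float:
    """Energy-driven transpiration demand (mm day-1).

    Priestley-Taylor PET of the canopy's absorbed shortwave, damped by
    the canopy resistance through the multiplicative factor
    ``1 / (1 + R_canopy)``: zero resistance means demand equals the
    energy-limited rate; a higher (e.g. CO2-adjusted) resistance lowers
    demand.
    """
    if canopy_resistance < 0:
        raise ValueError("canopy resistance must be >= 0")
    return priestley_taylor_pet(intercepted, t_mean, alpha) / (1.0 + canopy_resistance)


def actual_transpiration(demand: float, available: np.ndarray, occupancy: np.ndarray
                         ) -> tuple[float, np.ndarray]:
    """Actual uptake given per-layer available water and root occupancy.

    Supply is the occupancy-weighted available water above the species'
    wilting point; uptake is ``min(demand, supply)`` and is withdrawn
    from layers in proportion to ``occupancy * available``, which can
    never draw a layer below its wilting point.
    """
    if demand < 0:
        raise ValueError("demand must be >= 0")
    weights = occupancy * np.maximum(available, 0.0)
    supply = float(np.sum(weights))
    if supply <= 0.0 or demand == 0.0:
        return 0.0, np.zeros_like(weights)
    actual = min(demand, supply)
    extraction = actual * weights / supply
    return actual, extraction


def compute_tdi(demand: float, actual: float) -> float:
    """Transpiration deficit index, ``(demand - actual) / demand`` in [0, 1].

    Defined as 0 when demand is zero (winter convention: no demand means
    no stress).
    """
    if demand < 0 or actual < 0 or actual > demand + 1e-12:
        raise ValueError("require 0 <= actual <= demand")
    if demand == 0.0:
        return 0.0
    return min(1.0, max(0.0, (demand - actual) / demand))


def root_occupancy(species: SpeciesCanopySpec, profile: list[SoilLayerSpec]) -> np.ndarray:
    """Fraction of each layer's depth interval reached by the species' roots."""
    occ = np.zeros(len(profile))
    top = 0.0
    for i, layer in enumerate(profile):
        bottom = top + layer.depth
        overlap = max(0.0, min(species.max_root_depth, bottom) - top)
        occ[i] = overlap / layer.depth
        top = bottom
    return occ


# -- the daily step ----------------------------------------------------


def step_day(state: WaterState, t_mean: float, precip: float, snow_frac: float,
             solar: float, vegetation: list[SpeciesCanopySpec],
             profile: list[SoilLayerSpec],
             occupancy: dict[str, np.ndarray] | None = None
             ) -> tuple[WaterState, DailyFlux]:
    """Advance the water balance one day and return the flux summary.

    The update order is fixed: rain/snow split -> snowmelt -> canopy
    interception -> infiltration -> per-species uptake (in list order)
    -> soil evaporation -> drainage cascade.  The returned flux carries
    the water-balance residual, which closes to ~1e-12 mm.
    """
    if not all(map(math.isfinite, (t_mean, precip, snow_frac, solar))):
        raise ValueError("non-finite forcing")
    if precip < 0 or solar < 0 or not (0 <= snow_frac <= 1):
        raise ValueError("invalid forcing")

    water = state.layer_water.copy()
    flux = DailyFlux(precip=precip)
    storage_before = state.total()

    # precipitation split and snowpack
    snowfall = precip * snow_frac
    rain = precip - snowfall
    snow = state.snow + snowfall
    melt = min(snow, SNOWMELT_DEGREE_DAY * max(0.0, t_mean))
    snow -= melt
    flux.snowmelt = melt

    # canopy interception: storage up to 0.2 mm x LAI evaporates same day
    lai_total = sum(v.lai for v in vegetation)
    interception = min(rain, CANOPY_STORAGE_PER_LAI * lai_total)
    flux.interception_loss = interception
    throughfall = rain - interception + melt

    # infiltration into the top layer (may transiently exceed capacity)
    if water.size:
        water[0] += throughfall
    flux.infiltration = throughfall

    # radiation partition and per-species demand / uptake
    absorbed, soil_net = partition_radiation(solar, vegetation)
    flux.absorbed = absorbed
    transpiration = 0.0
    for veg in vegetation:
        demand = transpiration_demand(absorbed[veg.name], t_mean, veg.r_can)
        occ = (occupancy or {}).get(veg.name)
        if occ is None:
            occ = root_occupancy(veg, profile)
        wilting = np.array([l.wilting_mm(veg.name) for l in profile])
        available = water - wilting
        actual, extraction = actual_transpiration(demand, available, occ)
        water -= extraction
        transpiration += actual
        flux.demand[veg.name] = demand
        flux.actual[veg.name] = actual
        flux.tdi[veg.name] = compute_tdi(demand, actual)

    # soil evaporation from the humus layer, suppressed under snow
    if snow <= 0.0 and water.size:
        cap0 = profile[0].capacity_mm
        rel = min(1.0, max(0.0, water[0] / cap0)) if cap0 > 0 else 0.0
        pet_soil = priestley_taylor_pet(soil_net, t_mean)
        evap = min(water[0], pet_soil * (1.0 - math.exp(-SOIL_EVAP_SHAPE * rel)))
        water[0] -= evap
        flux.soil_evaporation = evap

    # drainage cascade: excess above field capacity moves down and out
    drainage = 0.0
    for i, layer in enumerate(profile):
        excess = water[i] - layer.capacity_mm
        if excess > 0.0:
            water[i] = layer.capacity_mm
            if i + 1 < len(profile):
                water[i + 1] += excess
            else:
                drainage = excess
    flux.drainage = drainage

    new_state = WaterState(snow, 0.0, water)
    flux.balance_residual = (
        precip - (new_state.total() - storage_before)
        - flux.interception_loss - transpiration - flux.soil_evaporation - drainage
    )
    return new_state, flux
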