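"""Simplified annual stand growth engine with drought mortality.

This is a deliberately minimal light- and nutrient-limited growth core:
annual base growth per species is absorbed growing-season shortwave
times a radiation-use-efficiency parameter, down-regulated by a Liebig
nitrogen modifier.  Climate-limited growth is split by fixed allocation
fractions among foliage, sapwood, branches, fine roots and coarse roots;
per-pool turnover fractions generate litter cohorts.  The engine is
isolated behind :func:`base_growth_rate` so a richer calibrated growth
model could be swapped in without touching the climate machinery.

Drought mortality follows a species response curve of the two-year
running mean of the growing-season transpiration deficit index, so two
consecutive dry years kill more trees than an isolated one.  Mortality
removes stems and biomass proportionally and routes the dead biomass to
litter (foliage and fine roots to fast types, wood to slow snag types),
which lowers leaf area and hence next year's canopy water demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .curves import ResponseCurve, eval_curve
from .decomposition import LitterCohort

BIOMASS_POOLS = ("foliage", "sapwood", "branches", "fine_roots", "coarse_roots")

#: litter type each biomass pool becomes at turnover or death, and the
#: DRI layer in which that litter decomposes
LITTER_ROUTING = {
    "foliage": ("foliage_litter", "litter"),
    "sapwood": ("stem_snag", "litter"),
    "branches": ("branch_litter", "litter"),
    "fine_roots": ("fine_root_litter", "mineral_a"),
    "coarse_roots": ("coarse_root_litter", "mineral_a"),
}


@dataclass(frozen=True)
class SpeciesGrowthParams:
    """Growth, allocation and mortality parameters for one species."""

    name: str
    sla: float                       # specific leaf area, m2 per kg foliage
    rue: float                       # g dry matter per MJ absorbed shortwave
    allocation: dict[str, float]     # fractions over BIOMASS_POOLS, sum to 1
    turnover: dict[str, float]       # annual fractions per pool
    n_concentration: dict[str, float]  # kg N per ton biomass, per pool
    litter_bdr: dict[str, float]     # base decomposition rate per litter type
    mortality_curve: ResponseCurve   # 2-y mean TDI -> annual mortality fraction
    background_mortality: float = 0.005

    def __post_init__(self):
        total = sum(self.allocation.get(p, 0.0) for p in BIOMASS_POOLS)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: allocation fractions sum to {total}, not 1")
        for p in BIOMASS_POOLS:
            if not (0.0 <= self.turnover.get(p, 0.0) <= 1.0):
                raise ValueError(f"{self.name}: turnover fraction outside [0, 1]")
        if not (0.0 <= self.background_mortality < 1.0):
            raise ValueError(f"{self.name}: background mortality outside [0, 1)")

    @property
    def n_per_ton_growth(self) -> float:
        """Nitrogen demand of one ton of new growth (kg N)."""
        return sum(self.allocation.get(p, 0.0) * self.n_concentration.get(p, 0.0)
                   for p in BIOMASS_POOLS)


@dataclass
class SpeciesPools:
    """Live biomass pools (tons ha-1) and stem density for one species."""

    species: str
    pools: dict[str, float]
    stems: float

    def __post_init__(self):
        for p in BIOMASS_POOLS:
            self.pools.setdefault(p, 0.0)
            if self.pools[p] < 0:
                raise ValueError(f"negative {p} biomass")
        if self.stems < 0:
            raise ValueError("negative stem density")

    @property
    def total(self) -> float:
        return sum(self.pools[p] for p in BIOMASS_POOLS)

    def lai(self, params: SpeciesGrowthParams) -> float:
        """Leaf area index; 1 t/ha of foliage is 0.1 kg/m2."""
        return self.pools["foliage"] * 0.1 * params.sla

    def nitrogen(self, params: SpeciesGrowthParams) -> float:
        """Live nitrogen content (kg ha-1) at the per-pool concentrations."""
        return sum(self.pools[p] * params.n_concentration.get(p, 0.0)
                   for p in BIOMASS_POOLS)


@dataclass
class StandState:
    """Whole-stand state: per-species pools, age, and TDI history."""

    species: dict[str, SpeciesPools]
    age: int = 1
    available_n: float = 0.0            # kg ha-1 mineral N pool
    tdi_history: dict[str, list[float]] = field(default_factory=dict)


def base_growth_rate(absorbed_mj_m2: float, available_n: float,
                     params: SpeciesGrowthParams) -> float:
    """Light- and nutrient-limited base annual growth (tons ha-1).

    The light-limited potential is absorbed growing-season shortwave
    (MJ m-2) times the radiation-use efficiency (g DM per MJ), converted
    to tons ha-1; the nitrogen modifier is ``min(1, supply / demand)``
    with demand evaluated at the light-limited potential.
    """
    if absorbed_mj_m2 < 0 or available_n < 0:
        raise ValueError("invalid inputs")
    light_potential = params.rue * absorbed_mj_m2 / 100.0  # g/m2 -> t/ha
    if light_potential <= 0:
        return 0.0
    n_demand = light_potential * params.n_per_ton_growth
    modifier = 1.0 if n_demand <= 0 else min(1.0, available_n / n_demand)
    return light_potential * modifier


def _cohorts_from(species: str, masses: dict[str, float],
                  params: SpeciesGrowthParams) -> list[LitterCohort]:
    cohorts = []
    for pool, mass in masses.items():
        if mass <= 0:
            continue
        litter_type, layer = LITTER_ROUTING[pool]
        cohorts.append(LitterCohort(
            litter_type=f"{species}:{litter_type}",
            layer=layer,
            mass_original=mass,
            mass=mass,
            nitrogen=mass * params.n_concentration.get(pool, 0.0),
            bdr=params.litter_bdr[litter_type],
        ))
    return cohorts


def allocate_and_turnover(state: SpeciesPools, cgr: float,
                          params: SpeciesGrowthParams
                          ) -> tuple[SpeciesPools, list[LitterCohort]]:
    """Distribute one year's growth and shed turnover litter.

    New growth is split by the fixed allocation fractions; each pool then
    loses its turnover fraction as a fresh litter cohort.  Biomass is
    conserved: the pool change equals growth minus litterfall.
    """
    if cgr < 0:
        raise ValueError("climate-limited growth must be >= 0")
    pools = dict(state.pools)
    litter_masses = {}
    for p in BIOMASS_POOLS:
        pools[p] += params.allocation.get(p, 0.0) * cgr
        shed = pools[p] * params.turnover.get(p, 0.0)
        pools[p] -= shed
        if shed > 0:
            litter_masses[p] = shed
    cohorts = _cohorts_from(state.species, litter_masses, params)
    return replace(state, pools=pools), cohorts


def drought_mortality(state: SpeciesPools, tdi_running_mean: float,
                      params: SpeciesGrowthParams
                      ) -> tuple[SpeciesPools, float, list[LitterCohort]]:
    """Apply annual drought (plus background) mortality to one species.

    The drought fraction comes from the species mortality curve
    evaluated at the two-year running mean growing-season TDI; the
    background rate adds independently.  Stems and every biomass pool
    shrink by the combined fraction and the dead biomass becomes litter.
    """
    if not 0.0 <= tdi_running_mean <= 1.0:
        raise ValueError("TDI running mean outside [0, 1]")
    drought = eval_curve(params.mortality_curve, tdi_running_mean)
    fraction = min(1.0, 1.0 - (1.0 - drought) * (1.0 - params.background_mortality))
    pools = {p: state.pools[p] * (1.0 - fraction) for p in BIOMASS_POOLS}
    dead = {p: state.pools[p] * fraction for p in BIOMASS_POOLS}
    cohorts = _cohorts_from(state.species, dead, params)
    survivor = replace(state, pools=pools, stems=state.stems * (1.0 - fraction))
    return survivor, fraction, cohorts


def sapwood_index(increments) -> np.ndarray:
    """Normalized two-year-average sapwood production index.

    Ring growth draws on both the previous and the current year's
    carbohydrates, so each year is represented by the mean of its own
    and the preceding year's sapwood increment; the resulting series is
    normalized by its mean (scale invariant, mean exactly 1).
    """
    arr = np.asarray(increments, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least two annual increments")
    two_year = 0.5 * (arr[:-1] + arr[1:])
    mean = two_year.mean()
    if mean == 0:
        raise ValueError("zero-mean increment series cannot be normalized")
    return two_year / mean
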