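"""Litter-cohort and humus decomposition with climate modifiers.

Dead biomass enters independent litter cohorts at tissue death; each
cohort loses mass at a base annual rate (BDR, a property of litter
quality) modified by an annual climate decomposition factor (CDF).  The
CDF is built exactly like the growth factor: a daily decomposition
response index per soil layer,

    DRI = T_decomp(air temperature) * M_decomp(relative water content),

is summed annually, normalized against the reference climate (NDRI), and
expressed as a signed relative anomaly.  The temperature response is a
Q10 = 2 exponential anchored to 1.0 at 25 degC (capped there); the
moisture responses are piecewise-linear curves, distinct for litter,
humus and mineral soil.

When a cohort's remaining mass falls to 15-20 % of its original mass
(default threshold 17.5 %) the residual mass and nitrogen transfer to
the active and passive humus pools, whose mean residence times under a
neutral climate are 50 and 600 years respectively.  Nitrogen is released
in proportion to mass loss throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .curves import ResponseCurve, eval_curve

Q10_DEFAULT = 2.0
Q10_REFERENCE_TEMP = 25.0     # degC at which the temperature response caps at 1
TRANSFER_THRESHOLD = 0.175    # fraction of original mass remaining
ACTIVE_HUMUS_FRACTION = 0.8   # share of transferred litter entering the active pool
ACTIVE_RESIDENCE_YEARS = 50.0
PASSIVE_RESIDENCE_YEARS = 600.0


@dataclass(frozen=True)
class LitterCohort:
    """One litter cohort: a litter type's input from a single year."""

    litter_type: str
    layer: str                  # DRI layer the cohort decomposes under
    mass_original: float        # tons ha-1
    mass: float                 # tons ha-1 remaining
    nitrogen: float             # kg ha-1 remaining
    bdr: float                  # base annual mass-loss fraction

    def __post_init__(self):
        if not (0.0 <= self.mass <= self.mass_original):
            raise ValueError("cohort mass outside [0, original]")
        if self.nitrogen < 0:
            raise ValueError("negative cohort nitrogen")
        if not (0.0 < self.bdr <= 1.0):
            raise ValueError("base decomposition rate outside (0, 1]")


@dataclass(frozen=True)
class HumusPool:
    """Active or passive humus: slow pools fed by exhausted litter cohorts."""

    kind: str                   # "active" | "passive"
    mass: float                 # tons ha-1
    nitrogen: float             # kg ha-1
    residence_time: float       # years, mean under neutral climate
    layer: str = "humus"

    def __post_init__(self):
        if self.mass < 0 or self.nitrogen < 0 or self.residence_time <= 0:
            raise ValueError("invalid humus pool")


@dataclass(frozen=True)
class DecompNormalization:
    """Per-layer reference-climate decomposition baselines."""

    ndri: dict[str, float]
    n_years: int

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("need at least one reference year")
        for layer, v in self.ndri.items():
            if v <= 0:
                raise ValueError(f"NDRI for layer {layer!r} must be > 0")


def temp_decomp_response(t_mean: float, q10: float = Q10_DEFAULT,
                         t_ref: float = Q10_REFERENCE_TEMP) -> float:
    """Temperature response of decomposition, a capped Q10 exponential.

    ``min(1, q10 ** ((t - t_ref) / 10))``: anchored to 1.0 at the
    reference temperature (25 degC) and halving per 10 degC of cooling,
    so the ratio of responses 10 degC apart equals q10 wherever the cap
    is inactive.  Near 0 for frozen conditions.
    """
    if not q10 > 1:
        raise ValueError("q10 must be > 1")
    return min(1.0, q10 ** ((t_mean - t_ref) / 10.0))


def moisture_decomp_response(rel_water: float, curve: ResponseCurve) -> float:
    """Moisture response: the layer-kind curve at relative water content.

    ``rel_water`` is the layer's water content as a fraction of its field
    capacity, in [0, 1]; curves rise from near zero when dry to a
    plateau of 1 near field capacity.
    """
    if not 0.0 <= rel_water <= 1.0 + 1e-9:
        raise ValueError("relative water content outside [0, 1]")
    return eval_curve(curve, rel_water)


def daily_decomp_index(t_mean: float, rel_water: float, curve: ResponseCurve,
                       q10: float = Q10_DEFAULT,
                       t_ref: float = Q10_REFERENCE_TEMP) -> float:
    """DRI for one layer and day: temperature times moisture response."""
    return temp_decomp_response(t_mean, q10, t_ref) * moisture_decomp_response(rel_water, curve)


def normalize_decomp(annual_by_layer: dict[str, "np.ndarray | list"]) -> DecompNormalization:
    """Per-layer mean of annual summed DRI over the reference years."""
    ndri = {}
    n_years = None
    for layer, values in annual_by_layer.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 1:
            raise ValueError("need at least one reference year")
        if n_years is None:
            n_years = int(arr.size)
        ndri[layer] = float(np.mean(arr))
    return DecompNormalization(ndri=ndri, n_years=n_years or 0)


def climate_decomp_factor(dri_year: float, ndri: float) -> float:
    """Signed relative decomposition anomaly of one year vs the baseline."""
    if ndri <= 0:
        raise ValueError("NDRI must be > 0")
    return (dri_year - ndri) / ndri


def step_litter_year(cohorts: list[LitterCohort], cdf_by_layer: dict[str, float],
                     transfer_threshold: float = TRANSFER_THRESHOLD,
                     active_fraction: float = ACTIVE_HUMUS_FRACTION,
                     ) -> tuple[list[LitterCohort], float, float, list[tuple[str, float, float]]]:
    """Decompose every litter cohort for one year.

    The effective annual loss rate is ``BDR * (1 + CDF)`` clamped to
    [0, 1] (mirroring the growth-side ``1 + CRF`` interpretation);
    nitrogen is released in proportion to mass loss.  Cohorts whose
    remaining mass reaches the transfer threshold move wholesale to
    humus, split ``active_fraction`` / ``1 - active_fraction`` between
    the active and passive pools.

    Returns ``(surviving cohorts, total mass loss, N release,
    humus transfers as (kind, mass, N))``.  Mass and nitrogen are
    conserved across the three outputs.
    """
    if not (0.0 < transfer_threshold < 1.0):
        raise ValueError("transfer threshold outside (0, 1)")
    if not (0.0 <= active_fraction <= 1.0):
        raise ValueError("active humus fraction outside [0, 1]")
    survivors: list[LitterCohort] = []
    transfers: list[tuple[str, float, float]] = []
    mass_loss = 0.0
    n_release = 0.0
    for cohort in cohorts:
        cdf = cdf_by_layer.get(cohort.layer, 0.0)
        rate = min(1.0, max(0.0, cohort.bdr * (1.0 + cdf)))
        dm = cohort.mass * rate
        dn = cohort.nitrogen * rate
        mass_loss += dm
        n_release += dn
        remaining = cohort.mass - dm
        n_remaining = cohort.nitrogen - dn
        if cohort.mass_original > 0 and remaining / cohort.mass_original <= transfer_threshold:
            if remaining > 0:
                transfers.append(("active", remaining * active_fraction,
                                  n_remaining * active_fraction))
                transfers.append(("passive", remaining * (1.0 - active_fraction),
                                  n_remaining * (1.0 - active_fraction)))
        elif remaining > 1e-12:
            survivors.append(replace(cohort, mass=remaining, nitrogen=n_remaining))
    return survivors, mass_loss, n_release, transfers


def step_humus_year(pools: list[HumusPool], cdf_by_layer: dict[str, float]
                    ) -> tuple[list[HumusPool], float, float]:
    """Decompose the humus pools for one year.

    The annual decay fraction is ``(1 / residence_time) * (1 + CDF)``
    clamped to [0, 1]; under a neutral climate (CDF = 0) the implied mean
    residence time equals the configured value exactly.  Returns
    ``(updated pools, mass loss, N release)``.
    """
    updated = []
    mass_loss = 0.0
    n_release = 0.0
    for pool in pools:
        cdf = cdf_by_layer.get(pool.layer, 0.0)
        frac = min(1.0, max(0.0, (1.0 / pool.residence_time) * (1.0 + cdf)))
        dm = pool.mass * frac
        dn = pool.nitrogen * frac
        mass_loss += dm
        n_release += dn
        updated.append(replace(pool, mass=pool.mass - dm, nitrogen=pool.nitrogen - dn))
    return updated, mass_loss, n_release


def add_humus_transfers(pools: list[HumusPool], transfers: list[tuple[str, float, float]]
                        ) -> list[HumusPool]:
    """Fold litter->humus transfers into the matching pools."""
    by_kind = {p.kind: p for p in pools}
    for kind, mass, nitrogen in transfers:
        pool = by_kind[kind]
        by_kind[kind] = replace(pool, mass=pool.mass + mass,
                                nitrogen=pool.nitrogen + nitrogen)
    return [by_kind[p.kind] for p in pools]
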