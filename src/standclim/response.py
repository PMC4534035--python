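"""Growth response indices and the climate response factor.

Daily growth potential is the product of two species-specific response
curves: a temperature response T_growth of daily mean air temperature
(dormancy break near 5 degC, a species-specific optimum, high-temperature
decline) and a water-stress response S_growth of the daily transpiration
deficit index.  Daily values are summed to an annual growth response
index (GRI); averaging GRI over a reference climate gives the
normalization NGRI, and each simulated year's climate anomaly is

    CRF = (GRI_year - NGRI) / NGRI,

a signed relative factor that is zero for an average reference year.
The annual light/nutrient-limited base growth rate is scaled by
``1 + CRF`` (floored at zero growth), so a stand under the average
reference climate grows at exactly its base rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import ResponseCurve, eval_curve

__all__ = [
    "ResponseCurve", "eval_curve", "daily_growth_index", "annual_growth_index",
    "normalize", "climate_response_factor", "climate_limited_growth",
    "growing_season_length", "Normalization",
]

DAYS_PER_YEAR = 365
TGROWTH_SEASON_THRESHOLD = 0.25


@dataclass(frozen=True)
class Normalization:
    """Reference-climate growth baseline for one species."""

    ngri: float
    n_years: int

    def __post_init__(self):
        if self.ngri <= 0:
            raise ValueError("NGRI must be > 0 (degenerate response curves?)")
        if self.n_years < 1:
            raise ValueError("need at least one reference year")


def daily_growth_index(t_mean: float, tdi: float, t_curve: ResponseCurve,
                       s_curve: ResponseCurve) -> float:
    """GRI for one day: T_growth(t_mean) * S_growth(TDI), in [0, 1]."""
    if not 0.0 <= tdi <= 1.0:
        raise ValueError("TDI outside [0, 1]")
    return eval_curve(t_curve, t_mean) * eval_curve(s_curve, tdi)


def annual_growth_index(daily_values) -> float:
    """Sum of the 365 daily growth indices of one year."""
    arr = np.asarray(daily_values, dtype=float)
    if arr.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"expected {DAYS_PER_YEAR} daily values, got {arr.shape}")
    return float(np.sum(arr))


def normalize(annual_indices) -> Normalization:
    """Mean annual growth index over the reference years (NGRI)."""
    arr = np.asarray(annual_indices, dtype=float)
    if arr.size < 1:
        raise ValueError("need at least one reference year")
    return Normalization(ngri=float(np.mean(arr)), n_years=int(arr.size))


def climate_response_factor(gri_year: float, ngri: float) -> float:
    """Signed relative growth anomaly of one year vs the reference mean."""
    if ngri <= 0:
        raise ValueError("NGRI must be > 0")
    return (gri_year - ngri) / ngri


def climate_limited_growth(bgr: float, crf: float) -> float:
    """Climate-limited growth rate: ``BGR * (1 + CRF)``, CRF floored at -1.

    The ``1 + CRF`` form makes an average reference-climate year
    reproduce the base growth rate exactly (CRF ~ 0 means "similar to
    the historical average year"); the floor keeps growth non-negative.
    """
    if bgr < 0:
        raise ValueError("base growth rate must be >= 0")
    return bgr * (1.0 + max(-1.0, crf))


def growing_season_length(daily_t_growth,
                          threshold: float = TGROWTH_SEASON_THRESHOLD) -> int:
    """Temperature-limited growing season length of one year (days).

    The number of calendar days whose temperature response index meets
    the threshold (default 0.25).
    """
    arr = np.asarray(daily_t_growth, dtype=float)
    if arr.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"expected {DAYS_PER_YEAR} daily values")
    return int(np.count_nonzero(arr >= threshold))
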