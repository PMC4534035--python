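"""Daily climate forcing: data model, I/O, solar estimation, scenarios.

A climate series is a table of daily meteorological forcing (mean/max/min
air temperature, precipitation, snow fraction, shortwave radiation) plus
the annual atmospheric CO2 concentration, carried on a fixed 365-day
calendar (Feb 29 is dropped on read) so that cycling a reference series
and day-index arithmetic are exact.

The module provides

* CSV read/write for the series,
* estimation of daily shortwave radiation from the diurnal temperature
  range (Bristow-Campbell model),
* cycling of a reference series to extend it (e.g. 30 y -> 150 y),
* delta-method scenario downscaling (monthly temperature offsets and
  precipitation ratios interpolated between anchor periods, applied to
  the cycled reference so its interannual variability is retained), and
* a stochastic generator producing a montane-interior synthetic climate
  (cold snowy winters, ~12.5 degC growing-season mean, summer-dry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Growing season window (May 1 - Sep 30 on the 365-day calendar).
GROWING_SEASON_DOYS = (121, 273)

#: Days in each month on the fixed 365-day calendar.
_MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
_MONTH_EDGES = np.concatenate([[0], np.cumsum(_MONTH_LENGTHS)])

#: month (1..12) for each day-of-year 1..365
DOY_MONTH = np.searchsorted(_MONTH_EDGES, np.arange(1, 366), side="left")

COLUMNS = ["year", "doy", "tmean", "tmax", "tmin", "precip", "snow_frac", "solar", "co2"]


def month_of_doy(doy):
    """Calendar month (1-12) of a day-of-year on the 365-day calendar."""
    return DOY_MONTH[np.asarray(doy, int) - 1]


def snow_fraction_from_temperature(t_mean):
    """Linear ramp: all snow at or below 0 degC, all rain at or above +2 degC."""
    return np.clip(1.0 - np.asarray(t_mean, float) / 2.0, 0.0, 1.0)


@dataclass(frozen=True)
class DailyClimateRecord:
    """One day of meteorological forcing plus the year's CO2 (ppm)."""

    year: int
    doy: int
    t_mean: float
    t_max: float
    t_min: float
    precip: float
    snow_fraction: float
    solar: float
    co2: float

    def __post_init__(self):
        if not (self.t_min <= self.t_mean <= self.t_max):
            raise ValueError("temperature ordering t_min <= t_mean <= t_max violated")
        if self.precip < 0 or not (0.0 <= self.snow_fraction <= 1.0):
            raise ValueError("invalid precipitation or snow fraction")
        if self.solar < 0 or self.co2 <= 0:
            raise ValueError("invalid solar radiation or CO2")


@dataclass
class ClimateSeries:
    """An ordered multi-year daily climate table on a 365-day calendar.

    ``data`` holds one row per day with columns ``year, doy, tmean, tmax,
    tmin, precip, snow_frac, solar, co2``.  Site metadata rides along for
    radiation estimation.
    """

    data: pd.DataFrame
    latitude: float = 50.9
    elevation: float = 1160.0
    slope: float = 0.0
    aspect: float = 0.0

    def __post_init__(self):
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"climate table missing columns: {missing}")
        if len(df) == 0:
            raise ValueError("empty climate series")
        if len(df) % 365 != 0:
            raise ValueError("climate series must contain whole 365-day years")
        expect_doy = np.tile(np.arange(1, 366), len(df) // 365)
        if not np.array_equal(df["doy"].to_numpy(), expect_doy):
            raise ValueError("climate series has date gaps or misordered days")
        years = df["year"].to_numpy()[::365]
        if len(years) > 1 and not np.all(np.diff(years) == 1):
            raise ValueError("years must increase by 1")
        self.data = df.reset_index(drop=True)

    @property
    def n_years(self) -> int:
        return len(self.data) // 365

    @property
    def start_year(self) -> int:
        return int(self.data["year"].iloc[0])

    def year(self, index: int) -> pd.DataFrame:
        """The 365-row block of the index-th simulated year (0-based)."""
        return self.data.iloc[index * 365 : (index + 1) * 365]

    def iter_records(self):
        for row in self.data.itertuples(index=False):
            yield DailyClimateRecord(
                int(row.year), int(row.doy), row.tmean, row.tmax, row.tmin,
                row.precip, row.snow_frac, row.solar, row.co2,
            )

    # -- I/O ------------------------------------------------------------

    def to_csv(self, path) -> None:
        df = self.data.copy()
        df.insert(0, "date", _doy_to_date(df["year"], df["doy"]))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, latitude: float = 50.9, elevation: float = 1160.0,
                 co2: float | None = None) -> "ClimateSeries":
        """Read a headered daily climate CSV.

        Accepts either explicit ``year``/``doy`` columns or a ``date``
        column (Feb 29 rows are dropped).  ``snow_frac`` is derived from
        ``tmean`` when absent; a constant ``co2`` may be supplied when the
        file has no CO2 column.
        """
        df = pd.read_csv(path)
        if "year" not in df.columns or "doy" not in df.columns:
            if "date" not in df.columns:
                raise ValueError("climate CSV needs either year/doy or a date column")
            dates = pd.to_datetime(df["date"])
            keep = ~((dates.dt.month == 2) & (dates.dt.day == 29))
            df = df.loc[keep].reset_index(drop=True)
            dates = dates[keep]
            df["year"] = dates.dt.year.to_numpy()
            month = dates.dt.month.to_numpy()
            day = dates.dt.day.to_numpy()
            df["doy"] = _MONTH_EDGES[month - 1] + day
        if "snow_frac" not in df.columns:
            df["snow_frac"] = snow_fraction_from_temperature(df["tmean"])
        if "co2" not in df.columns:
            if co2 is None:
                raise ValueError("climate CSV has no co2 column and no constant given")
            df["co2"] = co2
        return cls(df[COLUMNS].copy(), latitude=latitude, elevation=elevation)


def _doy_to_date(year, doy):
    month = month_of_doy(doy)
    day = np.asarray(doy, int) - _MONTH_EDGES[month - 1]
    return [f"{y:04d}-{m:02d}-{d:02d}" for y, m, d in zip(np.asarray(year, int), month, day)]


# -- solar radiation ----------------------------------------------------

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1


def extraterrestrial_radiation(latitude: float, day_of_year: int) -> float:
    """Daily top-of-atmosphere shortwave radiation (MJ m-2 day-1).

    Standard solar-geometry closed form (inverse relative Earth-Sun
    distance, solar declination, sunset hour angle).
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude outside [-90, 90]")
    if not 1 <= day_of_year <= 366:
        raise ValueError("day_of_year outside [1, 366]")
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * math.cos(2.0 * math.pi * day_of_year / 365.0)
    delta = 0.409 * math.sin(2.0 * math.pi * day_of_year / 365.0 - 1.39)
    cos_ws = -math.tan(phi) * math.tan(delta)
    ws = math.acos(min(1.0, max(-1.0, cos_ws)))
    ra = (24.0 * 60.0 / math.pi) * _SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * math.sin(delta)
        + math.cos(phi) * math.cos(delta) * math.sin(ws)
    )
    return max(0.0, ra)


def estimate_solar(t_max: float, t_min: float, latitude: float, elevation: float,
                   day_of_year: int, a: float = 0.7, b: float = 0.005,
                   c: float = 2.4) -> float:
    """Estimate daily shortwave radiation from the diurnal temperature range.

    Bristow-Campbell model: atmospheric transmissivity
    ``tau = a * (1 - exp(-b * dT**c))`` applied to the extraterrestrial
    radiation for the latitude and day.  A large diurnal range signals
    clear skies; a zero range gives the model's minimum transmissivity
    (zero).  Default coefficients a=0.7, b=0.005, c=2.4 are the commonly
    used mid-latitude values; ``a`` is the clear-sky ceiling.
    """
    if not (math.isfinite(t_max) and math.isfinite(t_min)):
        raise ValueError("non-finite temperatures")
    if t_max < t_min:
        raise ValueError("t_max < t_min")
    del elevation  # site pressure effects not represented in this form
    ra = extraterrestrial_radiation(latitude, day_of_year)
    dt = t_max - t_min
    tau = a * (1.0 - math.exp(-b * dt**c)) if dt > 0 else 0.0
    return tau * ra


# -- reference cycling and scenario downscaling -------------------------


def cycle_reference(series: ClimateSeries, n_cycles: int) -> ClimateSeries:
    """Repeat a reference series end-to-end, relabelling years sequentially.

    A 30-year reference with ``n_cycles=5`` yields 150 years of daily
    data; every cycle reproduces the input day for day.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if len(series.data) == 0:
        raise ValueError("empty series")
    df = pd.concat([series.data] * n_cycles, ignore_index=True)
    df["year"] = series.start_year + np.repeat(
        np.arange(series.n_years * n_cycles), 365
    )
    return replace(series, data=df)


@dataclass
class ScenarioDeltas:
    """Monthly climate-change anomalies for a set of future anchor periods.

    ``anchors`` maps an anchor year (e.g. 2025 for "the 2020s") to a pair
    of 12-vectors: additive monthly temperature offsets (degC) and
    multiplicative monthly precipitation ratios.  ``co2`` maps years to
    an annual CO2 concentration (ppm); it is linearly interpolated.
    """

    anchors: dict[int, tuple[np.ndarray, np.ndarray]]
    co2: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        cleaned = {}
        for year, (off, ratio) in sorted(self.anchors.items()):
            off = np.asarray(off, float)
            ratio = np.asarray(ratio, float)
            if off.shape != (12,) or ratio.shape != (12,):
                raise ValueError("each anchor needs 12 offsets and 12 ratios")
            if np.any(ratio <= 0):
                raise ValueError("precipitation ratios must be > 0")
            cleaned[int(year)] = (off, ratio)
        self.anchors = cleaned

    def interpolate(self, year: float) -> tuple[np.ndarray, np.ndarray]:
        """Monthly offsets/ratios for one calendar year.

        Piecewise-linear on the year axis between anchors, constant
        beyond the first/last anchor.  A scenario that should ramp up
        from present-day conditions must therefore include an explicit
        present-day anchor with zero offsets and unit ratios.
        """
        years = np.array(sorted(self.anchors))
        offs = np.stack([self.anchors[y][0] for y in years])
        rats = np.stack([self.anchors[y][1] for y in years])
        off = np.array([np.interp(year, years, offs[:, m]) for m in range(12)])
        rat = np.array([np.interp(year, years, rats[:, m]) for m in range(12)])
        return off, rat

    def co2_at(self, year: float, default: float) -> float:
        if not self.co2:
            return default
        years = np.array(sorted(self.co2))
        vals = np.array([self.co2[y] for y in years])
        return float(np.interp(year, years, vals))


def downscale_direct(reference: ClimateSeries, deltas: ScenarioDeltas,
                     horizon_years: int, start_year: int | None = None,
                     reference_co2: float = 380.0) -> ClimateSeries:
    """Delta-method downscaling of monthly anomalies onto a daily reference.

    The reference series is cycled to cover ``horizon_years``; each output
    day gets the linearly interpolated monthly temperature offset added
    and its precipitation multiplied by the interpolated monthly ratio.
    Because the perturbation is applied to observed days, the interannual
    variability of the reference is retained.  CO2 follows the scenario
    trajectory (falling back to ``reference_co2``).
    """
    if horizon_years < 1:
        raise ValueError("horizon must cover at least 1 year")
    if reference.n_years < 1:
        raise ValueError("reference must span at least one full year")
    n_cycles = -(-horizon_years // reference.n_years)  # ceil
    cycled = cycle_reference(reference, n_cycles)
    df = cycled.data.iloc[: horizon_years * 365].copy().reset_index(drop=True)
    if start_year is None:
        start_year = reference.start_year
    df["year"] = start_year + np.repeat(np.arange(horizon_years), 365)

    month_idx = month_of_doy(df["doy"].to_numpy()) - 1
    offsets = np.empty(len(df))
    ratios = np.empty(len(df))
    co2 = np.empty(len(df))
    for iy in range(horizon_years):
        yr = start_year + iy
        off, rat = deltas.interpolate(yr)
        sl = slice(iy * 365, (iy + 1) * 365)
        offsets[sl] = off[month_idx[sl]]
        ratios[sl] = rat[month_idx[sl]]
        co2[sl] = deltas.co2_at(yr, reference_co2)

    for col in ("tmean", "tmax", "tmin"):
        df[col] = df[col].to_numpy() + offsets
    df["precip"] = df["precip"].to_numpy() * ratios
    df["snow_frac"] = snow_fraction_from_temperature(df["tmean"])
    df["co2"] = co2
    return replace(cycled, data=df)


# -- synthetic climate generator ----------------------------------------


@dataclass
class SyntheticClimateParams:
    """Descriptors of the synthetic montane-interior climate.

    Defaults target a high-elevation southern-interior British Columbia
    station: annual mean near 3.6 degC with a 12 degC seasonal amplitude
    (growing-season May-Sep mean ~12.5 degC), snowy winters and a
    relatively dry summer, ~450 mm annual precipitation.
    """

    t_annual_mean: float = 3.6       # degC
    t_amplitude: float = 12.0        # degC, seasonal half-range
    t_peak_doy: int = 200            # warmest day of year
    t_noise_sd: float = 3.0          # degC, daily AR(1) anomaly
    t_noise_ar1: float = 0.7
    diurnal_range_mean: float = 9.0  # degC
    diurnal_range_amplitude: float = 3.0  # larger range in summer
    wet_prob_winter: float = 0.45
    wet_prob_summer: float = 0.28
    wet_day_mean_winter: float = 3.8  # mm, mean wet-day amount
    wet_day_mean_summer: float = 3.2
    co2: float = 380.0               # ppm, constant reference level
    start_year: int = 1975


def generate_synthetic_climate(params: SyntheticClimateParams, years: int,
                               seed: int, latitude: float = 50.9,
                               elevation: float = 1160.0) -> ClimateSeries:
    """Generate a reproducible synthetic daily climate series.

    Temperature is a sinusoidal seasonal cycle plus an AR(1) daily
    anomaly; precipitation is a seasonal occurrence probability times an
    exponential wet-day amount; snow fraction follows the 0-2 degC ramp;
    solar radiation is estimated from the diurnal range
    (:func:`estimate_solar`).
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    rng = np.random.default_rng(seed)
    n = years * 365
    doy = np.tile(np.arange(1, 366), years)
    phase = 2.0 * np.pi * (doy - params.t_peak_doy) / 365.0

    seasonal = params.t_annual_mean + params.t_amplitude * np.cos(phase)
    noise = np.empty(n)
    eps = rng.normal(0.0, 1.0, n)
    innov_sd = params.t_noise_sd * math.sqrt(max(1e-12, 1.0 - params.t_noise_ar1**2))
    prev = 0.0
    for i in range(n):
        prev = params.t_noise_ar1 * prev + innov_sd * eps[i]
        noise[i] = prev
    if params.t_noise_sd == 0:
        noise[:] = 0.0
    tmean = seasonal + noise

    drange = np.maximum(
        0.5, params.diurnal_range_mean + params.diurnal_range_amplitude * np.cos(phase)
    )
    tmax = tmean + 0.5 * drange
    tmin = tmean - 0.5 * drange

    # summer-dry seasonality: winter peak occurrence/amount
    wetness = 0.5 * (1.0 - np.cos(phase))  # 0 at t_peak_doy, 1 midwinter
    wet_prob = params.wet_prob_summer + (params.wet_prob_winter - params.wet_prob_summer) * wetness
    wet_mean = params.wet_day_mean_summer + (
        params.wet_day_mean_winter - params.wet_day_mean_summer
    ) * wetness
    wet = rng.random(n) < wet_prob
    amounts = rng.exponential(1.0, n) * wet_mean
    precip = np.where(wet, amounts, 0.0)

    solar = np.array([
        estimate_solar(tx, tn, latitude, elevation, int(d))
        for tx, tn, d in zip(tmax, tmin, doy)
    ])

    df = pd.DataFrame({
        "year": params.start_year + np.repeat(np.arange(years), 365),
        "doy": doy,
        "tmean": tmean,
        "tmax": tmax,
        "tmin": tmin,
        "precip": precip,
        "snow_frac": snow_fraction_from_temperature(tmean),
        "solar": solar,
        "co2": np.full(n, params.co2),
    })
    return ClimateSeries(df, latitude=latitude, elevation=elevation)


def growing_season_mean_temperature(series: ClimateSeries) -> float:
    """Mean of May-Sep daily mean temperature over the whole series."""
    lo, hi = GROWING_SEASON_DOYS
    df = series.data
    mask = (df["doy"] >= lo) & (df["doy"] <= hi)
    return float(df.loc[mask, "tmean"].mean())
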