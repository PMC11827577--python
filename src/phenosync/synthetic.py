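"""Simulators for weather, NDVI, DEM and occurrence inputs with known truth.

Every generator is a pure function of its configuration and seed, and every
generator hands back the planted ground truth next to the data so downstream
tests never have to re-derive it.

Conventions
-----------
* Cells live on an abstract projected plane with kilometre units; cell ``i``
  occupies the 10 km square ``[10*i, 10*(i+1)) x [0, 10)`` and has its centre
  at ``(10*i + 5, 5)``.
* The seasonal temperature harmonic uses a 364-day period with its peak on an
  integer day-of-year, so daily sampling attains the exact annual extremes
  (range = 2 * seasonal_amplitude without discretisation error).
* Precipitation is wet-day thinned: Bernoulli(wet_day_prob) times an
  exponential with mean ``precip_rate / wet_day_prob``, so the long-run mean
  equals ``precip_rate``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from datetime import date as Date

import numpy as np
import pandas as pd
from scipy.special import expit

from phenosync.errors import CoverageError, InvalidConfigError

_PEAK_DOY = 183          # seasonal maximum (early July)
_SEASONAL_PERIOD = 364.0 # so day 1 and day 365 sit exactly at the trough
_DIURNAL_PEAK_HOUR = 15  # warmest hour of the day

VALID_VARIABLES = ("tmin", "tmax", "tppt")


@dataclass(frozen=True)
class WeatherSimConfig:
    """Configuration for the gridded weather simulator."""

    n_cells: int
    date_start: Date
    date_end: Date
    mean_temp_annual: float = 10.0
    seasonal_amplitude: float = 8.0
    diurnal_amplitude: float = 4.0
    precip_rate: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0
    wet_day_prob: float = 0.4

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise InvalidConfigError(f"n_cells must be positive, got {self.n_cells}")
        if self.date_start >= self.date_end:
            raise InvalidConfigError(
                f"date_start {self.date_start} must precede date_end {self.date_end}"
            )
        if self.seasonal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise InvalidConfigError("amplitudes must be non-negative")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if not 0 < self.wet_day_prob <= 1:
            raise InvalidConfigError("wet_day_prob must be in (0, 1]")


@dataclass(frozen=True)
class PlantedWindow:
    """Ground-truth weather window linking aggregated weather to event dates.

    ``open_days``/``close_days`` count days before the event, open further in
    the past, matching the convention of the window-analysis engine.
    """

    variable: str
    open_days: int
    close_days: int
    slope: float
    intercept: float
    residual_sd: float = 0.0
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.variable not in VALID_VARIABLES:
            raise InvalidConfigError(f"variable must be one of {VALID_VARIABLES}")
        if not 0 <= self.close_days <= self.open_days <= 180:
            raise InvalidConfigError(
                "need 0 <= close_days <= open_days <= 180, got "
                f"open={self.open_days} close={self.close_days}"
            )
        if self.residual_sd < 0:
            raise InvalidConfigError("residual_sd must be non-negative")


@dataclass(frozen=True)
class SimResult:
    """A simulated table plus the ground truth that generated it."""

    frame: pd.DataFrame
    truth: dict


def _seasonal_temp(doy: np.ndarray, mean: float, amplitude: float) -> np.ndarray:
    return mean + amplitude * np.cos(2.0 * np.pi * (doy - _PEAK_DOY) / _SEASONAL_PERIOD)


def cell_centres(n_cells: int) -> pd.DataFrame:
    """Cell-centre coordinates for the abstract 10 km grid layout.

    Cell ids use the same ``"<col>_<row>"`` convention produced by 10 km
    gridding of occurrence coordinates, so simulated weather is directly
    joinable to gridded events.
    """
    ids = np.arange(n_cells)
    return pd.DataFrame(
        {
            "cell_id": [f"{i}_0" for i in ids],
            "x_km": 10.0 * ids + 5.0,
            "y_km": np.full(n_cells, 5.0),
        }
    )


def _parse_cell(cell_id: str) -> tuple[int, int]:
    try:
        a, b = str(cell_id).split("_")
        return int(a), int(b)
    except ValueError as exc:
        raise InvalidConfigError(
            f"cell_id {cell_id!r} does not follow the '<col>_<row>' convention"
        ) from exc


def gen_weather(config: WeatherSimConfig, granularity: str = "daily") -> SimResult:
    """Simulate a gridded weather table at hourly or daily granularity.

    Daily output has columns ``cell_id, date, tmax, tmin, tppt``; hourly
    output has ``cell_id, timestamp, temp_c, precip_mm`` with UTC timestamps,
    matching the CSV dialect consumed by :mod:`phenosync.weather`.
    """
    if granularity not in ("hourly", "daily"):
        raise InvalidConfigError(f"granularity must be hourly or daily, got {granularity!r}")
    rng = np.random.default_rng(config.seed)
    days = pd.date_range(config.date_start, config.date_end, freq="D")
    n_days = len(days)
    doy = days.dayofyear.to_numpy(dtype=float)

    if granularity == "daily":
        centre = _seasonal_temp(doy, config.mean_temp_annual, config.seasonal_amplitude)
        rows = []
        for cell in range(config.n_cells):
            cell_id = f"{cell}_0"
            # one synoptic anomaly per (cell, day), shared by tmax and tmin so
            # the diurnal range (and tmax >= tmin) is preserved under noise
            anomaly = rng.normal(0.0, config.noise_sd, n_days) if config.noise_sd else 0.0
            tmax = centre + config.diurnal_amplitude + anomaly
            tmin = centre - config.diurnal_amplitude + anomaly
            wet = rng.random(n_days) < config.wet_day_prob
            tppt = np.where(
                wet, rng.exponential(config.precip_rate / config.wet_day_prob, n_days), 0.0
            )
            rows.append(
                pd.DataFrame(
                    {"cell_id": cell_id, "date": days, "tmax": tmax, "tmin": tmin, "tppt": tppt}
                )
            )
        frame = pd.concat(rows, ignore_index=True)
    else:
        stamps = pd.date_range(
            pd.Timestamp(config.date_start),
            pd.Timestamp(config.date_end) + pd.Timedelta(hours=23),
            freq="h",
            tz="UTC",
        )
        frac_doy = stamps.dayofyear.to_numpy(dtype=float) + stamps.hour.to_numpy() / 24.0
        seasonal = _seasonal_temp(frac_doy, config.mean_temp_annual, config.seasonal_amplitude)
        diurnal = config.diurnal_amplitude * np.cos(
            2.0 * np.pi * (stamps.hour.to_numpy() - _DIURNAL_PEAK_HOUR) / 24.0
        )
        n = len(stamps)
        rows = []
        hourly_rate = config.precip_rate / 24.0
        for cell in range(config.n_cells):
            cell_id = f"{cell}_0"
            noise = rng.normal(0.0, config.noise_sd, n) if config.noise_sd else 0.0
            temp = seasonal + diurnal + noise
            wet = rng.random(n) < config.wet_day_prob
            precip = np.where(
                wet, rng.exponential(hourly_rate / config.wet_day_prob, n), 0.0
            )
            rows.append(
                pd.DataFrame(
                    {"cell_id": cell_id, "timestamp": stamps, "temp_c": temp, "precip_mm": precip}
                )
            )
        frame = pd.concat(rows, ignore_index=True)

    truth = {
        "config": dataclasses.asdict(config),
        "granularity": granularity,
        "cells": cell_centres(config.n_cells),
    }
    return SimResult(frame=frame, truth=truth)


def gen_dem(
    n_points: int,
    extent_km: tuple[float, float, float, float],
    seed: int = 0,
    base_elev: float = 80.0,
    relief: float = 120.0,
) -> SimResult:
    """Scatter DEM sample points with smoothly varying elevation over an extent."""
    if n_points <= 0:
        raise InvalidConfigError("n_points must be positive")
    x0, x1, y0, y1 = extent_km
    if x0 >= x1 or y0 >= y1:
        raise InvalidConfigError("extent must satisfy x0 < x1 and y0 < y1")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x0, x1, n_points)
    y = rng.uniform(y0, y1, n_points)
    span = max(x1 - x0, y1 - y0)
    elev = base_elev + relief * (
        0.5 + 0.5 * np.sin(2 * np.pi * x / span) * np.cos(2 * np.pi * y / span)
    )
    frame = pd.DataFrame({"x_km": x, "y_km": y, "elev_m": elev})
    truth = {"seed": seed, "extent_km": extent_km}
    return SimResult(frame=frame, truth=truth)


def gen_ndvi(
    green_up_day: int,
    base: float = 0.25,
    amplitude: float = 0.5,
    steepness: float = 0.05,
    noise_sd: float = 0.0,
    missing_rate: float = 0.0,
    seed: int = 0,
    year: int = 2015,
    senescence_day: int | None = None,
    senescence_steepness: float | None = None,
    polygon_id: str = "P1",
) -> SimResult:
    """Simulate one polygon-year of daily NDVI on a double-logistic curve.

    The curve is ``base + amplitude * min(rise, fall)`` where the rising limb
    is a logistic centred on ``green_up_day`` and the falling limb a mirrored
    logistic centred on ``senescence_day``.  Taking the pointwise minimum (as
    opposed to the sum-minus-one form) makes the half-amplitude crossing on
    the rising limb land exactly on ``green_up_day``.
    """
    if amplitude <= 0:
        raise InvalidConfigError("amplitude must be positive")
    if not (0 <= base and base + amplitude <= 1):
        raise InvalidConfigError("need 0 <= base and base + amplitude <= 1")
    if not 0 <= missing_rate < 1:
        raise InvalidConfigError("missing_rate must be in [0, 1)")
    if senescence_day is None:
        senescence_day = green_up_day + 170
    if senescence_steepness is None:
        senescence_steepness = steepness * 0.6
    if senescence_day <= green_up_day:
        raise InvalidConfigError("senescence_day must exceed green_up_day")

    rng = np.random.default_rng(seed)
    days = pd.date_range(Date(year, 1, 1), Date(year, 12, 31), freq="D")
    d = days.dayofyear.to_numpy(dtype=float)
    rise = expit(steepness * (d - green_up_day))
    fall = expit(senescence_steepness * (senescence_day - d))
    ndvi = base + amplitude * np.minimum(rise, fall)
    if noise_sd:
        ndvi = ndvi + rng.normal(0.0, noise_sd, len(d))
    keep = rng.random(len(d)) >= missing_rate
    frame = pd.DataFrame({"polygon_id": polygon_id, "date": days, "ndvi": ndvi})[keep]
    frame = frame.reset_index(drop=True)
    truth = {
        "green_up_day": green_up_day,
        "base": base,
        "amplitude": amplitude,
        "steepness": steepness,
        "senescence_day": senescence_day,
        "noise_sd": noise_sd,
        "missing_rate": missing_rate,
        "year": year,
    }
    return SimResult(frame=frame, truth=truth)


def gen_occurrences(
    weather: pd.DataFrame,
    window: PlantedWindow,
    n_grids: int,
    sightings_per_grid: int,
    year: int,
    seed: int = 0,
    species: str = "SYN",
) -> SimResult:
    """Simulate occurrence records whose per-grid first dates follow weather.

    For each grid cell the true event day is
    ``intercept + slope * statistic(variable over the planted window) +
    Gaussian(0, residual_sd)``, rounded to an integer day.  The planted
    window is event-relative, exactly as the analysis engine measures it:
    because the event day depends on weather aggregated relative to itself,
    the noiseless event day is found by fixed-point iteration (the map is a
    contraction whenever ``|slope| * seasonal temperature gradient < 1``),
    and the residual noise is added afterwards.

    The earliest sighting in each grid equals the event day by construction;
    at least ``sightings_per_grid`` records are placed per cell.
    """
    if n_grids <= 0 or sightings_per_grid <= 0:
        raise InvalidConfigError("n_grids and sightings_per_grid must be positive")
    required = {"cell_id", "date", window.variable}
    missing_cols = required - set(weather.columns)
    if missing_cols:
        raise InvalidConfigError(f"weather table missing columns {sorted(missing_cols)}")

    rng = np.random.default_rng(seed)
    year_start = pd.Timestamp(Date(year, 1, 1))
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])

    cells = sorted(w["cell_id"].unique(), key=_parse_cell)[:n_grids]
    if len(cells) < n_grids:
        raise InvalidConfigError(
            f"weather has only {len(cells)} cells, need n_grids={n_grids}"
        )

    def _covariate(sub: pd.DataFrame, event_day: float) -> float:
        anchor = year_start + pd.Timedelta(days=int(round(event_day)) - 1)
        start = anchor - pd.Timedelta(days=window.open_days)
        end = anchor - pd.Timedelta(days=window.close_days)
        vals = sub.loc[start:end, window.variable].to_numpy()
        if len(vals) != window.open_days - window.close_days + 1:
            have = set(sub.index)
            for d in pd.date_range(start, end, freq="D"):
                if d not in have:
                    raise CoverageError(
                        f"weather for cell {sub.name} does not cover {d.date()}"
                    )
        return float(vals.sum() if window.statistic == "sum" else vals.mean())

    records = []
    true_events: dict[str, int] = {}
    for cell in cells:
        sub = w[w["cell_id"] == cell].set_index("date").sort_index()
        sub.name = cell
        # coverage: the engine later needs up to 180 days before any event
        lookback = max(window.open_days, 180)
        first_needed = year_start + pd.Timedelta(days=int(window.intercept) - 1 - lookback)
        probe = pd.date_range(first_needed, year_start, freq="D")
        uncovered = probe.difference(sub.index)
        if len(uncovered):
            raise CoverageError(
                f"weather for cell {cell} does not cover {uncovered[0].date()}"
            )
        day = float(window.intercept)
        for _ in range(40):  # fixed point of the event-relative window map
            new_day = window.intercept + window.slope * _covariate(sub, day)
            if abs(new_day - day) < 0.25:
                day = new_day
                break
            day = new_day
        noise = rng.normal(0.0, window.residual_sd) if window.residual_sd else 0.0
        event_day = int(round(day + noise))
        true_events[cell] = event_day
        col, row = _parse_cell(cell)
        offsets = np.concatenate([[0], np.sort(rng.integers(1, 30, sightings_per_grid - 1))]) \
            if sightings_per_grid > 1 else np.array([0])
        for off in offsets:
            day = pd.Timestamp(Date(year, 1, 1)) + pd.Timedelta(days=event_day - 1 + int(off))
            records.append(
                {
                    "species": species,
                    "date": day,
                    "x_km": 10.0 * col + rng.uniform(1.0, 9.0),
                    "y_km": 10.0 * row + rng.uniform(1.0, 9.0),
                }
            )
    frame = pd.DataFrame.from_records(records)
    truth = {
        "window": dataclasses.asdict(window),
        "events_by_cell": true_events,
        "year": year,
        "species": species,
        "n_grids": n_grids,
        "sightings_per_grid": sightings_per_grid,
    }
    return SimResult(frame=frame, truth=truth)
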