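"""Daily weather preparation: 09 UTC aggregation and lapse-rate correction.

The daily convention: precipitation totals and maximum temperature over the
half-open window [day D 09:00 UTC, day D+1 09:00 UTC) are assigned to day D;
the minimum temperature over the same window is assigned to day D+1.
Windows with incomplete hourly coverage are dropped, never partially
aggregated.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenosync.errors import CoverageError, SchemaError

#: ICAO international standard atmosphere lapse rate, K per km of height.
STANDARD_LAPSE_RATE = 6.49

_WINDOW_START_HOUR = 9


def aggregate_daily(hourly: pd.DataFrame) -> pd.DataFrame:
    """Aggregate an hourly table to daily TMAX/TMIN/TPPT on the 09 UTC window.

    Parameters
    ----------
    hourly:
        Columns ``cell_id, timestamp, temp_c, precip_mm``; timestamps must be
        UTC (tz-aware UTC or naive, interpreted as UTC) on an hourly lattice,
        sorted within each cell.

    Returns
    -------
    DataFrame with columns ``cell_id, date, tmax, tmin, tppt``, one row per
    complete (cell, day).  A day needs both its own complete 09-09 window
    (for tmax/tppt) and a complete preceding window (for tmin).
    """
    required = {"cell_id", "timestamp", "temp_c", "precip_mm"}
    missing = required - set(hourly.columns)
    if missing:
        raise SchemaError(f"hourly table missing columns {sorted(missing)}")
    ts = pd.to_datetime(hourly["timestamp"])
    if ts.dt.tz is not None:
        if str(ts.dt.tz) not in ("UTC", "utc"):
            raise SchemaError(f"timestamps must be UTC, got timezone {ts.dt.tz}")
        ts = ts.dt.tz_localize(None)
    df = hourly.assign(_ts=ts)
    if (df.groupby("cell_id")["_ts"].apply(lambda s: s.is_monotonic_increasing) == False).any():  # noqa: E712
        raise SchemaError("timestamps must be sorted within each cell")

    # Window day D covers [D 09:00, D+1 09:00): shift back 9 h and take the date.
    df["_window_day"] = (df["_ts"] - pd.Timedelta(hours=_WINDOW_START_HOUR)).dt.normalize()

    grouped = df.groupby(["cell_id", "_window_day"], sort=True)
    agg = grouped.agg(
        tmax=("temp_c", "max"),
        _tmin=("temp_c", "min"),
        tppt=("precip_mm", "sum"),
        _count=("temp_c", "size"),
    ).reset_index()
    agg = agg[agg["_count"] >= 24]  # incomplete windows are dropped

    maxpart = agg[["cell_id", "_window_day", "tmax", "tppt"]].rename(
        columns={"_window_day": "date"}
    )
    minpart = agg[["cell_id", "_window_day", "_tmin"]].copy()
    minpart["date"] = minpart["_window_day"] + pd.Timedelta(days=1)
    minpart = minpart[["cell_id", "date", "_tmin"]].rename(columns={"_tmin": "tmin"})

    daily = maxpart.merge(minpart, on=["cell_id", "date"], how="inner")
    daily = daily[["cell_id", "date", "tmax", "tmin", "tppt"]]
    return daily.sort_values(["cell_id", "date"]).reset_index(drop=True)


def regrid_dem_nearest(dem: pd.DataFrame, grid: pd.DataFrame) -> pd.DataFrame:
    """Assign each grid cell the elevation of its nearest DEM sample point.

    Ties in distance are broken by the smallest DEM sample index, which makes
    the assignment stable across runs.  ``dem`` has columns
    ``x_km, y_km, elev_m``; ``grid`` has ``cell_id, x_km, y_km``.
    """
    for name, frame, cols in (
        ("dem", dem, {"x_km", "y_km", "elev_m"}),
        ("grid", grid, {"cell_id", "x_km", "y_km"}),
    ):
        missing = cols - set(frame.columns)
        if missing:
            raise SchemaError(f"{name} table missing columns {sorted(missing)}")
    if dem.empty:
        raise CoverageError("DEM table is empty")

    dx = dem["x_km"].to_numpy()
    dy = dem["y_km"].to_numpy()
    gx = grid["x_km"].to_numpy()
    gy = grid["y_km"].to_numpy()

    pad = 1e-9
    outside = (
        (gx < dx.min() - pad) | (gx > dx.max() + pad)
        | (gy < dy.min() - pad) | (gy > dy.max() + pad)
    )
    if outside.any():
        bad = grid.loc[outside, "cell_id"].tolist()
        raise CoverageError(f"cell centres outside DEM extent: {bad}")

    # Exhaustive argmin keeps the lowest-index tie-break exact; chunk the
    # distance matrix to bound memory on large grids.
    nearest = np.empty(len(gx), dtype=np.int64)
    chunk = max(1, int(2e7 / max(len(dx), 1)))
    for start in range(0, len(gx), chunk):
        sl = slice(start, start + chunk)
        d2 = (gx[sl, None] - dx[None, :]) ** 2 + (gy[sl, None] - dy[None, :]) ** 2
        nearest[sl] = d2.argmin(axis=1)

    out = grid[["cell_id"]].copy()
    out["dem_elev"] = dem["elev_m"].to_numpy()[nearest]
    return out


def correct_temperature(
    daily: pd.DataFrame, lapse_rate: float = STANDARD_LAPSE_RATE
) -> pd.DataFrame:
    """Apply the lapse-rate elevation correction to tmax and tmin.

    ``corrected = T + lapse_rate * (model_elev - dem_elev) / 1000`` — a model
    surface sitting above the true terrain is warmed, below is cooled.
    Precipitation is unchanged.  Requires ``model_elev`` and ``dem_elev``
    columns on every row.
    """
    for col in ("model_elev", "dem_elev"):
        if col not in daily.columns:
            raise SchemaError(f"daily table missing column {col!r}")
        bad = daily[daily[col].isna()]
        if not bad.empty:
            cells = sorted(bad["cell_id"].unique().tolist())
            raise CoverageError(f"missing {col} for cells {cells}")
    out = daily.copy()
    delta = lapse_rate * (out["model_elev"] - out["dem_elev"]) / 1000.0
    out["tmax"] = out["tmax"] + delta
    out["tmin"] = out["tmin"] + delta
    return out
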