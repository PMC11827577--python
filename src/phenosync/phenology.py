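"""Phenological event extraction.

Green-up (GU) dates come from NDVI series via monthly-max compositing,
climatology gap filling, LOESS smoothing with daily interpolation, and the
half-amplitude rule.  First-flight (FF) and date-of-arrival (DA) events come
from occurrence records after 10 km gridding and the inclusion filters
(>= 3 sightings per grid, >= 20 grids per species-year).

Day-of-year convention: 1 January is day 1; leap years keep natural
numbering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from phenosync.errors import (
    DegenerateSeriesError,
    FitError,
    SchemaError,
)

DEFAULT_CELL_SIZE_KM = 10.0
DEFAULT_MIN_PER_GRID = 3
DEFAULT_MIN_GRIDS = 20
DEFAULT_LOESS_SPAN = 0.25

_MIN_LOCAL_POINTS = 4  # local quadratic needs >= 4 points per neighbourhood


# ---------------------------------------------------------------------------
# NDVI -> green-up
# ---------------------------------------------------------------------------

def monthly_max_composite(
    series: pd.DataFrame, day_convention: str = "argmax"
) -> pd.DataFrame:
    """Composite an NDVI series to one maximum value per calendar month.

    Returns one row per (polygon_id, year, month) covering the full monthly
    span of the input; months with no observation carry a missing ``ndvi``
    (absence is never coerced to zero).  Each composite keeps a ``date`` for
    interpolation: the date of the retained maximum observation
    (``day_convention="argmax"``, default — it preserves the timing of the
    underlying curve) or the 15th of the month (``"midpoint"``).
    """
    if series.empty:
        raise SchemaError("empty NDVI series")
    required = {"polygon_id", "date", "ndvi"}
    missing = required - set(series.columns)
    if missing:
        raise SchemaError(f"NDVI series missing columns {sorted(missing)}")
    if day_convention not in ("argmax", "midpoint"):
        raise SchemaError(f"unknown day_convention {day_convention!r}")

    df = series.copy()
    df["date"] = pd.to_datetime(df["date"])
    df = df.dropna(subset=["ndvi"])
    if df.empty:
        raise SchemaError("NDVI series has no non-missing observations")

    out_rows = []
    for polygon, sub in df.groupby("polygon_id"):
        months = pd.period_range(
            sub["date"].min().to_period("M"), sub["date"].max().to_period("M"), freq="M"
        )
        by_month = sub.set_index(sub["date"].dt.to_period("M"))
        for m in months:
            obs = by_month.loc[[m]] if m in by_month.index else None
            if obs is None or obs.empty:
                value, when = np.nan, pd.Timestamp(m.year, m.month, 15)
            else:
                i = obs["ndvi"].to_numpy().argmax()
                value = float(obs["ndvi"].iloc[i])
                when = (
                    obs["date"].iloc[i]
                    if day_convention == "argmax"
                    else pd.Timestamp(m.year, m.month, 15)
                )
            out_rows.append(
                {
                    "polygon_id": polygon,
                    "year": m.year,
                    "month": m.month,
                    "date": when,
                    "ndvi": value,
                }
            )
    return pd.DataFrame(out_rows)


def fill_climatology(monthly: pd.DataFrame) -> pd.DataFrame:
    """Fill missing composite months with the cross-year mean for that month.

    A missing month m in year y becomes the mean of month-m composites over
    every year in which it is observed; observed values are untouched.
    Raises if some calendar month is missing in all years (per polygon).
    """
    required = {"polygon_id", "year", "month", "date", "ndvi"}
    missing_cols = required - set(monthly.columns)
    if missing_cols:
        raise SchemaError(f"monthly table missing columns {sorted(missing_cols)}")

    out = monthly.copy()
    for polygon, sub in out.groupby("polygon_id"):
        clim = sub.groupby("month")["ndvi"].mean()  # skips NaN
        needed = sub.loc[sub["ndvi"].isna(), "month"].unique()
        unfillable = [int(m) for m in needed if pd.isna(clim.get(m, np.nan))]
        if unfillable:
            raise DegenerateSeriesError(
                f"polygon {polygon}: months {unfillable} have no observation in any year"
            )
        mask = (out["polygon_id"] == polygon) & out["ndvi"].isna()
        out.loc[mask, "ndvi"] = out.loc[mask, "month"].map(clim)
    return out


def _loess_quadratic(
    x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float
) -> np.ndarray:
    """Local quadratic regression with tricube weights (classic LOESS)."""
    n = len(x)
    k = int(np.ceil(span * n))
    if k < _MIN_LOCAL_POINTS:
        raise FitError(
            f"span {span} keeps only {k} of {n} points per fit; "
            f"minimal feasible span is {(_MIN_LOCAL_POINTS / n):.4f}"
        )
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    result = np.empty(len(x_eval))
    for i, x0 in enumerate(x_eval):
        d = np.abs(xs - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            result[i] = ys[idx[d[idx].argmin()]]
            continue
        w = (1.0 - (d[idx] / h) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        t = xs[idx] - x0
        design = np.column_stack([np.ones(k), t, t * t])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(design * sw[:, None], ys[idx] * sw, rcond=None)
        result[i] = beta[0]
    return result


def smooth_and_interpolate(
    monthly: pd.DataFrame, span: float = DEFAULT_LOESS_SPAN
) -> pd.DataFrame:
    """LOESS-smooth a gap-free monthly series and interpolate to daily values.

    Degree-2 local regression with tricube weights, evaluated at every
    calendar day between the first and last composite date (per polygon).
    """
    required = {"polygon_id", "date", "ndvi"}
    missing_cols = required - set(monthly.columns)
    if missing_cols:
        raise SchemaError(f"monthly table missing columns {sorted(missing_cols)}")
    if monthly["ndvi"].isna().any():
        raise SchemaError("monthly series must be gap-free; run fill_climatology first")

    frames = []
    for polygon, sub in monthly.groupby("polygon_id"):
        sub = sub.sort_values("date")
        if len(sub) < 8:
            raise FitError(f"polygon {polygon}: need >= 8 monthly points, have {len(sub)}")
        dates = pd.to_datetime(sub["date"])
        t = dates.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
        y = sub["ndvi"].to_numpy(dtype=float)
        day_index = pd.date_range(dates.min().normalize(), dates.max().normalize(), freq="D")
        t_eval = day_index.map(pd.Timestamp.toordinal).to_numpy(dtype=float)
        smoothed = _loess_quadratic(t, y, t_eval, span)
        frames.append(
            pd.DataFrame({"polygon_id": polygon, "date": day_index, "ndvi": smoothed})
        )
    return pd.concat(frames, ignore_index=True)


def greenup_half_amplitude(daily: pd.DataFrame) -> int:
    """Green-up day-of-year via the half-amplitude rule, for one polygon-year.

    GU is the first day on the rising limb where NDVI reaches
    ``min + (max - min) / 2``; the minimum is taken before the annual-maximum
    day so a late-season trough cannot shadow the rising limb.  The crossing
    is linearly interpolated between bracketing days and rounded to the
    nearest integer day.
    """
    required = {"date", "ndvi"}
    missing_cols = required - set(daily.columns)
    if missing_cols:
        raise SchemaError(f"daily series missing columns {sorted(missing_cols)}")
    sub = daily.sort_values("date")
    dates = pd.to_datetime(sub["date"])
    if dates.dt.year.nunique() > 1:
        raise SchemaError("greenup_half_amplitude expects a single polygon-year")
    v = sub["ndvi"].to_numpy(dtype=float)
    doy = dates.dt.dayofyear.to_numpy()

    i_max = int(v.argmax())
    if i_max == 0:
        raise DegenerateSeriesError("annual maximum at the first day: no rising limb")
    rising = v[: i_max + 1]
    i_min = int(rising.argmin())
    v_min, v_max = v[i_min], v[i_max]
    if v_max <= v_min:
        raise DegenerateSeriesError("flat series: annual max does not exceed annual min")
    threshold = v_min + (v_max - v_min) / 2.0

    seg = v[i_min : i_max + 1]
    seg_doy = doy[i_min : i_max + 1]
    above = np.nonzero(seg >= threshold)[0]
    i = int(above[0])
    if i == 0:
        return int(seg_doy[0])
    frac = (threshold - seg[i - 1]) / (seg[i] - seg[i - 1])
    crossing = seg_doy[i - 1] + frac * (seg_doy[i] - seg_doy[i - 1])
    return int(np.floor(crossing + 0.5))


def extract_greenup(
    series: pd.DataFrame,
    span: float = DEFAULT_LOESS_SPAN,
    day_convention: str = "argmax",
) -> pd.DataFrame:
    """Full NDVI pipeline: composite, fill, smooth, half-amplitude per year.

    Returns events with columns ``polygon_id, year, event_day, event_type``
    (event_type ``"GU"``).  Years whose smoothed series is degenerate are
    skipped.
    """
    monthly = monthly_max_composite(series, day_convention=day_convention)
    filled = fill_climatology(monthly)
    daily = smooth_and_interpolate(filled, span=span)
    rows = []
    daily = daily.assign(_year=pd.to_datetime(daily["date"]).dt.year)
    for (polygon, year), sub in daily.groupby(["polygon_id", "_year"]):
        if len(sub) < 300:  # partial edge years lack a full seasonal cycle
            continue
        try:
            gu = greenup_half_amplitude(sub[["date", "ndvi"]])
        except DegenerateSeriesError:
            continue
        rows.append(
            {"polygon_id": polygon, "year": int(year), "event_day": gu, "event_type": "GU"}
        )
    return pd.DataFrame(rows, columns=["polygon_id", "year", "event_day", "event_type"])


# ---------------------------------------------------------------------------
# Occurrences -> first events
# ---------------------------------------------------------------------------

def grid_occurrences(
    records: pd.DataFrame, cell_size_km: float = DEFAULT_CELL_SIZE_KM
) -> tuple[pd.DataFrame, int]:
    """Annotate records with the 10 km grid cell containing each point.

    Cells follow the half-open floor convention
    ``cell = (floor(x / size), floor(y / size))``, so a point exactly on a
    boundary belongs to the higher cell only.  Rows with missing coordinates
    are rejected; the count of rejected rows is returned alongside.
    """
    required = {"x_km", "y_km"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise SchemaError(f"records missing columns {sorted(missing_cols)}")
    ok = records["x_km"].notna() & records["y_km"].notna()
    rejected = int((~ok).sum())
    out = records[ok].copy()
    cx = np.floor(out["x_km"].to_numpy(dtype=float) / cell_size_km).astype(np.int64)
    cy = np.floor(out["y_km"].to_numpy(dtype=float) / cell_size_km).astype(np.int64)
    out["cell_x"] = cx
    out["cell_y"] = cy
    out["cell_id"] = [f"{a}_{b}" for a, b in zip(cx, cy)]
    return out, rejected


def first_event(
    records: pd.DataFrame,
    min_per_grid: int = DEFAULT_MIN_PER_GRID,
    min_grids: int = DEFAULT_MIN_GRIDS,
    event_type: str = "FF",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-grid earliest sighting dates with the inclusion filters applied.

    Grids with fewer than ``min_per_grid`` sightings are discarded; a
    (species, year) with fewer than ``min_grids`` surviving grids is excluded
    entirely.  Exclusion is a reported outcome, not an error: the second
    return value lists excluded (species, year, n_grids) rows.

    Returns ``(events, exclusions)`` where events has columns
    ``species, cell_id, year, event_day, event_type, n_grids``.
    """
    required = {"species", "date", "cell_id"}
    missing_cols = required - set(records.columns)
    if missing_cols:
        raise SchemaError(f"records missing columns {sorted(missing_cols)}")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"])
    df["year"] = df["date"].dt.year

    counts = df.groupby(["species", "year", "cell_id"], sort=True).size()
    surviving = counts[counts >= min_per_grid]

    events_rows = []
    exclusion_rows = []
    for (species, year), grids in surviving.groupby(level=[0, 1]):
        n_grids = len(grids)
        if n_grids < min_grids:
            exclusion_rows.append(
                {"species": species, "year": int(year), "n_grids": n_grids}
            )
            continue
        keep_cells = grids.index.get_level_values("cell_id")
        sub = df[
            (df["species"] == species)
            & (df["year"] == year)
            & df["cell_id"].isin(keep_cells)
        ]
        firsts = sub.groupby("cell_id")["date"].min()
        for cell, when in firsts.items():
            events_rows.append(
                {
                    "species": species,
                    "cell_id": cell,
                    "year": int(year),
                    "event_day": int(when.dayofyear),
                    "event_type": event_type,
                    "n_grids": n_grids,
                }
            )
    # species-years that vanished entirely at the per-grid stage
    all_pairs = set(map(tuple, df.groupby(["species", "year"]).size().index))
    seen = {(r["species"], r["year"]) for r in events_rows} | {
        (r["species"], r["year"]) for r in exclusion_rows
    }
    for species, year in sorted(all_pairs - seen):
        exclusion_rows.append({"species": species, "year": int(year), "n_grids": 0})

    events = pd.DataFrame(
        events_rows,
        columns=["species", "cell_id", "year", "event_day", "event_type", "n_grids"],
    )
    exclusions = pd.DataFrame(exclusion_rows, columns=["species", "year", "n_grids"])
    return events, exclusions.sort_values(["species", "year"]).reset_index(drop=True)


def summarize_events(events: pd.DataFrame) -> pd.DataFrame:
    """National per-(species, year) summary of event days.

    Median uses the midpoint-of-two convention for even counts (numpy
    default).  Output columns: species, year, median, q1, q3, min, max, n.
    """
    if events.empty:
        raise SchemaError("no events to summarise")
    rows = []
    for (species, year), sub in events.groupby(["species", "year"]):
        d = sub["event_day"].to_numpy(dtype=float)
        rows.append(
            {
                "species": species,
                "year": int(year),
                "median": float(np.median(d)),
                "q1": float(np.percentile(d, 25)),
                "q3": float(np.percentile(d, 75)),
                "min": float(d.min()),
                "max": float(d.max()),
                "n": len(d),
            }
        )
    return pd.DataFrame(rows)
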