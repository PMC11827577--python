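"""Relative sliding time-window regression with AICc selection.

For each candidate window (open, close) measured in days before each
record's own event date, the weather variable is aggregated over
``[event - open, event - close]`` (inclusive, so day 0 is the event day
itself), an ordinary least-squares line of event day on the aggregate is
fitted, and the window minimising AICc is selected.  Significance is
attached by permuting event days across records and re-running the full
search (``randomization_pc``).

Cross-year lookups use real calendar arithmetic: an event on day 40 reaches
into the previous year's weather.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from phenosync.errors import CoverageError, SampleSizeError, SchemaError

DEFAULT_MAX_LAG = 180

#: Default aggregate statistic per variable: mean temperatures, total precipitation.
DEFAULT_STATISTICS = {"tmin": "mean", "tmax": "mean", "tppt": "sum"}

_K_SLOPE = 3  # intercept + slope + variance
_K_NULL = 2  # intercept + variance


@dataclass(frozen=True)
class WindowSpec:
    """A candidate window: ``open_days >= close_days``, both before the event."""

    open_days: int
    close_days: int
    variable: str
    statistic: str = "mean"

    def __post_init__(self) -> None:
        if not 0 <= self.close_days <= self.open_days:
            raise SchemaError(
                f"need 0 <= close <= open, got open={self.open_days} close={self.close_days}"
            )
        if self.statistic not in ("mean", "sum"):
            raise SchemaError(f"statistic must be mean or sum, got {self.statistic!r}")

    @property
    def length(self) -> int:
        return self.open_days - self.close_days + 1


@dataclass(frozen=True)
class WindowFit:
    """Result of fitting one window (or the best of a search)."""

    spec: WindowSpec
    slope: float
    intercept: float
    aicc: float
    delta_aicc: float
    n: int
    pc: float | None = None
    species: str | None = None
    year: int | None = None


def enumerate_windows(max_lag: int = DEFAULT_MAX_LAG, step: int = 1) -> list[tuple[int, int]]:
    """All (open, close) pairs with open >= close on the step lattice.

    Ordered by open ascending then close ascending; count is T(T+1)/2 for
    T = max_lag // step + 1 lattice points.
    """
    if max_lag < 0 or step < 1:
        raise SchemaError("need max_lag >= 0 and step >= 1")
    lattice = range(0, max_lag + 1, step)
    return [(o, c) for o in lattice for c in lattice if c <= o]


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n <= k + 1:
        raise SampleSizeError(f"AICc needs n > k + 1 (n={n}, k={k})")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood with the variance MLE rss/n."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * sigma2) + 1.0)


def _event_dates(events: pd.DataFrame) -> pd.Series:
    if not {"year", "event_day"} <= set(events.columns):
        raise SchemaError("events need 'year' and 'event_day' columns")
    parts = pd.DataFrame(
        {"year": events["year"].to_numpy(), "month": 1, "day": 1}
    )
    return pd.to_datetime(parts) + pd.to_timedelta(
        events["event_day"].to_numpy(dtype=int) - 1, unit="D"
    )


def _lag_matrix(
    weather: pd.DataFrame, events: pd.DataFrame, variable: str, max_lag: int
) -> np.ndarray:
    """Matrix L with L[i, lag] = weather value in event i's cell at event_date - lag."""
    if variable not in weather.columns:
        raise SchemaError(f"weather table has no column {variable!r}")
    if "cell_id" not in events.columns:
        raise SchemaError("events need a 'cell_id' column")
    w = weather[["cell_id", "date", variable]].copy()
    w["date"] = pd.to_datetime(w["date"])
    by_cell = {
        cell: sub.set_index("date")[variable].sort_index()
        for cell, sub in w.groupby("cell_id")
    }
    dates = _event_dates(events)
    out = np.empty((len(events), max_lag + 1))
    lags = pd.to_timedelta(np.arange(max_lag + 1), unit="D")
    for i, (cell, when) in enumerate(zip(events["cell_id"].to_numpy(), dates)):
        ser = by_cell.get(cell)
        if ser is None:
            raise CoverageError(f"no weather for cell {cell!r}")
        vals = ser.reindex(when - lags).to_numpy(dtype=float)
        if np.isnan(vals).any():
            first_bad = int(np.nonzero(np.isnan(vals))[0][0])
            raise CoverageError(
                f"weather for cell {cell!r} missing {(when - lags[first_bad]).date()} "
                f"(event on {when.date()})"
            )
        out[i] = vals
    return out


def aggregate_relative(
    weather: pd.DataFrame, events: pd.DataFrame, spec: WindowSpec
) -> np.ndarray:
    """Per-event scalar covariate over the record-relative window."""
    lagm = _lag_matrix(weather, events, spec.variable, spec.open_days)
    block = lagm[:, spec.close_days : spec.open_days + 1]
    return block.sum(axis=1) if spec.statistic == "sum" else block.mean(axis=1)


def _null_aicc(y: np.ndarray) -> float:
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    return aicc(_gaussian_loglik(rss0, n), _K_NULL, n)


def fit_window(
    events: pd.DataFrame, weather: pd.DataFrame, spec: WindowSpec
) -> WindowFit:
    """OLS of event day on the window covariate, scored by AICc.

    A zero-variance covariate yields the degenerate sentinel
    ``delta_aicc = +inf`` with an undefined slope, so the window can never
    be selected.
    """
    if len(events) < 4:
        raise SampleSizeError(f"need >= 4 events, have {len(events)}")
    x = aggregate_relative(weather, events, spec)
    y = events["event_day"].to_numpy(dtype=float)
    n = len(y)
    null = _null_aicc(y)
    sxx = float(((x - x.mean()) ** 2).sum())
    if sxx <= 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
        return WindowFit(
            spec=spec, slope=float("nan"), intercept=float("nan"),
            aicc=float("inf"), delta_aicc=float("inf"), n=n,
        )
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    rss = float(((y - y.mean()) ** 2).sum()) - slope * sxy
    rss = max(rss, 0.0)
    fit_aicc = aicc(_gaussian_loglik(rss, n), _K_SLOPE, n)
    return WindowFit(
        spec=spec, slope=slope, intercept=intercept,
        aicc=fit_aicc, delta_aicc=fit_aicc - null, n=n,
    )


def _search(
    lagm: np.ndarray,
    y: np.ndarray,
    windows: list[tuple[int, int]],
    statistic: str,
) -> tuple[int, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised AICc search over all windows given a lag matrix.

    Returns (best index, delta_aicc per window, slope per window,
    intercept per window).  Tie-break: lowest AICc, then shorter window,
    then smaller close_days.
    """
    n = lagm.shape[0]
    cs = np.concatenate([np.zeros((n, 1)), np.cumsum(lagm, axis=1)], axis=1)
    opens = np.array([o for o, _ in windows])
    closes = np.array([c for _, c in windows])
    lengths = opens - closes + 1
    X = cs[:, opens + 1] - cs[:, closes]  # window sums, shape (n, W)
    if statistic == "mean":
        X = X / lengths[None, :]

    ybar = y.mean()
    syy = float(((y - ybar) ** 2).sum())
    sx = X.sum(axis=0)
    sxx = (X * X).sum(axis=0) - sx * sx / n
    sxy = (X * y[:, None]).sum(axis=0) - sx * y.sum() / n

    scale = np.maximum(1.0, (np.abs(X).max(axis=0)) ** 2)
    degenerate = sxx <= 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = np.where(degenerate, np.nan, sxy / np.where(degenerate, 1.0, sxx))
    rss = np.maximum(syy - slopes * sxy, 0.0)
    sigma2 = np.maximum(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
    aiccs = -2.0 * loglik + 2.0 * _K_SLOPE + 2.0 * _K_SLOPE * (_K_SLOPE + 1) / (n - _K_SLOPE - 1)
    aiccs = np.where(degenerate, np.inf, aiccs)
    delta = aiccs - _null_aicc(y)

    best = int(np.lexsort((closes, lengths, delta))[0])
    intercepts = ybar - slopes * sx / n
    return best, delta, slopes, intercepts


def best_window(
    events: pd.DataFrame,
    weather: pd.DataFrame,
    variable: str,
    statistic: str | None = None,
    max_lag: int = DEFAULT_MAX_LAG,
    step: int = 1,
) -> WindowFit:
    """Exhaustive window search returning the AICc-minimising WindowFit."""
    if len(events) < 4:
        raise SampleSizeError(f"need >= 4 events, have {len(events)}")
    if statistic is None:
        statistic = DEFAULT_STATISTICS.get(variable, "mean")
    windows = enumerate_windows(max_lag, step)
    lagm = _lag_matrix(weather, events, variable, max_lag)
    y = events["event_day"].to_numpy(dtype=float)
    best, delta, slopes, intercepts = _search(lagm, y, windows, statistic)
    o, c = windows[best]
    n = len(y)
    spec = WindowSpec(open_days=o, close_days=c, variable=variable, statistic=statistic)
    return WindowFit(
        spec=spec,
        slope=float(slopes[best]),
        intercept=float(intercepts[best]),
        aicc=float(delta[best] + _null_aicc(y)),
        delta_aicc=float(delta[best]),
        n=n,
    )


def randomization_pc(
    events: pd.DataFrame,
    weather: pd.DataFrame,
    variable: str,
    statistic: str | None = None,
    n_rand: int = 100,
    seed: int = 0,
    max_lag: int = DEFAULT_MAX_LAG,
    step: int = 1,
) -> float:
    """Permutation estimate of the selected window's chance probability.

    Event days are permuted across records ``n_rand`` times; the full window
    search is re-run on each permutation (anchor dates move with the permuted
    days, so lag matrices are rebuilt).  Returns
    ``(1 + #{permuted delta <= observed delta}) / (1 + n_rand)``.
    """
    if n_rand < 5:
        raise SampleSizeError(f"n_rand must be >= 5, got {n_rand}")
    if statistic is None:
        statistic = DEFAULT_STATISTICS.get(variable, "mean")
    windows = enumerate_windows(max_lag, step)
    rng = np.random.default_rng(seed)

    observed = best_window(events, weather, variable, statistic, max_lag, step).delta_aicc

    hits = 0
    days = events["event_day"].to_numpy()
    for _ in range(n_rand):
        perm = events.copy()
        perm["event_day"] = rng.permutation(days)
        lagm = _lag_matrix(weather, perm, variable, max_lag)
        y = perm["event_day"].to_numpy(dtype=float)
        _, delta, _, _ = _search(lagm, y, windows, statistic)
        if float(delta.min()) <= observed:
            hits += 1
    return (1 + hits) / (1 + n_rand)


def fit_with_pc(
    events: pd.DataFrame,
    weather: pd.DataFrame,
    variable: str,
    statistic: str | None = None,
    n_rand: int = 100,
    seed: int = 0,
    max_lag: int = DEFAULT_MAX_LAG,
    step: int = 1,
    species: str | None = None,
    year: int | None = None,
) -> WindowFit:
    """Best window plus its permutation pc, tagged with species/year."""
    fit = best_window(events, weather, variable, statistic, max_lag, step)
    pc = randomization_pc(
        events, weather, variable, statistic, n_rand=n_rand, seed=seed,
        max_lag=max_lag, step=step,
    )
    return replace(fit, pc=pc, species=species, year=year)
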