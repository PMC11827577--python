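import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from phenosync import synthetic, windows
from phenosync.errors import CoverageError, SampleSizeError
from phenosync.windows import WindowSpec


def brute_force_best_window(events, weather, variable, statistic, max_lag):
    """Independent oracle: plain triple loop, per-event date arithmetic.

    Deliberately naive: no shared lag matrix, no vectorisation; same
    tie-break contract (AICc, then shorter window, then smaller close).
    """
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"])
    lookup = {
        (r.cell_id, r.date): getattr(r, variable) for r in w.itertuples(index=False)
    }
    y = [float(d) for d in events["event_day"]]
    n = len(y)
    ybar = sum(y) / n
    syy = sum((v - ybar) ** 2 for v in y)
    sigma0 = syy / n
    null_ll = -0.5 * n * (math.log(2 * math.pi * max(sigma0, 1e-300)) + 1)
    null_aicc = -2 * null_ll + 4 + 12 / (n - 3)

    best = None
    for opened in range(0, max_lag + 1):
        for closed in range(0, opened + 1):
            xs = []
            for rec in events.itertuples(index=False):
                when = pd.Timestamp(date(int(rec.year), 1, 1)) + pd.Timedelta(
                    days=int(rec.event_day) - 1
                )
                vals = []
                for lag in range(closed, opened + 1):
                    key = (rec.cell_id, when - pd.Timedelta(days=lag))
                    vals.append(lookup[key])
                xs.append(sum(vals) if statistic == "sum" else sum(vals) / len(vals))
            xbar = sum(xs) / n
            sxx = sum((v - xbar) ** 2 for v in xs)
            if sxx <= 1e-12 * max(1.0, max(abs(v) for v in xs) ** 2):
                continue
            sxy = sum((a - xbar) * (b - ybar) for a, b in zip(xs, y))
            slope = sxy / sxx
            rss = max(syy - slope * sxy, 0.0)
            ll = -0.5 * n * (math.log(2 * math.pi * max(rss / n, 1e-300)) + 1)
            a = -2 * ll + 6 + 24 / (n - 4)
            cand = (a - null_aicc, opened - closed + 1, closed, opened, slope, a)
            if best is None or cand[:3] < best[:3]:
                best = cand
    delta, _, closed, opened, slope, a = best
    return {"open": opened, "close": closed, "slope": slope, "aicc": a, "delta": delta}


class TestEnumerateWindows:
    def test_exhaustive_small_case(self):
        assert windows.enumerate_windows(2, 1) == [
            (0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2),
        ]

    def test_full_range_count(self):
        assert len(windows.enumerate_windows(180, 1)) == 16471

    def test_zero_lag(self):
        assert windows.enumerate_windows(0, 1) == [(0, 0)]


class TestAicc:
    def test_plug_in_formula(self):
        assert windows.aicc(-50.0, 2, 100) == pytest.approx(104 + 12 / 97)

    def test_converges_to_aic(self):
        a = windows.aicc(-50.0, 3, 10**7)
        assert a - (100 + 6) == pytest.approx(0.0, abs=1e-4)

    def test_penalty_monotone_in_k(self):
        assert windows.aicc(-30.0, 2, 20) < windows.aicc(-30.0, 3, 20)

    def test_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            windows.aicc(-1.0, 3, 4)


def _events_for(weather_frame, days_by_cell, year=2015):
    rows = [
        {"species": "SP", "cell_id": c, "year": year, "event_day": d,
         "event_type": "FF", "n_grids": len(days_by_cell)}
        for c, d in days_by_cell.items()
    ]
    return pd.DataFrame(rows)


class TestAggregateRelative:
    def test_window_0_0_is_event_day_value(self, small_weather):
        w = small_weather.frame
        events = _events_for(w, {"0_0": 100, "1_0": 120})
        spec = WindowSpec(0, 0, "tmin", "mean")
        cov = windows.aggregate_relative(w, events, spec)
        w2 = w.set_index(["cell_id", "date"])
        assert cov[0] == pytest.approx(
            w2.loc[("0_0", pd.Timestamp("2015-04-10"))]["tmin"]
        )

    def test_constant_weather(self):
        dates = pd.date_range("2014-06-01", "2015-12-31", freq="D")
        w = pd.DataFrame({"cell_id": "0_0", "date": dates, "tmin": 4.0})
        events = _events_for(w, {"0_0": 150})
        mean = windows.aggregate_relative(w, events, WindowSpec(50, 25, "tmin", "mean"))
        total = windows.aggregate_relative(w, events, WindowSpec(50, 25, "tmin", "sum"))
        assert mean[0] == pytest.approx(4.0)
        assert total[0] == pytest.approx(4.0 * 26)

    def test_matches_brute_force_loop(self, small_weather):
        w = small_weather.frame
        events = _events_for(w, {"0_0": 130, "2_0": 145, "4_0": 160})
        spec = WindowSpec(50, 25, "tmax", "mean")
        cov = windows.aggregate_relative(w, events, spec)
        w2 = w.set_index(["cell_id", "date"])
        for i, rec in enumerate(events.itertuples(index=False)):
            when = pd.Timestamp(date(rec.year, 1, 1)) + pd.Timedelta(days=rec.event_day - 1)
            vals = [
                w2.loc[(rec.cell_id, when - pd.Timedelta(days=lag))]["tmax"]
                for lag in range(25, 51)
            ]
            assert cov[i] == pytest.approx(np.mean(vals))

    def test_uncovered_day_raises_with_date(self, small_weather):
        w = small_weather.frame
        events = _events_for(w, {"0_0": 30}, year=2014)  # needs 2013 weather
        with pytest.raises(CoverageError, match="2013"):
            windows.aggregate_relative(w, events, WindowSpec(60, 0, "tmin", "mean"))


class TestFitWindow:
    def test_perfect_linear_fit(self):
        # time-constant, cell-varying weather: the covariate equals the cell
        # value for any window, so the planted line is recovered exactly
        dates = pd.date_range("2014-06-01", "2015-12-31", freq="D")
        frames = [
            pd.DataFrame({"cell_id": f"{i}_0", "date": dates, "tmin": float(i)})
            for i in range(12)
        ]
        w = pd.concat(frames, ignore_index=True)
        events = _events_for(w, {f"{i}_0": 200 - 3 * i for i in range(12)})
        fit = windows.fit_window(events, w, WindowSpec(40, 20, "tmin", "mean"))
        assert fit.slope == pytest.approx(-3.0, abs=1e-9)
        assert fit.intercept == pytest.approx(200.0, abs=1e-6)
        assert fit.delta_aicc < -50

    def test_constant_covariate_degenerate(self):
        dates = pd.date_range("2014-06-01", "2015-12-31", freq="D")
        frames = [
            pd.DataFrame({"cell_id": f"{i}_0", "date": dates, "tmin": 4.0})
            for i in range(6)
        ]
        w = pd.concat(frames, ignore_index=True)
        events = _events_for(w, {f"{i}_0": 100 + i for i in range(6)})
        fit = windows.fit_window(events, w, WindowSpec(30, 10, "tmin", "mean"))
        assert math.isinf(fit.delta_aicc)
        assert math.isnan(fit.slope)

    def test_slope_recovery_over_seeds(self, recovery_weather):
        # Planted slope -2 at residual SD 1.  Relative windows anchored on
        # noisy, day-rounded event dates misalign slightly with the planted
        # window, attenuating the estimate toward zero (errors-in-variables);
        # the pooled estimate must sit near -2 within that known bias.
        w = recovery_weather.frame
        slopes = []
        for seed in range(20):
            win = synthetic.PlantedWindow(
                "tmin", 50, 25, slope=-2.0, intercept=120.0, residual_sd=1.0
            )
            occ = synthetic.gen_occurrences(
                w, win, n_grids=40, sightings_per_grid=3, year=2015, seed=seed
            )
            from phenosync.phenology import first_event, grid_occurrences

            g, _ = grid_occurrences(occ.frame)
            ev, _ = first_event(g)
            fit = windows.fit_window(ev, w, WindowSpec(50, 25, "tmin", "mean"))
            slopes.append(fit.slope)
        mean = np.mean(slopes)
        assert -2.3 < mean < -1.6

    def test_too_few_events(self, small_weather):
        events = _events_for(small_weather.frame, {"0_0": 100})
        with pytest.raises(SampleSizeError):
            windows.fit_window(events, small_weather.frame, WindowSpec(5, 0, "tmin", "mean"))


class TestBestWindow:
    def test_matches_brute_force_oracle(self, recovery_weather):
        w = recovery_weather.frame
        rng = np.random.default_rng(2)
        events = _events_for(
            w, {f"{i}_0": int(d) for i, d in enumerate(rng.integers(100, 140, 12))}
        )
        for statistic, variable in (("mean", "tmin"), ("sum", "tppt")):
            fit = windows.best_window(events, w, variable, statistic, max_lag=10)
            oracle = brute_force_best_window(events, w, variable, statistic, max_lag=10)
            assert (fit.spec.open_days, fit.spec.close_days) == (
                oracle["open"], oracle["close"],
            )
            assert fit.slope == pytest.approx(oracle["slope"], rel=1e-9)
            assert fit.aicc == pytest.approx(oracle["aicc"], rel=1e-9)

    def test_superset_never_increases_minimum(self, recovery_weather):
        w = recovery_weather.frame
        rng = np.random.default_rng(4)
        events = _events_for(
            w, {f"{i}_0": int(d) for i, d in enumerate(rng.integers(100, 140, 10))}
        )
        small = windows.best_window(events, w, "tmin", "mean", max_lag=20)
        big = windows.best_window(events, w, "tmin", "mean", max_lag=40)
        assert big.aicc <= small.aicc + 1e-9

    def test_selected_delta_is_minimum(self, recovery_weather):
        w = recovery_weather.frame
        rng = np.random.default_rng(5)
        events = _events_for(
            w, {f"{i}_0": int(d) for i, d in enumerate(rng.integers(100, 140, 8))}
        )
        best = windows.best_window(events, w, "tmin", "mean", max_lag=15)
        for o, c in windows.enumerate_windows(15):
            fit = windows.fit_window(events, w, WindowSpec(o, c, "tmin", "mean"))
            assert best.delta_aicc <= fit.delta_aicc + 1e-9


class TestRandomizationPc:
    def test_rank_formula_bounds(self):
        # pc uses (1 + hits) / (1 + n_rand): 0 hits of 19 -> 0.05
        assert (1 + 0) / (1 + 19) == pytest.approx(0.05)

    def test_pc_in_unit_interval(self, recovery_weather):
        w = recovery_weather.frame
        rng = np.random.default_rng(6)
        events = _events_for(
            w, {f"{i}_0": int(d) for i, d in enumerate(rng.integers(100, 140, 10))}
        )
        pc = windows.randomization_pc(events, w, "tmin", n_rand=5, seed=0, max_lag=20)
        assert 1 / 6 <= pc <= 1.0

    def test_cell_relabelling_invariance(self, recovery_weather):
        w = recovery_weather.frame.copy()
        rng = np.random.default_rng(7)
        days = {f"{i}_0": int(d) for i, d in enumerate(rng.integers(100, 140, 10))}
        events = _events_for(w, days)
        pc1 = windows.randomization_pc(events, w, "tmin", n_rand=9, seed=3, max_lag=15)
        # bijectively rename cells in both tables
        rename = {f"{i}_0": f"{i}_7" for i in range(40)}
        w2 = w.assign(cell_id=w["cell_id"].map(lambda c: rename.get(c, c)))
        e2 = events.assign(cell_id=events["cell_id"].map(rename))
        pc2 = windows.randomization_pc(e2, w2, "tmin", n_rand=9, seed=3, max_lag=15)
        assert pc1 == pc2

    def test_n_rand_too_small(self, recovery_weather):
        events = _events_for(recovery_weather.frame, {f"{i}_0": 100 for i in range(6)})
        with pytest.raises(SampleSizeError):
            windows.randomization_pc(
                events, recovery_weather.frame, "tmin", n_rand=3, seed=0, max_lag=5
            )


class TestWindowRecoveryProperty:
    def test_bias_shrinks_with_noise(self, recovery_weather):
        # planted (50, 25): midpoint bias at three residual noise levels
        w = recovery_weather.frame
        biases = []
        for residual_sd in (8.0, 3.0, 0.5):
            mids = []
            for seed in range(3):
                win = synthetic.PlantedWindow(
                    "tmin", 50, 25, slope=-2.0, intercept=120.0, residual_sd=residual_sd
                )
                occ = synthetic.gen_occurrences(
                    w, win, n_grids=40, sightings_per_grid=3, year=2015, seed=seed
                )
                from phenosync.phenology import first_event, grid_occurrences

                g, _ = grid_occurrences(occ.frame)
                ev, _ = first_event(g)
                fit = windows.best_window(ev, w, "tmin", "mean")
                mids.append((fit.spec.open_days + fit.spec.close_days) / 2)
            biases.append(abs(np.mean(mids) - 37.5))
        assert biases[-1] <= biases[0] + 2.0  # monotone up to simulation noise
        assert biases[-1] < 8.0
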