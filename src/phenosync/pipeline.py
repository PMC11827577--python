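"""Run configuration, stage orchestration and reproducible file I/O.

All tabular artefacts are UTF-8 CSV with ISO-8601 dates and deterministic
row ordering, so identical config + seed reproduces identical bytes.  A
single run seed deterministically derives per-stage substream seeds via
``numpy.random.SeedSequence([seed, stage_index])``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import date as Date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import phenosync
from phenosync import indices as idx
from phenosync import phenology, synthetic, weather, windows
from phenosync.errors import PhenosyncError, SchemaError

STAGES = (
    "simulate",
    "prep-weather",
    "extract-greenup",
    "extract-events",
    "windows",
    "indices",
    "network",
)

_STAGE_SEED_INDEX = {name: i for i, name in enumerate(STAGES)}

#: Small fixed roster used by the synthetic end-to-end run.
SYNTHETIC_ROSTER = pd.DataFrame(
    {
        "code": ["B1", "B2", "I1", "I2", "I3", "V1", "V2"],
        "common_name": [
            "Sim Bird 1", "Sim Bird 2", "Sim Insect 1", "Sim Insect 2",
            "Sim Insect 3", "Sim Vegetation 1", "Sim Vegetation 2",
        ],
        "group": ["bird", "bird", "insect", "insect", "insect",
                  "vegetation", "vegetation"],
        "trophic_level": [3, 3, 2, 2, 2, 1, 1],
    }
)

#: Planted windows for the synthetic animal species (variable, open, close,
#: slope, intercept day-of-year).
SYNTHETIC_WINDOWS = {
    "B1": ("tmin", 55, 25, -2.0, 120.0),
    "B2": ("tmin", 45, 20, -1.5, 110.0),
    "I1": ("tmin", 50, 25, -2.0, 100.0),
    "I2": ("tmax", 60, 30, -1.5, 95.0),
    "I3": ("tmin", 40, 15, -2.5, 105.0),
}

#: Planted green-up days for the synthetic vegetation groups.
SYNTHETIC_GREENUP = {"V1": 64, "V2": 95}


@dataclass
class RunConfig:
    """Parameters for a pipeline run; defaults follow the method's values."""

    seed: int = 0
    out_dir: str = "run"
    cell_size_km: float = 10.0
    min_per_grid: int = 3
    min_grids: int = 20
    max_lag: int = 180
    step: int = 1
    statistics: dict = field(
        default_factory=lambda: dict(windows.DEFAULT_STATISTICS)
    )
    n_rand: int = 19
    loess_span: float = 0.25
    lapse_rate: float = weather.STANDARD_LAPSE_RATE
    pool: str = "pair_class"
    # synthetic-run parameters
    sim_n_cells: int = 25
    sim_year: int = 2015
    sim_sightings_per_grid: int = 3
    sim_residual_sd: float = 1.0
    sim_noise_sd: float = 6.0
    sim_seasonal_amplitude: float = 4.0

    def to_yaml(self, path: Path) -> None:
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage substream seed from the run seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_SEED_INDEX[stage]])
    return int(ss.generate_state(1)[0])


def write_csv(frame: pd.DataFrame, path: Path, sort_by: list[str] | None = None) -> int:
    """Byte-stable CSV write: sorted rows, ISO dates, '.' decimals."""
    out = frame.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    if sort_by:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, index=False, float_format="%.10g")
    return len(out)


class PipelineRun:
    """Executes ordered pipeline stages inside one output directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": dataclasses.asdict(config),
            "config_sha256": config.digest(),
            "seed": config.seed,
            "version": phenosync.__version__,
            "outputs": {},
        }

    # -- helpers ----------------------------------------------------------

    def _emit(self, frame: pd.DataFrame, name: str, sort_by: list[str] | None = None) -> None:
        rows = write_csv(frame, self.out / name, sort_by=sort_by)
        self.manifest["outputs"][name] = rows

    def _need(self, name: str, stage: str) -> pd.DataFrame:
        path = self.out / name
        if not path.exists():
            raise PhenosyncError(
                f"stage {stage!r} requires missing artefact {name!r}; "
                "run its producing stage first"
            )
        return pd.read_csv(path)

    # -- stages -----------------------------------------------------------

    def simulate(self) -> None:
        cfg = self.config
        seed = stage_seed(cfg.seed, "simulate")
        year = cfg.sim_year
        wx_cfg = synthetic.WeatherSimConfig(
            n_cells=cfg.sim_n_cells,
            date_start=Date(year - 1, 1, 1),
            date_end=Date(year, 12, 31),
            noise_sd=cfg.sim_noise_sd,
            seasonal_amplitude=cfg.sim_seasonal_amplitude,
            seed=seed,
        )
        wx = synthetic.gen_weather(wx_cfg, granularity="daily")
        cells = wx.truth["cells"].copy()
        rng = np.random.default_rng(seed + 1)
        cells["model_elev"] = rng.uniform(50.0, 400.0, len(cells))
        frame = wx.frame.merge(cells[["cell_id", "model_elev"]], on="cell_id")
        self._emit(frame, "weather_daily.csv", sort_by=["cell_id", "date"])
        self._emit(cells, "cells.csv", sort_by=["cell_id"])

        dem = synthetic.gen_dem(
            n_points=400,
            extent_km=(0.0, 10.0 * cfg.sim_n_cells, 0.0, 10.0),
            seed=seed + 2,
        )
        self._emit(dem.frame, "dem_points.csv", sort_by=["x_km", "y_km"])

        ndvi_frames = []
        for i, (code, gu) in enumerate(sorted(SYNTHETIC_GREENUP.items())):
            for j, y in enumerate((year - 1, year, year + 1)):
                sim = synthetic.gen_ndvi(
                    green_up_day=gu, noise_sd=0.01, missing_rate=0.2,
                    seed=seed + 10 * i + j, year=y, polygon_id=code,
                )
                ndvi_frames.append(sim.frame)
        self._emit(
            pd.concat(ndvi_frames, ignore_index=True), "ndvi.csv",
            sort_by=["polygon_id", "date"],
        )

        occ_frames = []
        truth_rows = []
        for k, (code, (var, op, cl, slope, intercept)) in enumerate(
            sorted(SYNTHETIC_WINDOWS.items())
        ):
            window = synthetic.PlantedWindow(
                variable=var, open_days=op, close_days=cl,
                slope=slope, intercept=intercept, residual_sd=cfg.sim_residual_sd,
            )
            occ = synthetic.gen_occurrences(
                wx.frame, window, n_grids=cfg.sim_n_cells,
                sightings_per_grid=cfg.sim_sightings_per_grid,
                year=year, seed=seed + 100 + k, species=code,
            )
            occ_frames.append(occ.frame)
            truth_rows.append(
                {"species": code, "variable": var, "open_days": op, "close_days": cl,
                 "slope": slope, "intercept": intercept}
            )
        self._emit(
            pd.concat(occ_frames, ignore_index=True), "occurrences.csv",
            sort_by=["species", "date", "x_km"],
        )
        self._emit(pd.DataFrame(truth_rows), "planted_windows.csv", sort_by=["species"])
        self._emit(SYNTHETIC_ROSTER, "roster.csv", sort_by=["code"])

    def prep_weather(self) -> None:
        daily = self._need("weather_daily.csv", "prep-weather")
        cells = self._need("cells.csv", "prep-weather")
        dem = self._need("dem_points.csv", "prep-weather")
        regrid = weather.regrid_dem_nearest(dem, cells)
        daily = daily.merge(regrid, on="cell_id")
        if "model_elev" not in daily.columns:
            daily = daily.merge(cells[["cell_id", "model_elev"]], on="cell_id")
        corrected = weather.correct_temperature(daily, lapse_rate=self.config.lapse_rate)
        self._emit(corrected, "weather_corrected.csv", sort_by=["cell_id", "date"])

    def extract_greenup(self) -> None:
        ndvi = self._need("ndvi.csv", "extract-greenup")
        events = phenology.extract_greenup(ndvi, span=self.config.loess_span)
        self._emit(events, "greenup_events.csv", sort_by=["polygon_id", "year"])

    def extract_events(self) -> None:
        records = self._need("occurrences.csv", "extract-events")
        gridded, rejected = phenology.grid_occurrences(
            records, cell_size_km=self.config.cell_size_km
        )
        events, exclusions = phenology.first_event(
            gridded,
            min_per_grid=self.config.min_per_grid,
            min_grids=self.config.min_grids,
        )
        self.manifest["rejected_occurrence_rows"] = rejected
        self._emit(events, "events.csv", sort_by=["species", "year", "cell_id"])
        self._emit(exclusions, "exclusions.csv", sort_by=["species", "year"])

    def windows_stage(self) -> None:
        events = self._need("events.csv", "windows")
        wx = self._need("weather_corrected.csv", "windows")
        cfg = self.config
        seed = stage_seed(cfg.seed, "windows")
        rows = []
        for (species, year), sub in events.groupby(["species", "year"]):
            for var in ("tmin", "tmax", "tppt"):
                stat = cfg.statistics.get(var, "mean")
                if cfg.n_rand >= 5:
                    fit = windows.fit_with_pc(
                        sub, wx, var, stat, n_rand=cfg.n_rand, seed=seed,
                        max_lag=cfg.max_lag, step=cfg.step,
                        species=species, year=int(year),
                    )
                else:
                    fit = windows.best_window(
                        sub, wx, var, stat, max_lag=cfg.max_lag, step=cfg.step
                    )
                rows.append(
                    {
                        "species": species,
                        "year": int(year),
                        "n": fit.n,
                        "variable": var,
                        "statistic": stat,
                        "window_open": fit.spec.open_days,
                        "window_close": fit.spec.close_days,
                        "slope": fit.slope,
                        "delta_aicc": fit.delta_aicc,
                        "pc": fit.pc if fit.pc is not None else np.nan,
                    }
                )
        self._emit(
            pd.DataFrame(rows), "window_fits.csv",
            sort_by=["species", "year", "variable"],
        )

    def indices_stage(self) -> None:
        events = self._need("events.csv", "indices")
        greenup = self._need("greenup_events.csv", "indices")
        fits = self._need("window_fits.csv", "indices")
        roster = self._need("roster.csv", "indices")
        cfg = self.config

        summaries = phenology.summarize_events(events)
        gu = greenup.rename(columns={"polygon_id": "species"})
        gu_sum = (
            gu.groupby(["species", "year"])["event_day"].median().rename("median").reset_index()
        )
        summaries = pd.concat(
            [summaries[["species", "year", "median"]], gu_sum], ignore_index=True
        )

        al_table = idx.compute_al_table(summaries, roster)
        scored = idx.standardize_al_table(al_table, pool=cfg.pool)
        scored["pool_mode"] = cfg.pool
        self._emit(
            scored, "al_scores.csv",
            sort_by=["pair_class", "species_hi", "species_lo", "year"],
        )

        # QAI per bird-insect pair: median AL' over years on each leg.
        med = (
            scored.groupby(["species_hi", "species_lo", "pair_class"])["al_prime"]
            .median()
            .reset_index()
        )
        birds = roster.loc[roster["trophic_level"] == 3, "code"]
        insects = roster.loc[roster["trophic_level"] == 2, "code"]
        bi = med[med["pair_class"] == "bird-insect"].set_index(
            ["species_hi", "species_lo"]
        )["al_prime"]
        iv = med[med["pair_class"] == "insect-vegetation"]
        qai_rows = []
        for b in birds:
            for i in insects:
                ab = bi.get((b, i))
                if ab is None or pd.isna(ab):
                    continue
                legs = iv[iv["species_hi"] == i]["al_prime"]
                if legs.empty:
                    continue
                labels = [idx.classify_sync(v) for v in legs]
                summary = " ".join(
                    f"{s}{labels.count(s)}" for s in ("S", "A") if labels.count(s)
                )
                qai_rows.append(
                    {
                        "bird": b,
                        "insect": i,
                        "al_prime_32": float(ab),
                        "qai": idx.classify_sync(float(ab))
                        + idx.classify_sync(float(legs.median())),
                        "al21_summary": summary,
                    }
                )
        qai_df = pd.DataFrame(qai_rows)
        self._emit(qai_df, "qai.csv", sort_by=["bird", "insect"])

        # IICWM per bird-insect pair per year.
        med_al = (
            scored[scored["pair_class"] == "bird-insect"]
            .groupby(["species_hi", "species_lo", "year"])["al"]
            .median()
            .reset_index()
        )
        wo_open = fits.pivot_table(
            index=["species", "year"], columns="variable", values="window_open"
        )
        rows = []
        for rec in med_al.itertuples(index=False):
            key_b = (rec.species_hi, rec.year)
            key_i = (rec.species_lo, rec.year)
            if key_b not in wo_open.index or key_i not in wo_open.index:
                continue
            bird_wo = wo_open.loc[key_b].to_dict()
            insect_wo = wo_open.loc[key_i].to_dict()
            try:
                wo = idx.wo_composite(bird_wo, insect_wo)
                value, category = idx.iicwm(rec.al, wo)
            except PhenosyncError:
                wo, value, category = np.nan, np.nan, "undefined"
            rows.append(
                {
                    "bird": rec.species_hi,
                    "insect": rec.species_lo,
                    "year": int(rec.year),
                    "al": rec.al,
                    "wo": wo,
                    "iicwm": value,
                    "category": category,
                }
            )
        self._emit(pd.DataFrame(rows), "iicwm.csv", sort_by=["bird", "insect", "year"])

    def network_stage(self) -> None:
        scored = self._need("al_scores.csv", "network")
        roster = self._need("roster.csv", "network")
        med = (
            scored.groupby(["species_hi", "species_lo"])["al_prime"].median().reset_index()
        )
        import networkx as nx

        edge_frames = []
        for mode in ("sync", "async"):
            graph, edges = idx.build_network(med, mode, roster)
            edge_frames.append(edges)
            nx.write_graphml(graph, self.out / f"network_{mode}.graphml")
        self._emit(
            pd.concat(edge_frames, ignore_index=True), "network_edges.csv",
            sort_by=["mode", "source", "target"],
        )

    # -- driver -----------------------------------------------------------

    _DISPATCH = {
        "simulate": simulate,
        "prep-weather": prep_weather,
        "extract-greenup": extract_greenup,
        "extract-events": extract_events,
        "windows": windows_stage,
        "indices": indices_stage,
        "network": network_stage,
    }

    def run(self, stages: list[str] | None = None) -> dict:
        chosen = list(STAGES) if stages is None else list(stages)
        unknown = set(chosen) - set(STAGES)
        if unknown:
            raise SchemaError(f"unknown stages {sorted(unknown)}")
        chosen.sort(key=STAGES.index)
        for name in chosen:
            self._DISPATCH[name](self)
        manifest_path = self.out / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return self.manifest


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order and write a manifest."""
    return PipelineRun(config).run(stages)


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "ndvi": {"polygon_id", "date", "ndvi"},
    "occurrences": {"species", "date", "x_km", "y_km"},
    "weather_daily": {"cell_id", "date", "tmax", "tmin", "tppt"},
    "weather_hourly": {"cell_id", "timestamp", "temp_c", "precip_mm"},
}


def validate_inputs(path: str | Path, schema_name: str) -> list[dict]:
    """Schema, range, monotone-date and duplicate checks for an input CSV.

    Returns a list of issue dicts (empty = clean).  Row numbers are 1-based
    data rows (header excluded).
    """
    if schema_name not in _SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}; know {sorted(_SCHEMAS)}")
    df = pd.read_csv(path)
    issues: list[dict] = []
    missing = _SCHEMAS[schema_name] - set(df.columns)
    if missing:
        issues.append({"issue": "missing-columns", "detail": sorted(missing)})
        return issues

    def flag(mask: pd.Series, issue: str) -> None:
        for i in df.index[mask]:
            issues.append({"issue": issue, "row": int(i) + 1})

    if schema_name == "ndvi":
        flag(df["ndvi"].notna() & ~df["ndvi"].between(-1, 1), "ndvi-out-of-range")
        dates = pd.to_datetime(df["date"], errors="coerce")
        flag(dates.isna(), "unparseable-date")
        for polygon, sub in df.assign(_d=dates).groupby("polygon_id"):
            if not sub["_d"].is_monotonic_increasing:
                issues.append({"issue": "dates-not-increasing", "detail": str(polygon)})
            dup = sub["_d"].duplicated()
            for i in sub.index[dup]:
                issues.append({"issue": "duplicate-date", "row": int(i) + 1})
    elif schema_name == "occurrences":
        flag(df["x_km"].isna() | df["y_km"].isna(), "missing-coordinate")
        flag(pd.to_datetime(df["date"], errors="coerce").isna(), "unparseable-date")
    elif schema_name == "weather_daily":
        flag(df["tmax"] < df["tmin"], "tmax-below-tmin")
        flag(df["tppt"] < 0, "negative-precipitation")
        dup = df.duplicated(subset=["cell_id", "date"])
        flag(dup, "duplicate-cell-date")
    elif schema_name == "weather_hourly":
        flag(df["precip_mm"] < 0, "negative-precipitation")
        flag(pd.to_datetime(df["timestamp"], errors="coerce", utc=True).isna(),
             "unparseable-timestamp")
    return issues
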