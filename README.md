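# phenosync

Trophic phenological synchrony/asynchrony indices with a meteorological
dimension: extraction of phenological event dates (vegetation green-up from
NDVI, insect first flight and bird arrival from occurrence records), a
relative sliding time-window regression engine that identifies the critical
weather window preceding each event, and an interaction-index family
(AL, AL′, QAI, WO, IICWM) with weighted synchrony-network export.

## What is in the box

| Module | Purpose |
| --- | --- |
| `phenosync.synthetic` | Simulators for gridded weather, double-logistic NDVI, DEM surfaces and occurrence records with planted ground truth |
| `phenosync.weather` | Hourly → daily TMAX/TMIN/TPPT aggregation on the 09 UTC convention; nearest-neighbour DEM regridding; 6.49 K/km lapse-rate correction |
| `phenosync.phenology` | Monthly-max NDVI compositing, climatology gap filling, LOESS smoothing and daily interpolation, half-amplitude green-up; 10 km gridding, inclusion filters (≥3 sightings/grid, ≥20 grids/species-year), earliest-date events |
| `phenosync.windows` | Exhaustive relative window search (0–180 days before each record's own event), per-window OLS, AICc selection, permutation significance (`Pc`) |
| `phenosync.indices` | AL / AL′ / QAI / WO / IICWM with the three-symbol (+, −, \*) categorisation; packaged species roster and 90-row classification fixtures; network export |
| `phenosync.pipeline`, `phenosync.cli` | Stage orchestration, YAML config, byte-stable CSV artefacts, manifest, validation |

## CLI

```sh
phenosync run --seed 1 --out run1            # full synthetic end-to-end run
phenosync simulate --seed 1 --out run1       # any single stage also works
phenosync tally                              # packaged classification table
phenosync validate run1/ndvi.csv ndvi        # schema/range checks, exit 1 on issues
```

Stages (in order): `simulate`, `prep-weather`, `extract-greenup`,
`extract-events`, `windows`, `indices`, `network`. Each stage reads and
writes CSV artefacts in the output directory and the run writes a
`manifest.json` (config hash, seed, row counts). Identical config + seed
reproduces identical bytes. Exit codes: 0 ok, 1 validation failure,
2 runtime error.

## Conventions worth knowing

- Day-of-year: 1 January = day 1; window day 0 is the event day itself;
  windows are inclusive on both ends, `open ≥ close`.
- Daily weather: tmax/tppt over [D 09:00, D+1 09:00) UTC assigned to day D;
  tmin over the same window assigned to day D+1; incomplete windows are
  dropped, never partially aggregated.
- Monthly NDVI composites keep the date of the retained maximum observation
  by default (`day_convention="argmax"`), which preserves the timing of the
  underlying curve; a fixed mid-month convention is available.
- Aggregate statistics default to mean for TMIN/TMAX and sum for TPPT.
- `Pc` is a permutation estimate with the +1 correction,
  `(1 + #{permuted Δ ≤ observed Δ}) / (1 + n_rand)`.
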