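"""The synchrony-asynchrony index family and trophic-network export.

* ``al_index`` -- signed day gap between a higher- and lower-trophic-level
  event (positive when the higher level follows the lower level).
* ``standardize_al`` -- min-max standardisation of an AL pool to [0, 1];
  0 is total asynchrony, 0.5 perfect synchrony, 1 delayed synchrony.
* ``classify_sync`` / ``qai`` -- the A/S labelling and its two-letter
  concatenation across the bird-insect and insect-vegetation levels.
* ``wo_composite`` / ``iicwm`` -- the window-open composite and the
  ratio index with its three-symbol (+, -, *) categorisation.
* ``build_network`` -- weighted synchrony/asynchrony edge lists.
* ``tally_classifications`` -- category histogram of a packaged
  classification table.
"""

from __future__ import annotations

from importlib import resources

import networkx as nx
import numpy as np
import pandas as pd

from phenosync.errors import (
    DegenerateSeriesError,
    MissingWindowError,
    SchemaError,
)

WO_VARIABLES = ("tmin", "tmax", "tppt")

PAIR_CLASSES = {
    (3, 2): "bird-insect",
    (2, 1): "insect-vegetation",
    (3, 1): "bird-vegetation",
}


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def load_roster() -> pd.DataFrame:
    """The packaged species roster: code, common_name, group, trophic_level."""
    with resources.files("phenosync.data").joinpath("species_roster.csv").open() as fh:
        roster = pd.read_csv(fh)
    if roster["code"].duplicated().any():
        raise SchemaError("roster codes must be unique")
    return roster


def load_iicwm_table() -> pd.DataFrame:
    """The packaged 90-row bird-insect classification table."""
    with resources.files("phenosync.data").joinpath("iicwm_classifications.csv").open() as fh:
        table = pd.read_csv(fh)
    required = {"bird", "insect", "al32", "al21", "iicwm"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"classification table missing columns {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# AL family
# ---------------------------------------------------------------------------

def al_index(event_hi: float, event_lo: float) -> float:
    """Signed gap in days: positive when the higher-level event is later."""
    return event_hi - event_lo


def standardize_al(scores) -> np.ndarray:
    """Min-max standardise a pool of AL values to [0, 1]."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise DegenerateSeriesError("standardisation pool needs at least 2 values")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateSeriesError("standardisation pool has zero range")
    return (arr - lo) / (hi - lo)


def classify_sync(al_prime: float) -> str:
    """'A' (asynchrony) below 0.5, 'S' (synchrony) at or above 0.5."""
    if not 0.0 <= al_prime <= 1.0:
        raise SchemaError(f"al_prime must be in [0, 1], got {al_prime}")
    return "S" if al_prime >= 0.5 else "A"


def qai(al_prime_ab: float, al_prime_bc: float) -> str:
    """Two-letter qualitative integrated (a)synchrony category."""
    return classify_sync(al_prime_ab) + classify_sync(al_prime_bc)


def cross_trophic_pairs(roster: pd.DataFrame | None = None) -> pd.DataFrame:
    """All higher-vs-lower trophic pairs from the roster.

    Columns: species_hi, species_lo, level_hi, level_lo, pair_class.  The
    full roster yields 90 bird-insect + 126 insect-vegetation +
    35 bird-vegetation = 251 combinations.
    """
    if roster is None:
        roster = load_roster()
    rows = []
    by_level = {
        level: roster.loc[roster["trophic_level"] == level, "code"].tolist()
        for level in (1, 2, 3)
    }
    for (hi, lo), name in PAIR_CLASSES.items():
        for a in by_level[hi]:
            for b in by_level[lo]:
                rows.append(
                    {
                        "species_hi": a,
                        "species_lo": b,
                        "level_hi": hi,
                        "level_lo": lo,
                        "pair_class": name,
                    }
                )
    return pd.DataFrame(rows)


def compute_al_table(
    summaries: pd.DataFrame, roster: pd.DataFrame | None = None
) -> pd.DataFrame:
    """AL per cross-trophic pair per year from national event summaries.

    ``summaries`` needs columns species, year, median (one national event
    day per species-year, as produced by ``summarize_events``).  Pairs are
    scored in every year where both species have a summary.
    """
    if roster is None:
        roster = load_roster()
    required = {"species", "year", "median"}
    missing = required - set(summaries.columns)
    if missing:
        raise SchemaError(f"summaries missing columns {sorted(missing)}")
    pairs = cross_trophic_pairs(roster)
    med = summaries.set_index(["species", "year"])["median"]
    rows = []
    years = sorted(summaries["year"].unique())
    for pair in pairs.itertuples(index=False):
        for year in years:
            hi = med.get((pair.species_hi, year))
            lo = med.get((pair.species_lo, year))
            if hi is None or lo is None or pd.isna(hi) or pd.isna(lo):
                continue
            rows.append(
                {
                    "species_hi": pair.species_hi,
                    "species_lo": pair.species_lo,
                    "pair_class": pair.pair_class,
                    "year": year,
                    "al": al_index(float(hi), float(lo)),
                }
            )
    return pd.DataFrame(
        rows, columns=["species_hi", "species_lo", "pair_class", "year", "al"]
    )


def standardize_al_table(al_table: pd.DataFrame, pool: str = "pair_class") -> pd.DataFrame:
    """Attach AL' by min-max standardising within the chosen pool.

    ``pool="pair_class"`` (default) pools all AL values of the same index
    family across species pairs and years; ``pool="pair"`` standardises each
    species pair over its own years.
    """
    if pool not in ("pair_class", "pair"):
        raise SchemaError(f"pool must be 'pair_class' or 'pair', got {pool!r}")
    keys = ["pair_class"] if pool == "pair_class" else ["species_hi", "species_lo"]
    out = al_table.copy()
    out["al_prime"] = np.nan
    for _, idx in out.groupby(keys).groups.items():
        out.loc[idx, "al_prime"] = standardize_al(out.loc[idx, "al"].to_numpy())
    out["label"] = [classify_sync(v) for v in out["al_prime"]]
    return out


# ---------------------------------------------------------------------------
# IICWM
# ---------------------------------------------------------------------------

def wo_composite(
    bird_wo: dict, insect_wo: dict, drop_missing: bool = False
) -> float:
    """Sum over TMIN/TMAX/TPPT of bird-minus-insect window-open differences.

    Positive means bird windows sit further in the past and/or insect
    windows closer to first flight (scenario A).  Missing components raise
    unless ``drop_missing`` is set, in which case the variable is dropped
    from both sides symmetrically.
    """
    total = 0.0
    used = 0
    for var in WO_VARIABLES:
        b = bird_wo.get(var)
        i = insect_wo.get(var)
        if b is None or i is None or pd.isna(b) or pd.isna(i):
            if drop_missing:
                continue
            raise MissingWindowError(f"window-open component {var!r} missing")
        total += float(b) - float(i)
        used += 1
    if used == 0:
        raise MissingWindowError("no window-open components available")
    return total


def iicwm(al: float, wo: float) -> tuple[float, str]:
    """The ratio index AL/WO with its categorisation.

    '+' : synchronous (al >= 0) under scenario A (wo > 0)
    '*' : asynchronous (al < 0) under scenario B (wo < 0)
    '-' : the two mixed cases
    """
    if wo == 0:
        raise MissingWindowError("WO composite is zero: IICWM undefined (boundary case)")
    value = al / wo
    if al >= 0 and wo > 0:
        category = "+"
    elif al < 0 and wo < 0:
        category = "*"
    else:
        category = "-"
    return value, category


# ---------------------------------------------------------------------------
# Networks & tallies
# ---------------------------------------------------------------------------

def build_network(
    scores: pd.DataFrame, mode: str, roster: pd.DataFrame | None = None
) -> tuple[nx.Graph, pd.DataFrame]:
    """Weighted synchrony or asynchrony network from median AL' scores.

    ``scores`` needs columns species_hi, species_lo, al_prime (one row per
    pair, typically the median over years).  Sync mode keeps pairs with
    AL' >= 0.5 weighted ``1 - 2*|AL' - 0.5|`` (thickest at perfect
    synchrony); async mode keeps AL' < 0.5 weighted ``1 - 2*AL'`` (thickest
    at total asynchrony).  Every pair lands in exactly one of the two
    networks; nodes carry trophic_level attributes.
    """
    if mode not in ("sync", "async"):
        raise SchemaError(f"mode must be 'sync' or 'async', got {mode!r}")
    if roster is None:
        roster = load_roster()
    levels = roster.set_index("code")["trophic_level"].to_dict()
    groups = roster.set_index("code")["group"].to_dict()

    graph = nx.Graph(mode=mode)
    rows = []
    for rec in scores.itertuples(index=False):
        ap = float(rec.al_prime)
        if mode == "sync" and ap >= 0.5:
            weight = 1.0 - 2.0 * abs(ap - 0.5)
        elif mode == "async" and ap < 0.5:
            weight = 1.0 - 2.0 * ap
        else:
            continue
        for node in (rec.species_hi, rec.species_lo):
            if node not in graph:
                graph.add_node(
                    node,
                    trophic_level=int(levels.get(node, 0)),
                    group=str(groups.get(node, "unknown")),
                )
        graph.add_edge(rec.species_hi, rec.species_lo, weight=weight, al_prime=ap)
        rows.append(
            {
                "source": rec.species_hi,
                "target": rec.species_lo,
                "weight": weight,
                "al_prime": ap,
                "mode": mode,
            }
        )
    edges = pd.DataFrame(rows, columns=["source", "target", "weight", "al_prime", "mode"])
    return graph, edges


def _summary_has_sync(al21_summary: str) -> bool:
    """Whether an insect-vegetation summary string contains any S pairing."""
    return any(tok.startswith("S") for tok in str(al21_summary).split())


def tally_classifications(table: pd.DataFrame) -> dict:
    """Histogram of IICWM symbols plus the fully-synchronous row count.

    A row is fully synchronous when its bird-insect label is S and its
    insect-vegetation summary includes at least one synchronous vegetation
    pairing.
    """
    required = {"al32", "al21", "iicwm"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"classification table missing columns {sorted(missing)}")
    symbols = table["iicwm"].astype(str).str.strip()
    bad = sorted(set(symbols) - {"+", "-", "*"}) if len(symbols) else []
    if bad:
        raise SchemaError(f"unknown IICWM symbols {bad}")
    counts = {sym: int((symbols == sym).sum()) for sym in ("+", "-", "*")}
    fully = int(
        (
            (table["al32"].astype(str).str.strip() == "S")
            & table["al21"].map(_summary_has_sync)
        ).sum()
    )
    counts["fully_synchronous"] = fully
    counts["n"] = int(len(table))
    return counts
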