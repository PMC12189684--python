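"""Catch-per-unit-effort metrics and seasonal survey summaries.

Definitions follow standard trawl-survey practice: CPUE by weight
(CPUE_w, g/h) and by number (CPUE_n, ind/h) per standardized tow, and the
average individual weight AIW = CPUE_w / CPUE_n at each station (g/ind).
Seasonal summaries report totals over all stations and means/ranges over
"collection stations" — stations where the species was actually caught.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEASON_ORDER = ["spring", "summer", "autumn", "winter"]

#: allometric length-weight coefficients for Uroteuthis edulis:
#: W (g) = LW_A * L(mm) ** LW_B
LW_A = 2.559e-3
LW_B = 2.185

REQUIRED_COLUMNS = [
    "station_id", "lat", "lon", "season", "tow_duration", "count", "weight",
]


def cpue(weight: float, count: float, tow_duration: float) -> tuple[float, float]:
    """CPUE by weight (g/h) and by number (ind/h) for one tow.

    Raises ValueError on non-positive tow duration.
    """
    if tow_duration <= 0:
        raise ValueError("tow_duration must be positive")
    return weight / tow_duration, count / tow_duration


def aiw(cpue_w: float, cpue_n: float) -> float:
    """Average individual weight (g/ind) at a station.

    Undefined at zero-catch stations: returns NaN so such stations drop
    out of AIW summaries.
    """
    if cpue_n == 0:
        return float("nan")
    return cpue_w / cpue_n


def station_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Per-station CPUE_w, CPUE_n, AIW columns appended to a copy."""
    _validate(records)
    out = records.copy()
    out["cpue_w"] = out["weight"] / out["tow_duration"]
    out["cpue_n"] = out["count"] / out["tow_duration"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["aiw"] = np.where(out["cpue_n"] > 0, out["cpue_w"] / out["cpue_n"], np.nan)
    return out


@dataclass
class SeasonalSummary:
    """Totals over all stations and means/ranges over collection stations.

    ``per_season`` is indexed by season with columns total_cpue_w,
    total_cpue_n, n_stations, n_collection, mean/min/max of cpue_w, cpue_n
    and aiw at collection stations (NaN when a season has no catches).
    """

    per_season: pd.DataFrame
    grand_total_cpue_w: float
    grand_total_cpue_n: float

    def to_frame(self) -> pd.DataFrame:
        out = self.per_season.copy()
        total = {c: np.nan for c in out.columns}
        total["total_cpue_w"] = self.grand_total_cpue_w
        total["total_cpue_n"] = self.grand_total_cpue_n
        out.loc["total"] = pd.Series(total)
        return out


def _validate(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"survey table lacks columns: {missing}")
    if len(records) == 0:
        raise ValueError("empty survey table")
    if (records["tow_duration"] <= 0).any():
        raise ValueError("non-positive tow duration")
    if (records["count"] < 0).any() or (records["weight"] < 0).any():
        raise ValueError("negative catch")


def _season_key(seasons: pd.Index) -> list[str]:
    known = [s for s in SEASON_ORDER if s in set(seasons)]
    extra = sorted(set(seasons) - set(SEASON_ORDER))
    return known + extra


def seasonal_summary(records: pd.DataFrame) -> SeasonalSummary:
    """Seasonal totals of CPUE and collection-station means/ranges.

    Totals sum station CPUE values over every station fished in the
    season; means and ranges use only stations with a positive catch.
    Grand totals equal the sum of seasonal totals by construction.
    """
    tbl = station_metrics(records)
    rows = {}
    for season, grp in tbl.groupby("season", sort=False):
        caught = grp[grp["count"] > 0]
        row = {
            "total_cpue_w": float(grp["cpue_w"].sum()),
            "total_cpue_n": float(grp["cpue_n"].sum()),
            "n_stations": int(len(grp)),
            "n_collection": int(len(caught)),
        }
        for col in ("cpue_w", "cpue_n", "aiw"):
            vals = caught[col].dropna()
            row[f"mean_{col}"] = float(vals.mean()) if len(vals) else np.nan
            row[f"min_{col}"] = float(vals.min()) if len(vals) else np.nan
            row[f"max_{col}"] = float(vals.max()) if len(vals) else np.nan
        rows[season] = row
    per_season = pd.DataFrame.from_dict(rows, orient="index")
    per_season = per_season.loc[_season_key(per_season.index)]
    return SeasonalSummary(
        per_season=per_season,
        grand_total_cpue_w=float(per_season["total_cpue_w"].sum()),
        grand_total_cpue_n=float(per_season["total_cpue_n"].sum()),
    )


ENV_VARS = ["depth", "sst", "sbt", "sss", "sbs"]


def env_range_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Seasonal min-max of environmental variables at presence stations.

    Returns a DataFrame indexed by season with ``<var>_min`` / ``<var>_max``
    columns; seasons without any presence yield NaN entries (printed
    reports use "/" for those).
    """
    _validate(records)
    present_vars = [v for v in ENV_VARS if v in records.columns]
    rows = {}
    for season, grp in records.groupby("season", sort=False):
        caught = grp[grp["count"] > 0]
        row = {}
        for v in present_vars:
            vals = caught[v].dropna()
            row[f"{v}_min"] = float(vals.min()) if len(vals) else np.nan
            row[f"{v}_max"] = float(vals.max()) if len(vals) else np.nan
        rows[season] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    return out.loc[_season_key(out.index)]


def weight_from_mantle_length(length_mm: float) -> float:
    """Wet weight (g) from mantle length (mm): W = a * L**b."""
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(length_mm <= 0):
        raise ValueError("mantle length must be positive")
    return LW_A * length_mm**LW_B


def mantle_length_from_weight(weight_g: float) -> float:
    """Mantle length (mm) from wet weight (g), inverting W = a * L**b."""
    weight_g = np.asarray(weight_g, dtype=float)
    if np.any(weight_g <= 0):
        raise ValueError("weight must be positive")
    return (weight_g / LW_A) ** (1.0 / LW_B)


def write_survey_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_survey_csv(path) -> pd.DataFrame:
    records = pd.read_csv(path)
    _validate(records)
    return records
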