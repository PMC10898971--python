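"""Encounter ingestion and condensation to one capture per individual-season.

An *encounter* is one photographic identification of an individual: an ID,
a calendar date and a position (plus an optional stratum override).  For
two-occasion estimation, all of an individual's encounters within one season
of one year are *condensed* to a single capture, keeping the encounter whose
date is closest to the seasonal midpoint (1 March for winter, 1 August for
summer).  The surviving encounter also fixes the individual's geographic
stratum for that season-year.

Season windows are a convention: the year is split symmetrically between the
two midpoints, so winter of year *y* runs 16 October of *y−1* through
15 May of *y*, and summer of *y* runs 16 May through 15 October of *y*.
Every calendar date therefore maps to exactly one (season, season-year).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .strata import SUMMER, WINTER, StrataConfig

ENCOUNTER_COLUMNS = ["individual_id", "date", "latitude", "longitude"]
CAPTURE_COLUMNS = ["individual_id", "season", "season_year", "stratum", "capture_date"]

#: (month, day) of the seasonal midpoints.
WINTER_MIDPOINT = (3, 1)
SUMMER_MIDPOINT = (8, 1)
#: Summer window bounds, inclusive; winter is the complement of the year.
SUMMER_START = (5, 16)
SUMMER_END = (10, 15)


def season_midpoint(season: str, season_year: int) -> dt.date:
    month, day = WINTER_MIDPOINT if season == WINTER else SUMMER_MIDPOINT
    return dt.date(season_year, month, day)


def assign_season(date: dt.date) -> tuple[str, int]:
    """Map a calendar date to its (season, season_year).

    Winter of year ``y`` spans 16 Oct (y−1) … 15 May (y); summer of ``y``
    spans 16 May … 15 Oct (y).
    """
    md = (date.month, date.day)
    if SUMMER_START <= md <= SUMMER_END:
        return SUMMER, date.year
    if md > SUMMER_END:
        return WINTER, date.year + 1
    return WINTER, date.year


def _assign_season_frame(dates: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Vectorised :func:`assign_season` over a datetime series."""
    md = dates.dt.month * 100 + dates.dt.day
    lo = SUMMER_START[0] * 100 + SUMMER_START[1]
    hi = SUMMER_END[0] * 100 + SUMMER_END[1]
    is_summer = (md >= lo) & (md <= hi)
    season = pd.Series(np.where(is_summer, SUMMER, WINTER), index=dates.index)
    year = dates.dt.year + ((~is_summer) & (md > hi)).astype(int)
    return season, year


@dataclass
class CondenseReport:
    """Bookkeeping of rows dropped while condensing encounters to captures."""

    n_encounters: int = 0
    n_captures: int = 0
    n_duplicates: int = 0
    n_unassigned: int = 0
    n_class_mismatch: int = 0
    n_out_of_range: int = 0
    unassigned: pd.DataFrame = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "n_encounters": self.n_encounters,
            "n_captures": self.n_captures,
            "n_duplicates": self.n_duplicates,
            "n_unassigned": self.n_unassigned,
            "n_class_mismatch": self.n_class_mismatch,
            "n_out_of_range": self.n_out_of_range,
        }


def read_encounters(path, delimiter: str = ",") -> pd.DataFrame:
    """Read an encounter table from delimited text.

    Expected header: ``individual_id,date,latitude,longitude[,stratum]``
    with ISO-8601 dates.
    """
    df = pd.read_csv(path, sep=delimiter, dtype={"individual_id": str})
    missing = [c for c in ENCOUNTER_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    validate_encounters(df)
    return df


def validate_encounters(df: pd.DataFrame) -> None:
    if df["individual_id"].isna().any() or (df["individual_id"] == "").any():
        raise ValidationError("individual_id must be non-empty")
    if df["date"].isna().any():
        raise ValidationError("encounter dates contain unparseable values")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise ValidationError("latitude out of [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise ValidationError("longitude out of [-180, 180]")


def condense(
    encounters: pd.DataFrame,
    strata: StrataConfig,
    season_years: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, CondenseReport]:
    """Condense encounters to one capture per (individual, season, season-year).

    Steps: assign season-years; drop season-years outside ``season_years``
    (if given); resolve each encounter's stratum (an explicit ``stratum``
    column overrides the spatial lookup); drop encounters falling in no
    stratum or in a stratum of the opposite season class; then keep, per
    (individual, season, season-year), the encounter closest to the seasonal
    midpoint (ties: earlier date).

    Returns the capture table (columns ``individual_id, season, season_year,
    stratum, capture_date``) and a :class:`CondenseReport`.
    """
    report = CondenseReport(n_encounters=len(encounters))
    if encounters.empty:
        report.unassigned = pd.DataFrame(columns=ENCOUNTER_COLUMNS)
        return pd.DataFrame(columns=CAPTURE_COLUMNS), report

    df = encounters.copy()
    df["date"] = pd.to_datetime(df["date"])
    validate_encounters(df)
    df["season"], df["season_year"] = _assign_season_frame(df["date"])

    if season_years is not None:
        first, last = season_years
        in_range = (df["season_year"] >= first) & (df["season_year"] <= last)
        report.n_out_of_range = int((~in_range).sum())
        df = df[in_range]

    # stratum resolution: override column wins, else first containing extent
    if "stratum" in df.columns:
        assigned = df["stratum"].astype("object").where(df["stratum"].notna())
        unknown = assigned.dropna()[~assigned.dropna().isin(strata.names())]
        if len(unknown):
            raise ValidationError(
                f"unknown stratum override(s): {sorted(set(unknown))}"
            )
    else:
        assigned = pd.Series(pd.NA, index=df.index, dtype="object")
    todo = assigned.isna()
    if todo.any():
        lats = df.loc[todo, "latitude"].to_numpy()
        lons = df.loc[todo, "longitude"].to_numpy()
        found = np.full(len(lats), None, dtype=object)
        remaining = np.ones(len(lats), dtype=bool)
        for s in strata:
            if not remaining.any():
                break
            idx = np.flatnonzero(remaining)
            hit = np.fromiter(
                (s.contains(lats[i], lons[i]) for i in idx), bool, count=len(idx)
            )
            found[idx[hit]] = s.name
            remaining[idx[hit]] = False
        assigned.loc[todo] = found
    df["stratum"] = assigned

    unassigned = df["stratum"].isna()
    report.n_unassigned = int(unassigned.sum())
    report.unassigned = encounters.loc[df.index[unassigned]]
    df = df[~unassigned]

    stratum_class = df["stratum"].map(strata.season_class_of)
    mismatch = stratum_class != df["season"]
    report.n_class_mismatch = int(mismatch.sum())
    df = df[~mismatch]

    if df.empty:
        return pd.DataFrame(columns=CAPTURE_COLUMNS), report

    # per (individual, season, season-year): closest to midpoint, earlier date on tie
    month = np.where(df["season"] == WINTER, WINTER_MIDPOINT[0], SUMMER_MIDPOINT[0])
    day = np.where(df["season"] == WINTER, WINTER_MIDPOINT[1], SUMMER_MIDPOINT[1])
    mid = pd.to_datetime(
        pd.DataFrame({"year": df["season_year"].to_numpy(), "month": month, "day": day})
    ).set_axis(df.index)
    df["_dist"] = (df["date"] - mid).abs()
    df = df.sort_values(
        ["individual_id", "season", "season_year", "_dist", "date"],
        kind="mergesort",
    )
    keep = ~df.duplicated(["individual_id", "season", "season_year"], keep="first")
    report.n_duplicates = int((~keep).sum())
    out = df[keep].rename(columns={"date": "capture_date"})[CAPTURE_COLUMNS]
    out = out.reset_index(drop=True)
    report.n_captures = len(out)
    return out, report


def stratify_counts(captures: pd.DataFrame) -> pd.DataFrame:
    """Unique-individual counts per (stratum, season, season_year).

    Input must be condensed captures (one row per individual-season-year),
    so a plain row count per cell is a unique-individual count.
    """
    if captures.empty:
        return pd.DataFrame(columns=["stratum", "season", "season_year", "n"])
    out = (
        captures.groupby(["stratum", "season", "season_year"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out
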