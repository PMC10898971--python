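"""Bundled example datasets: a published two-decade summary series.

These are the printed summary tables of a basin-wide North Pacific humpback
whale photo-identification mark-recapture study (2001-2022 data, mid-years
2002-2021): the pooled occasion sizes, between-season matches, uncorrected
and bias-corrected abundance estimates with jackknife standard errors; the
Hawai'i and Mainland Mexico relative-abundance index series; and the
migratory-destination contingency counts for southeast Alaska / northern
British Columbia whales in two periods.  They serve as worked examples and
as desk-scale checks of the estimator arithmetic (the raw photo-ID archive
itself is not redistributable).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_basin_series() -> pd.DataFrame:
    """Basin-wide series: mid_year, n_winter, n_summer, matches, uncorrected,
    f_t, corrected, dyoy_pct, se, match_rate_pct (one row per mid-year,
    2002-2021)."""
    return _load("north_pacific_series.csv")


def load_regional_series() -> pd.DataFrame:
    """Hawai'i and Mainland Mexico relative-abundance index series (long
    format: mid_year, region, n_winter, n_summer, matches, estimate, se,
    dyoy_pct)."""
    return _load("regional_series.csv")


def load_migration_table() -> pd.DataFrame:
    """Migratory destinations of one feeding area's whales in two periods
    (columns: period, total_sampled, winter_matches, Hawaii, MexMld, both;
    the destination columns each include the 'both' individuals)."""
    return _load("migration_destinations.csv")
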