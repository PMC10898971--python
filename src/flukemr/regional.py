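"""Regional relative-abundance indices and migratory-destination tests.

A *regional pair* couples one wintering (breeding) stratum with the feeding
strata that supply most of its migrants (for example Hawai'i with southeast
Alaska/northern British Columbia).  The paired Chapman estimate over rolling
windows is treated strictly as an index of relative abundance — the
wintering sample is not assumed to be a random draw from all contributing
feeding areas, so the index tracks trend, not absolute size.

Two diagnostics probe whether migratory structure changed over the study:

* the share of two wintering regions' combined index held by one of them,
  with an OLS line (share ~ year) and its slope F-test; and
* a contingency-table comparison of migratory destinations of one feeding
  area's whales in two time periods, tested with Pearson's chi-square.

The destination table follows field convention in reporting overlapping
columns: whales seen in both destinations are counted in each destination's
column *and* in a separate "both" column, so columns exceed the total
matched count by the overlap.  The chi-square is computed on the table as
reported; note the overlap mildly violates the test's independence
assumption (a disjoint variant is available via ``overlap="exclusive"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import (
    EstimationWindow,
    chapman_estimate,
    count_two_samples,
)
from .errors import EstimationError, ValidationError
from .strata import SUMMER, WINTER, StrataConfig
from .uncertainty import jackknife_se


@dataclass(frozen=True)
class RegionalPair:
    """One wintering stratum paired with its main feeding strata."""

    label: str
    winter_stratum: str
    summer_strata: tuple[str, ...]

    def validate(self, strata: StrataConfig) -> None:
        if strata.season_class_of(self.winter_stratum) != WINTER:
            raise ValidationError(
                f"{self.winter_stratum!r} is not a wintering stratum"
            )
        for s in self.summer_strata:
            if strata.season_class_of(s) != SUMMER:
                raise ValidationError(f"{s!r} is not a summer stratum")


def relative_abundance_series(
    captures: pd.DataFrame,
    pair: RegionalPair,
    windows: list[EstimationWindow],
    jackknife_n: int = 20,
    drop_fraction: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Chapman index series for a paired wintering/feeding region.

    Per window: n1 = unique individuals in the wintering stratum over the
    three pooled winters, n2 = unique individuals in the paired feeding
    strata over the two pooled summers, m = their intersection.  The
    jackknife SE uses only the pair's own capture records.  Windows with an
    empty occasion are skipped with a warning.  No bias correction is
    applied: values are an index of relative abundance.
    """
    rng = np.random.default_rng(rng)
    pair_strata = (pair.winter_stratum, *pair.summer_strata)
    sub = captures[captures["stratum"].isin(pair_strata)]
    rows = []
    for window in windows:
        try:
            counts = count_two_samples(
                sub,
                window,
                winter_strata=(pair.winter_stratum,),
                summer_strata=pair.summer_strata,
            )
        except EstimationError:
            counts = None
        if counts is None or counts.n1 == 0 or counts.n2 == 0:
            warnings.warn(
                f"{pair.label}: window {window.mid_year} has an empty occasion; skipped"
            )
            continue
        estimate = chapman_estimate(counts.n1, counts.n2, counts.m)

        def _est(dropped: pd.DataFrame, _w=window) -> float:
            c = count_two_samples(
                dropped,
                _w,
                winter_strata=(pair.winter_stratum,),
                summer_strata=pair.summer_strata,
            )
            return chapman_estimate(c.n1, c.n2, c.m)

        window_rows = sub[
            (
                (sub["season"] == WINTER)
                & sub["season_year"].isin(window.winter_years)
            )
            | (
                (sub["season"] == SUMMER)
                & sub["season_year"].isin(window.summer_years)
            )
        ]
        jk = jackknife_se(
            _est, window_rows, n_replicates=jackknife_n,
            drop_fraction=drop_fraction, rng=rng,
        )
        rows.append(
            {
                "mid_year": window.mid_year,
                "n1": counts.n1,
                "n2": counts.n2,
                "m": counts.m,
                "estimate": estimate,
                "se": jk.se,
                "cv": jk.se / estimate if estimate > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ProportionTrend:
    """Share series of region A within A+B, with its OLS trend line."""

    table: pd.DataFrame  # mid_year, share_a
    slope_per_year: float  # fraction / year
    intercept: float
    p_value: float

    @property
    def slope_points_per_year(self) -> float:
        """Slope in percentage points per year."""
        return 100.0 * self.slope_per_year


def proportion_trend(series_a: pd.DataFrame, series_b: pd.DataFrame) -> ProportionTrend:
    """Per-year shares N_A/(N_A+N_B) and the OLS slope of share on year.

    The two inputs are index series with ``mid_year`` and ``estimate``
    columns; only aligned mid-years are used (at least 3 required).  The
    p-value is the F-test of a non-zero slope (identical to the slope
    t-test in simple regression); a perfectly constant share series is
    reported with slope 0 and p = 1.
    """
    merged = series_a.merge(
        series_b, on="mid_year", suffixes=("_a", "_b"), how="inner"
    )
    if len(merged) < 3:
        raise ValidationError("proportion trend requires >= 3 aligned mid-years")
    share = merged["estimate_a"] / (merged["estimate_a"] + merged["estimate_b"])
    years = merged["mid_year"].to_numpy(dtype=float)
    table = pd.DataFrame({"mid_year": merged["mid_year"], "share_a": share})
    if np.allclose(share, share.iloc[0]):
        return ProportionTrend(
            table=table, slope_per_year=0.0,
            intercept=float(share.iloc[0]), p_value=1.0,
        )
    fit = stats.linregress(years, share.to_numpy())
    return ProportionTrend(
        table=table,
        slope_per_year=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
    )


@dataclass
class DestinationTable:
    """Migratory destinations of one feeding area's whales in two periods.

    ``counts`` is a 2x3 table (rows: periods; columns: destination A,
    destination B, both).  With the default overlapping convention the A and
    B columns each include the "both" individuals.
    """

    counts: pd.DataFrame
    total_sampled: tuple[int, int]
    total_matched: tuple[int, int]
    period_labels: tuple[str, str]


def destination_table(
    captures: pd.DataFrame,
    feeder_strata: tuple[str, ...],
    period_1_years: tuple[int, ...],
    period_2_years: tuple[int, ...],
    dest_a: str,
    dest_b: str,
    overlap: str = "inclusive",
) -> DestinationTable:
    """Cross-period destination counts for whales from given feeding strata.

    For each period: the sampled set is all individuals with a summer
    capture in ``feeder_strata`` during the period's years; of those, count
    the ones with a winter capture in ``dest_a``, in ``dest_b``, and in
    both (within the same period's winters).  ``overlap="inclusive"``
    (default) counts "both" whales in all three columns; ``"exclusive"``
    makes the three columns disjoint.
    """
    if overlap not in ("inclusive", "exclusive"):
        raise ValidationError(f"unknown overlap mode {overlap!r}")
    rows, sampled_totals, matched_totals = [], [], []
    for years in (period_1_years, period_2_years):
        summer = captures[
            (captures["season"] == SUMMER)
            & captures["season_year"].isin(years)
            & captures["stratum"].isin(feeder_strata)
        ]
        sampled = set(summer["individual_id"])
        if not sampled:
            raise EstimationError("empty feeder-area sample for a period")
        winter = captures[
            (captures["season"] == WINTER)
            & captures["season_year"].isin(years)
            & captures["individual_id"].isin(sampled)
        ]
        in_a = set(winter.loc[winter["stratum"] == dest_a, "individual_id"])
        in_b = set(winter.loc[winter["stratum"] == dest_b, "individual_id"])
        both = in_a & in_b
        if overlap == "inclusive":
            rows.append([len(in_a), len(in_b), len(both)])
        else:
            rows.append([len(in_a - both), len(in_b - both), len(both)])
        sampled_totals.append(len(sampled))
        matched_totals.append(len(in_a | in_b))
    counts = pd.DataFrame(
        rows, columns=[dest_a, dest_b, "both"], index=["period_1", "period_2"]
    )
    labels = (
        f"{min(period_1_years)}-{max(period_1_years)}",
        f"{min(period_2_years)}-{max(period_2_years)}",
    )
    return DestinationTable(
        counts=counts,
        total_sampled=tuple(sampled_totals),
        total_matched=tuple(matched_totals),
        period_labels=labels,
    )


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence on a 2xk count table.

    No continuity correction.  Returns (chi2, df, p) with p the upper-tail
    chi-square probability.  Rejects tables with a zero row or column margin.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("chi-square requires a 2-D count table")
    if (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square table has a zero margin")
    chi2, p, dof, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(dof), float(p)
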