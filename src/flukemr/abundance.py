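"""Two-occasion Chapman-Petersen estimation over rolling pooled windows.

The estimator treats three consecutive pooled winters as capture occasion 1
and the two intervening summers as occasion 2.  For occasion sizes ``n1``
and ``n2`` with ``m`` individuals seen in both, the Chapman bias-corrected
Petersen estimate of closed-population size is

    N' = (n1 + 1)(n2 + 1) / (m + 1) - 1

which is nearly unbiased when the expected number of recaptures is
moderately large and the two occasions sample independently.  A window with
mid-year ``t`` pools winters {t-1, t, t+1} and summers {t-1, t}; for data
years 2001-2022 this yields 20 overlapping annual estimates, 2002-2021.

Trend summaries follow the convention of smoothing the abundance series
with a centred 3-year moving average and reporting its year-over-year rate
of change (ΔYoY); entries whose moving-average support is truncated at the
series ends are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError
from .strata import SUMMER, WINTER


@dataclass(frozen=True)
class EstimationWindow:
    """Rolling pooled window labelled by its mid-year."""

    mid_year: int

    @property
    def winter_years(self) -> tuple[int, int, int]:
        t = self.mid_year
        return (t - 1, t, t + 1)

    @property
    def summer_years(self) -> tuple[int, int]:
        t = self.mid_year
        return (t - 1, t)

    def years(self, season: str) -> tuple[int, ...]:
        return self.winter_years if season == WINTER else self.summer_years


@dataclass(frozen=True)
class TwoSampleCounts:
    """Occasion sizes and recaptures for one estimation window."""

    n1: int
    n2: int
    m: int

    def __post_init__(self) -> None:
        if min(self.n1, self.n2, self.m) < 0:
            raise ValidationError("two-sample counts must be non-negative")
        if self.m > min(self.n1, self.n2):
            raise ValidationError("recaptures m cannot exceed min(n1, n2)")


def chapman_estimate(n1: int, n2: int, m: int) -> float:
    """Chapman bias-corrected Petersen estimate (n1+1)(n2+1)/(m+1) - 1."""
    TwoSampleCounts(n1, n2, m)
    if n1 == 0 or n2 == 0:
        warnings.warn("Chapman estimate with an empty capture occasion")
    return (n1 + 1) * (n2 + 1) / (m + 1) - 1


def chapman_variance(n1: int, n2: int, m: int) -> float:
    """Approximate analytic variance of the Chapman estimate (diagnostic).

    var = (n1+1)(n2+1)(n1-m)(n2-m) / ((m+1)^2 (m+2))
    """
    TwoSampleCounts(n1, n2, m)
    return (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))


def match_rate(n1: int, n2: int, m: int) -> float:
    """Between-season match rate m / (n1 + n2 - m) (fraction of the union)."""
    TwoSampleCounts(n1, n2, m)
    union = n1 + n2 - m
    if union <= 0:
        raise ValidationError("match rate undefined for an empty union")
    return m / union


def build_windows(
    first_year: int, last_year: int
) -> list[EstimationWindow]:
    """All complete rolling windows within a contiguous data-year range.

    Mid-years run from ``first_year + 1`` through ``last_year - 1``; edge
    clipping is not performed, so a range shorter than three years yields an
    empty list (with a warning).
    """
    if last_year - first_year + 1 < 3:
        warnings.warn("data range shorter than 3 years: no estimation windows")
        return []
    return [EstimationWindow(t) for t in range(first_year + 1, last_year)]


def count_two_samples(
    captures: pd.DataFrame,
    window: EstimationWindow,
    strata_filter: tuple[str, ...] | None = None,
    winter_strata: tuple[str, ...] | None = None,
    summer_strata: tuple[str, ...] | None = None,
) -> TwoSampleCounts:
    """Unique-individual occasion sizes and recaptures for one window.

    ``strata_filter`` restricts both occasions; ``winter_strata`` /
    ``summer_strata`` restrict each occasion separately (used for the
    regional paired-strata indices).
    """
    if captures.empty:
        raise EstimationError(f"no captures available for window {window.mid_year}")
    winter_sel = winter_strata if winter_strata is not None else strata_filter
    summer_sel = summer_strata if summer_strata is not None else strata_filter

    def occasion(season: str, strata_sel) -> set:
        mask = (captures["season"] == season) & captures["season_year"].isin(
            window.years(season)
        )
        if strata_sel is not None:
            mask &= captures["stratum"].isin(strata_sel)
        return set(captures.loc[mask, "individual_id"])

    winter_ids = occasion(WINTER, winter_sel)
    summer_ids = occasion(SUMMER, summer_sel)
    return TwoSampleCounts(
        n1=len(winter_ids), n2=len(summer_ids), m=len(winter_ids & summer_ids)
    )


@dataclass
class TrendSeries:
    """Abundance trend summaries over a consecutive series of mid-years.

    ``table`` has columns: ``mid_year, abundance, yoy_pct`` (raw
    year-over-year rate), ``ma3`` (centred 3-year moving average of
    abundance, truncated at the ends), ``dyoy_pct`` (year-over-year change
    of ``ma3``), ``end_truncated`` (True where the moving average used fewer
    than 3 terms).
    """

    table: pd.DataFrame

    @classmethod
    def from_estimates(cls, years, abundances) -> "TrendSeries":
        years = np.asarray(years, dtype=int)
        values = np.asarray(abundances, dtype=float)
        if len(years) < 3:
            raise ValidationError("trend series requires at least 3 estimates")
        if not np.all(np.diff(years) == 1):
            raise ValidationError("trend series requires consecutive mid-years")
        yoy = np.full(len(values), np.nan)
        yoy[1:] = 100.0 * (values[1:] / values[:-1] - 1.0)
        ma = np.array(
            [values[max(0, i - 1) : i + 2].mean() for i in range(len(values))]
        )
        dyoy = np.full(len(values), np.nan)
        dyoy[1:] = 100.0 * (ma[1:] / ma[:-1] - 1.0)
        truncated = np.zeros(len(values), dtype=bool)
        truncated[:2] = True  # ma[0] and hence dyoy[1] use a short window
        truncated[-1] = True
        table = pd.DataFrame(
            {
                "mid_year": years,
                "abundance": values,
                "yoy_pct": yoy,
                "ma3": ma,
                "dyoy_pct": dyoy,
                "end_truncated": truncated,
            }
        )
        return cls(table)

    def period_mean(self, first_year: int, last_year: int, column: str = "dyoy_pct") -> float:
        """Arithmetic mean of a rate column over mid-years [first, last]."""
        sel = self.table["mid_year"].between(first_year, last_year)
        vals = self.table.loc[sel, column].dropna()
        if vals.empty:
            raise ValidationError("no entries in the requested period")
        return float(vals.mean())

    def percent_change(self, year_a: int, year_b: int) -> float:
        """100 * (N_b - N_a) / N_a between two named mid-years."""
        s = self.table.set_index("mid_year")["abundance"]
        try:
            a, b = s.at[year_a], s.at[year_b]
        except KeyError as exc:
            raise ValidationError(f"mid-year {exc} not in series") from exc
        return float(100.0 * (b - a) / a)
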