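"""End-to-end orchestration: from an encounter file to results tables.

``run_estimate`` produces the basin-wide corrected abundance series (one row
per mid-year: occasion sizes, matches, match rate, uncorrected estimate,
correction factor, corrected estimate, smoothed year-over-year rate,
jackknife SE and combined CV).  ``run_regional`` produces the paired-region
index series, the wintering-share trend and the migratory-destination test.

All randomness flows through one seeded generator hierarchy, so a rerun
with the same inputs and seed reproduces every number exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .abundance import (
    EstimationWindow,
    TrendSeries,
    build_windows,
    count_two_samples,
    match_rate,
)
from .bias import ReferenceSpec, correction_factor
from .encounters import CondenseReport, condense
from .errors import EstimationError, ValidationError
from .regional import (
    RegionalPair,
    destination_table,
    pearson_chi2,
    proportion_trend,
    relative_abundance_series,
)
from .strata import StrataConfig
from .uncertainty import combine_cv, jackknife_se

logger = logging.getLogger("flukemr")

RESULT_SCHEMA_VERSION = 1

DEFAULT_REGIONAL_PAIRS = (
    RegionalPair("Hawaii", "Hawaii", ("SEAKNBC",)),
    RegionalPair("MainlandMexico", "MexMld", ("CAOR",)),
)


@dataclass
class RunConfig:
    """Options governing a full estimation run."""

    year_range: tuple[int, int] = (2001, 2022)
    bias_replicates: int = 25
    uncorrected_source: str = "subsampled"
    jackknife_n: int = 20
    drop_fraction: float = 0.05
    seed: int | None = None
    regional_pairs: tuple[RegionalPair, ...] = DEFAULT_REGIONAL_PAIRS
    skip_incomplete_windows: bool = True


def prepare_captures(
    encounters: pd.DataFrame,
    strata: StrataConfig,
    year_range: tuple[int, int],
) -> tuple[pd.DataFrame, CondenseReport]:
    captures, report = condense(encounters, strata, season_years=year_range)
    logger.info("condense: %s", report.as_dict())
    if captures.empty:
        raise ValidationError("no usable captures after condensation")
    return captures, report


def run_estimate(
    captures: pd.DataFrame,
    reference: ReferenceSpec,
    config: RunConfig | None = None,
    windows: list[EstimationWindow] | None = None,
) -> pd.DataFrame:
    """Basin-wide bias-corrected abundance series with jackknife uncertainty."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    if windows is None:
        windows = build_windows(*config.year_range)
    if not windows:
        raise EstimationError("no estimation windows in the configured range")

    rows = []
    for window in windows:
        logger.info(
            "window %s: winters %s summers %s",
            window.mid_year, window.winter_years, window.summer_years,
        )
        try:
            counts = count_two_samples(captures, window)
        except EstimationError:
            if config.skip_incomplete_windows:
                logger.warning("window %s skipped: no captures", window.mid_year)
                continue
            raise
        corr_rng, jack_rng = rng.spawn(2)
        try:
            result = correction_factor(
                reference,
                captures,
                window,
                n_replicates=config.bias_replicates,
                rng=corr_rng,
                uncorrected_source=config.uncorrected_source,
            )
        except EstimationError as exc:
            if config.skip_incomplete_windows:
                logger.warning("window %s skipped: %s", window.mid_year, exc)
                continue
            raise

        def corrected(sub: pd.DataFrame, _w=window, _r=jack_rng) -> float:
            return correction_factor(
                reference,
                sub,
                _w,
                n_replicates=config.bias_replicates,
                rng=_r,
                uncorrected_source=config.uncorrected_source,
            ).n_t

        jk = jackknife_se(
            corrected,
            captures,
            n_replicates=config.jackknife_n,
            drop_fraction=config.drop_fraction,
            rng=jack_rng,
        )
        cv_jack = jk.se / result.n_t if result.n_t > 0 else np.nan
        cv_total = combine_cv(cv_jack, reference.cv_ref)
        rows.append(
            {
                "mid_year": window.mid_year,
                "n1": counts.n1,
                "n2": counts.n2,
                "m": counts.m,
                "match_rate_pct": 100.0 * match_rate(counts.n1, counts.n2, counts.m),
                "n_prime": result.n_prime,
                "f_t": result.f_t,
                "n_t": result.n_t,
                "se": jk.se,
                "cv": cv_total,
            }
        )
    if not rows:
        raise EstimationError("every estimation window was skipped")
    table = pd.DataFrame(rows)
    if len(table) >= 3 and (table["mid_year"].diff().dropna() == 1).all():
        trend = TrendSeries.from_estimates(table["mid_year"], table["n_t"])
        table["dyoy_pct"] = trend.table["dyoy_pct"].to_numpy()
        table["dyoy_truncated"] = trend.table["end_truncated"].to_numpy()
    else:
        table["dyoy_pct"] = np.nan
        table["dyoy_truncated"] = True
    table.attrs["schema_version"] = RESULT_SCHEMA_VERSION
    return table


def run_regional(
    captures: pd.DataFrame,
    config: RunConfig | None = None,
    windows: list[EstimationWindow] | None = None,
    destination_periods: tuple[tuple[int, ...], tuple[int, ...]] | None = (
        (2004, 2005, 2006),
        (2019, 2020, 2021),
    ),
    feeder_strata: tuple[str, ...] = ("SEAKNBC",),
    destinations: tuple[str, str] = ("Hawaii", "MexMld"),
) -> dict:
    """Regional index series, share trend and the migration contingency test."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    if windows is None:
        windows = build_windows(*config.year_range)
    series = {}
    for pair in config.regional_pairs:
        series[pair.label] = relative_abundance_series(
            captures,
            pair,
            windows,
            jackknife_n=config.jackknife_n,
            drop_fraction=config.drop_fraction,
            rng=rng.spawn(1)[0],
        )
    out: dict = {"series": series, "schema_version": RESULT_SCHEMA_VERSION}
    labels = list(series)
    if len(labels) >= 2:
        out["proportion_trend"] = proportion_trend(
            series[labels[0]], series[labels[1]]
        )
    if destination_periods is not None:
        try:
            table = destination_table(
                captures,
                feeder_strata,
                destination_periods[0],
                destination_periods[1],
                dest_a=destinations[0],
                dest_b=destinations[1],
            )
            counts = table.counts.loc[:, table.counts.sum(axis=0) > 0]
            if counts.shape[1] < table.counts.shape[1]:
                logger.warning(
                    "migration test: dropping all-zero destination column(s)"
                )
            chi2, dof, p = pearson_chi2(counts.to_numpy())
        except (EstimationError, ValidationError) as exc:
            logger.warning("migration test skipped: %s", exc)
        else:
            out["destinations"] = table
            out["migration_test"] = {"chi2": chi2, "df": dof, "p": p}
    return out


def attach_presentation_columns(table: pd.DataFrame) -> pd.DataFrame:
    """Add rounded presentation columns (nearest whale; rates to 1 d.p.)."""
    out = table.copy()
    for col in ("n_prime", "n_t", "se"):
        if col in out:
            out[f"{col}_rounded"] = out[col].round(0).astype("Int64")
    for col in ("dyoy_pct",):
        if col in out:
            out[f"{col}_rounded"] = out[col].round(1)
    if "f_t" in out:
        out["f_t_rounded"] = out["f_t"].round(2)
    if "match_rate_pct" in out:
        out["match_rate_pct_rounded"] = out["match_rate_pct"].round(2)
    return out


# reference bundle I/O -------------------------------------------------------

def write_reference_bundle(reference: ReferenceSpec, directory) -> None:
    """Write a reference as a directory: captures.csv + meta.yaml."""
    import pathlib

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reference.captures.to_csv(directory / "captures.csv", index=False)
    meta = {
        "n_ref": float(reference.n_ref),
        "cv_ref": float(reference.cv_ref),
        "mid_year": int(reference.window.mid_year),
    }
    with open(directory / "meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)


def load_reference_bundle(directory) -> ReferenceSpec:
    import pathlib

    directory = pathlib.Path(directory)
    with open(directory / "meta.yaml") as fh:
        meta = yaml.safe_load(fh)
    captures = pd.read_csv(
        directory / "captures.csv",
        dtype={"individual_id": str},
        parse_dates=["capture_date"],
    )
    return ReferenceSpec(
        captures=captures,
        n_ref=float(meta["n_ref"]),
        cv_ref=float(meta["cv_ref"]),
        window=EstimationWindow(int(meta["mid_year"])),
    )
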