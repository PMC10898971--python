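"""Geographic-sampling bias correction by reference-dataset subsampling.

Uneven regional photographic effort biases a pooled two-occasion estimate
whenever under-sampling is correlated between the two seasons (for example,
a region whose breeding and feeding grounds both go unsurveyed for several
years).  The correction anchors every window to a *reference* capture set
gathered under representative effort, with known abundance ``N_ref`` (and
CV).  For a target window ``t``:

1. Count unique individuals per (stratum, season) in both the reference
   window and the target window.
2. Take the element-wise minimum — the largest common sample size (LCSS).
3. Randomly subsample (without replacement) both capture sets down to the
   LCSS in every cell, so both share the same geographic sample-size
   distribution.
4. Estimate abundance from the subsampled reference (``N_alt``).  The ratio
   ``F_t = N_ref / N_alt`` measures the bias induced by the target's
   geographic sampling pattern, and the corrected estimate is
   ``N_t = N'_t x F_t`` with ``N'_t`` the Chapman estimate on the
   (subsampled, by default) target data.

Subsampling is replicated (default 25 draws) and ``N_alt`` / ``N'_t`` are
replicate means; a seeded generator makes the whole procedure reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import EstimationWindow, chapman_estimate, count_two_samples
from .errors import EstimationError, ValidationError
from .strata import SUMMER, WINTER

Cell = tuple[str, str]  # (stratum, season)


@dataclass
class ReferenceSpec:
    """Reference capture set with its known abundance and uncertainty."""

    captures: pd.DataFrame
    n_ref: float
    cv_ref: float
    window: EstimationWindow

    def __post_init__(self) -> None:
        if self.n_ref <= 0:
            raise ValidationError("reference abundance must be positive")
        if self.cv_ref < 0:
            raise ValidationError("reference CV must be non-negative")
        for season in (WINTER, SUMMER):
            years = set(self.window.years(season))
            have = set(
                self.captures.loc[
                    self.captures["season"] == season, "season_year"
                ].unique()
            )
            if not years <= have:
                raise ValidationError(
                    f"reference captures do not span {season} years {sorted(years)}"
                )


@dataclass
class CorrectionResult:
    """Bias-corrected estimate for one window."""

    mid_year: int
    f_t: float
    n_alt: float
    n_prime: float
    n_t: float
    n_replicates: int
    f_sd: float
    n_discarded: int = 0
    f_replicates: tuple = field(default=(), repr=False)


def cell_members(
    captures: pd.DataFrame, window: EstimationWindow
) -> dict[Cell, np.ndarray]:
    """Unique individual IDs per (stratum, season) cell within a window.

    An individual recorded in different strata in different pooled years
    contributes to each such cell (selection during subsampling is decided
    per cell, independently).
    """
    members: dict[Cell, np.ndarray] = {}
    for season in (WINTER, SUMMER):
        sub = captures[
            (captures["season"] == season)
            & captures["season_year"].isin(window.years(season))
        ]
        for stratum, grp in sub.groupby("stratum", observed=True):
            members[(stratum, season)] = np.unique(grp["individual_id"].to_numpy())
    return members


def stratum_season_counts(
    captures: pd.DataFrame, window: EstimationWindow
) -> dict[Cell, int]:
    """Unique-individual counts per (stratum, season) cell within a window."""
    return {cell: len(ids) for cell, ids in cell_members(captures, window).items()}


def lcss_allocation(
    ref_counts: dict[Cell, int], target_counts: dict[Cell, int]
) -> dict[Cell, int]:
    """Element-wise minimum of two per-cell count tables (missing cells -> 0)."""
    cells = set(ref_counts) | set(target_counts)
    return {c: min(ref_counts.get(c, 0), target_counts.get(c, 0)) for c in cells}


def subsample_captures(
    captures: pd.DataFrame,
    window: EstimationWindow,
    allocation: dict[Cell, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Draw the LCSS from each (stratum, season) cell without replacement.

    Returns the capture rows (within the window) of the selected individuals.
    Selection is independent per cell: an individual kept in one cell keeps
    only its rows in that cell; its records elsewhere survive only if those
    cells also select it.
    """
    members = cell_members(captures, window)
    kept = []
    for cell in sorted(allocation):
        k = allocation[cell]
        if k == 0:
            continue
        ids = members.get(cell)
        if ids is None or len(ids) < k:
            raise ValidationError(
                f"allocation {k} exceeds available individuals in cell {cell}"
            )
        chosen = ids if len(ids) == k else rng.choice(ids, size=k, replace=False)
        stratum, season = cell
        rows = captures[
            (captures["season"] == season)
            & captures["season_year"].isin(window.years(season))
            & (captures["stratum"] == stratum)
            & captures["individual_id"].isin(chosen)
        ]
        kept.append(rows)
    if not kept:
        return captures.iloc[0:0]
    return pd.concat(kept, ignore_index=True)


def correction_factor(
    reference: ReferenceSpec,
    target_captures: pd.DataFrame,
    window: EstimationWindow,
    n_replicates: int = 25,
    rng: np.random.Generator | int | None = None,
    uncorrected_source: str = "subsampled",
) -> CorrectionResult:
    """Estimate F_t and the corrected abundance for one target window.

    ``uncorrected_source`` chooses how the companion uncorrected estimate
    N'_t is computed: ``"subsampled"`` (default; on the LCSS-subsampled
    target, so both datasets share identical per-stratum sample sizes) or
    ``"full"`` (on the full target window).  Replicates whose subsample has
    zero recaptures in either dataset are discarded with a warning.
    """
    if uncorrected_source not in ("subsampled", "full"):
        raise ValidationError(f"unknown uncorrected_source {uncorrected_source!r}")
    rng = np.random.default_rng(rng)
    ref_counts = stratum_season_counts(reference.captures, reference.window)
    tgt_counts = stratum_season_counts(target_captures, window)
    allocation = lcss_allocation(ref_counts, tgt_counts)
    if all(v == 0 for v in allocation.values()):
        raise EstimationError(
            f"window {window.mid_year}: no common sample with the reference"
        )

    n_alt_reps, n_prime_reps, discarded = [], [], 0
    for _ in range(n_replicates):
        ref_sub = subsample_captures(
            reference.captures, reference.window, allocation, rng
        )
        tgt_sub = subsample_captures(target_captures, window, allocation, rng)
        try:
            c_ref = count_two_samples(ref_sub, reference.window)
            c_tgt = count_two_samples(tgt_sub, window)
        except EstimationError:
            discarded += 1
            continue
        if c_ref.m == 0 or c_tgt.m == 0:
            discarded += 1
            continue
        n_alt_reps.append(chapman_estimate(c_ref.n1, c_ref.n2, c_ref.m))
        n_prime_reps.append(chapman_estimate(c_tgt.n1, c_tgt.n2, c_tgt.m))
    if discarded:
        warnings.warn(
            f"window {window.mid_year}: discarded {discarded} zero-match replicates"
        )
    if not n_alt_reps:
        raise EstimationError(
            f"window {window.mid_year}: all subsample replicates had zero matches"
        )

    n_alt = float(np.mean(n_alt_reps))
    f_t = reference.n_ref / n_alt
    f_reps = tuple(reference.n_ref / np.asarray(n_alt_reps))
    if uncorrected_source == "subsampled":
        n_prime = float(np.mean(n_prime_reps))
    else:
        c_full = count_two_samples(target_captures, window)
        n_prime = chapman_estimate(c_full.n1, c_full.n2, c_full.m)
    return CorrectionResult(
        mid_year=window.mid_year,
        f_t=f_t,
        n_alt=n_alt,
        n_prime=n_prime,
        n_t=n_prime * f_t,
        n_replicates=len(n_alt_reps),
        f_sd=float(np.std(f_reps, ddof=1)) if len(f_reps) > 1 else 0.0,
        n_discarded=discarded,
        f_replicates=f_reps,
    )
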