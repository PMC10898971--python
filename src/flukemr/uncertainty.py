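"""Resampling uncertainty: delete-d jackknife SE and CV combination.

The jackknife repeatedly drops a fixed fraction (default 5%) of the
condensed capture records uniformly without replacement, re-runs the full
estimator (including any bias correction wrapped into the closure) and
summarises the spread of the replicate estimates with

    s.e.(x) = sqrt( (n-1)/n * sum_i (x_i - x_bar)^2 )

where n is the number of jackknife replicates (default 20).  The CV of a
bias-corrected estimate additionally folds in the reference estimate's CV
in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .errors import EstimationError, ValidationError


@dataclass
class JackknifeResult:
    """Replicate estimates and the derived standard error."""

    n: int
    estimates: tuple[float, ...]
    mean: float
    se: float
    drop_fraction: float

    def cv(self, estimate: float) -> float:
        return self.se / estimate


def jackknife_formula_se(estimates) -> float:
    """s.e. = sqrt((n-1)/n * sum (x_i - x_bar)^2) over replicate estimates."""
    x = np.asarray(estimates, dtype=float)
    n = len(x)
    if n < 2:
        raise ValidationError("jackknife needs at least 2 replicate estimates")
    return math.sqrt((n - 1) / n * float(((x - x.mean()) ** 2).sum()))


def jackknife_se(
    estimator: Callable[[pd.DataFrame], float],
    captures: pd.DataFrame,
    n_replicates: int = 20,
    drop_fraction: float = 0.05,
    rng: np.random.Generator | int | None = None,
    stratified: bool = False,
    max_retries: int = 3,
) -> JackknifeResult:
    """Delete-d jackknife standard error of an estimator closure.

    Each replicate drops ``floor(drop_fraction * K)`` of the K capture
    records uniformly without replacement (a fresh draw per replicate) and
    re-runs ``estimator`` on the remainder.  With ``stratified=True`` the
    drop is apportioned proportionally within each stratum instead of
    globally.  A replicate whose estimator raises is retried with a new draw
    up to ``max_retries`` times.

    Records are canonically sorted first, so results depend only on the
    record set, the seed and the options — not on input row order.
    """
    if not 0 <= drop_fraction < 1:
        raise ValidationError("drop_fraction must be in [0, 1)")
    if n_replicates < 2:
        raise ValidationError("need at least 2 jackknife replicates")
    rng = np.random.default_rng(rng)
    df = captures.sort_values(
        ["individual_id", "season", "season_year", "stratum"], kind="mergesort"
    ).reset_index(drop=True)
    k = len(df)
    d = int(math.floor(drop_fraction * k))

    def drop_indices() -> np.ndarray:
        if not stratified:
            return rng.choice(k, size=d, replace=False)
        picks = []
        groups = df.groupby("stratum", observed=True).indices
        for stratum in sorted(groups):
            idx = groups[stratum]
            d_s = int(math.floor(drop_fraction * len(idx)))
            if d_s:
                picks.append(rng.choice(idx, size=d_s, replace=False))
        return np.concatenate(picks) if picks else np.empty(0, dtype=int)

    estimates = []
    for _ in range(n_replicates):
        for attempt in range(max_retries + 1):
            keep = np.ones(k, dtype=bool)
            keep[drop_indices()] = False
            try:
                value = float(estimator(df[keep]))
            except Exception:
                if attempt == max_retries:
                    raise EstimationError(
                        "jackknife replicate failed after retries"
                    )
                continue
            if not math.isfinite(value):
                if attempt == max_retries:
                    raise EstimationError("jackknife replicate was non-finite")
                continue
            estimates.append(value)
            break
    return JackknifeResult(
        n=len(estimates),
        estimates=tuple(estimates),
        mean=float(np.mean(estimates)),
        se=jackknife_formula_se(estimates),
        drop_fraction=drop_fraction,
    )


def combine_cv(cv_uncorrected: float, cv_ref: float) -> float:
    """Root-sum-square combination of two CVs."""
    if cv_uncorrected < 0 or cv_ref < 0:
        raise ValidationError("CVs must be non-negative")
    return math.sqrt(cv_uncorrected**2 + cv_ref**2)
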