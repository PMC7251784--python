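"""Between-season similarity of heading response and range extrapolation.

Quantifies how similarly the accession panel behaves in any two seasons:
the Pearson correlation of the two seasons' DHS vectors over accessions
(shape agreement) and their mean squared difference (level + shape
disagreement, in days²).  A season that uniformly shifts everyone later
keeps r = 1 while its MSE grows as the square of the shift.

Also provides the per-season summary (mean, SD, n) and the joint-regression
range extrapolation: given a season's regression of DHS on the multi-season
accession means, predict the heading-date range that season would produce
over a stated range of accession means, rounded half-away-from-zero to
whole days.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SeasonSimilarity:
    """Symmetric seasons x seasons Pearson-r and MSE matrices."""

    r_matrix: pd.DataFrame
    mse_matrix: pd.DataFrame


def _complete_wide(phenotypes: pd.DataFrame) -> pd.DataFrame:
    wide = phenotypes.pivot(index="accession_id", columns="season_id", values="dhs")
    if wide.isna().any().any():
        raise ValueError("pairwise season similarity requires a complete-case matrix")
    if wide.shape[1] < 2:
        raise ValueError("need at least two seasons")
    return wide.sort_index(axis=1)


def pairwise_season_similarity(phenotypes: pd.DataFrame) -> SeasonSimilarity:
    """Pearson r and MSE between every season pair, over accessions.

    A zero-variance season yields NaN in its r entries (undefined, flagged
    by NaN rather than dropped); its MSE entries are still computed.
    """
    wide = _complete_wide(phenotypes)
    r = wide.corr(method="pearson", min_periods=2)
    np.fill_diagonal(r.to_numpy(), 1.0)
    arr = wide.to_numpy()  # accessions x seasons
    diff = arr[:, :, None] - arr[:, None, :]
    mse = pd.DataFrame(
        (diff**2).mean(axis=0), index=wide.columns, columns=wide.columns
    )
    return SeasonSimilarity(r_matrix=r, mse_matrix=mse)


def season_summary(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per-season mean, SD (n-1 denominator) and n over accessions."""
    counts = phenotypes.groupby("season_id")["dhs"].size()
    single = counts[counts < 2]
    if len(single):
        raise ValueError(
            f"season(s) with a single observation, SD undefined: "
            f"{sorted(single.index)}"
        )
    out = (
        phenotypes.groupby("season_id")["dhs"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="size")
        .reset_index()
        .sort_values("season_id", ignore_index=True)
    )
    return out


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def predict_range(
    slope: float, intercept: float, x_min: float, x_max: float
) -> tuple[int, int]:
    """Heading-date range a season's regression implies over [x_min, x_max].

    Evaluates slope*x + intercept at both ends, swaps if the slope is
    negative, and rounds half-away-from-zero to the nearest day.
    """
    if x_min > x_max:
        raise ValueError("x_min must not exceed x_max")
    lo = slope * x_min + intercept
    hi = slope * x_max + intercept
    if slope < 0:
        lo, hi = hi, lo
    return _round_half_away(lo), _round_half_away(hi)
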