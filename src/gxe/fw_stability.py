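"""Finlay-Wilkinson joint-regression stability analysis, in both directions.

The classical Finlay-Wilkinson (1963) approach regresses each genotype's
trait values on an *environment index* — the mean trait value over all
genotypes in each environment.  The slope measures environmental
sensitivity: 1 is an average responder, below 1 a stable (buffered)
genotype, above 1 a hypersensitive one.

This module fits the regression per accession across seasons (the usual
direction) and per season across accessions (the dual direction, with the
accession's multi-season mean as the regressor), and correlates accession
slopes with covariates such as phenotypic SD, range, vernalization
requirement and longitude of origin.

On complete balanced data the unweighted mean of the per-accession slopes is
identically 1, since the sum of cov(y_i, E) over accessions equals
N * var(E); the dual direction obeys the same identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class ZeroVarianceIndexError(ValueError):
    """The environment index has no variance — the FW slope is undefined."""


@dataclass(frozen=True)
class FWFit:
    """A single Finlay-Wilkinson regression plus the unit's summary stats.

    ``unit_id`` is an accession (regression across seasons) or a season
    (regression across accessions).  ``unit_sd`` uses the n-1 denominator;
    ``unit_range`` is max - min over the unit's observed values.
    """

    unit_id: str
    slope: float
    intercept: float
    r2: float
    n_points: int
    unit_mean: float
    unit_sd: float
    unit_range: float


def compute_environment_index(phenotypes: pd.DataFrame) -> pd.Series:
    """Per-season mean DHS over all accessions (focal accession included).

    Expects a complete-case matrix so every season averages the same
    accession set.
    """
    if len(phenotypes) == 0:
        raise ValueError("empty phenotype table")
    idx = phenotypes.groupby("season_id")["dhs"].mean().sort_index()
    idx.name = "environment_index"
    return idx


def _simple_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form simple OLS; returns (slope, intercept, r2).

    A constant response gives slope 0 and R² defined as 0 (flat responders
    are reported, not dropped).  A constant regressor is an error upstream.
    """
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    if sxx == 0:
        raise ZeroVarianceIndexError("regressor has zero variance")
    syy = ((y - ybar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return float(slope), float(intercept), float(r2)


def _fit_unit(unit_id: str, x: np.ndarray, y: np.ndarray) -> FWFit:
    slope, intercept, r2 = _simple_ols(x, y)
    return FWFit(
        unit_id=str(unit_id),
        slope=slope,
        intercept=intercept,
        r2=r2,
        n_points=len(y),
        unit_mean=float(y.mean()),
        unit_sd=float(y.std(ddof=1)),
        unit_range=float(y.max() - y.min()),
    )


def fw_by_accession(phenotypes: pd.DataFrame, index: pd.Series) -> list[FWFit]:
    """Regress each accession's DHS across seasons on the environment index."""
    missing = set(phenotypes["season_id"]) - set(index.index)
    if missing:
        raise ValueError(f"environment index missing seasons: {sorted(missing)}")
    fits = []
    for acc, grp in phenotypes.groupby("accession_id", sort=True):
        grp = grp.sort_values("season_id")
        x = index.loc[grp["season_id"]].to_numpy()
        y = grp["dhs"].to_numpy()
        fits.append(_fit_unit(acc, x, y))
    return fits


def fw_by_season(phenotypes: pd.DataFrame) -> list[FWFit]:
    """Dual direction: regress each season's accession values on the
    accessions' across-season means.  Requires a complete-case matrix."""
    wide = phenotypes.pivot(index="accession_id", columns="season_id", values="dhs")
    if wide.isna().any().any():
        raise ValueError("fw_by_season requires a complete-case phenotype matrix")
    acc_means = wide.mean(axis=1).to_numpy()
    fits = []
    for season in sorted(wide.columns):
        y = wide[season].to_numpy()
        fits.append(_fit_unit(season, acc_means, y))
    return fits


def fits_to_frame(fits: list[FWFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": f.unit_id,
                "slope": f.slope,
                "intercept": f.intercept,
                "r2": f.r2,
                "n_points": f.n_points,
                "mean": f.unit_mean,
                "sd": f.unit_sd,
                "range": f.unit_range,
            }
            for f in fits
        ]
    )


#: covariates drawn from the fits themselves rather than metadata
_FIT_COVARIATES = {"unit_sd": "sd", "unit_range": "range", "unit_mean": "mean"}

DEFAULT_COVARIATES = ("unit_sd", "unit_range", "vernalization", "latitude", "longitude")


def correlate_slopes_with_covariates(
    fits: list[FWFit],
    metadata: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Pearson r (and two-sided t-test p) of FW slopes with each covariate.

    ``unit_sd`` / ``unit_range`` / ``unit_mean`` come from the fits; any
    other name must be a numeric metadata column.  A zero-variance covariate
    is flagged ``defined=False`` rather than dropped.
    """
    ftab = fits_to_frame(fits).set_index("unit_id")
    meta = metadata.set_index("accession_id").loc[ftab.index]
    rows = []
    for cov in covariates:
        if cov in _FIT_COVARIATES:
            vals = ftab[_FIT_COVARIATES[cov]]
        elif cov in meta.columns:
            vals = pd.to_numeric(meta[cov])
        else:
            raise ValueError(f"unknown covariate {cov!r}")
        mask = vals.notna()
        x = ftab.loc[mask, "slope"].to_numpy(dtype=float)
        y = vals[mask].to_numpy(dtype=float)
        if len(x) < 3 or np.std(y) == 0 or np.std(x) == 0:
            rows.append({"covariate": cov, "r": np.nan, "p_value": np.nan,
                         "n": int(mask.sum()), "defined": False})
            continue
        r, p = stats.pearsonr(x, y)
        rows.append({"covariate": cov, "r": float(r), "p_value": float(p),
                     "n": len(x), "defined": True})
    return pd.DataFrame(rows)
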