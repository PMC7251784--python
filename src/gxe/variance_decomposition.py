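"""Fixed-effect variance decomposition of heading date by OLS.

Fits additive fixed-effect models of days to heading on categorical
genetic factors (accession identity, origin, population cluster, growth
habit, kernel row) and the environmental factor (season), dummy-coded with
treatment coding (first level reference), and reports the degrees-of-freedom
accounting, R², adjusted R² and the overall F statistic for each factor set.

Each categorical factor with L levels contributes L-1 regression degrees of
freedom, so with an intercept df_regression + df_error + 1 = n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: map from factor names used in model specifications to table columns
FACTOR_COLUMNS = {
    "accession": "accession_id",
    "season": "season_id",
    "origin": "country",
    "origin_region": "origin_region",
    "population_cluster": "population_cluster",
    "growth_habit": "growth_habit",
    "kernel_row": "kernel_row",
}


class DegenerateModelError(ValueError):
    """A factor has fewer than two levels in the analysis sample."""


class RankDeficiencyError(ValueError):
    """The dummy-coded design is column-rank deficient."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"rank-deficient design; aliased columns: {aliased}")


@dataclass(frozen=True)
class ModelFitSummary:
    """One fitted factor model: d.f. accounting and fit statistics."""

    label: str
    n: int
    df_regression: int
    df_error: int
    r2: float
    adj_r2: float
    f_value: float
    p_value: float


def _design(df: pd.DataFrame, factors: list[str]) -> pd.DataFrame:
    """Intercept + treatment-coded dummies for each factor, in given order."""
    cols = [pd.Series(1.0, index=df.index, name="Intercept")]
    for factor in factors:
        if factor not in FACTOR_COLUMNS:
            raise ValueError(
                f"unknown factor {factor!r}; expected one of {sorted(FACTOR_COLUMNS)}"
            )
        col = FACTOR_COLUMNS[factor]
        if col not in df.columns:
            raise ValueError(f"factor {factor!r} needs column {col!r} in the data")
        levels = pd.Categorical(df[col].astype(str))
        if len(levels.categories) < 2:
            raise DegenerateModelError(
                f"factor {factor!r} has a single level in this sample"
            )
        dummies = pd.get_dummies(levels, prefix=factor, drop_first=True, dtype=float)
        dummies.index = df.index
        cols.append(dummies)
    return pd.concat(cols, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # pivoted QR: columns beyond the numerical rank are the aliased ones
    from scipy.linalg import qr

    _, R, piv = qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps
    aliased = [X.columns[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
    raise RankDeficiencyError(aliased)


def _merged(phenotypes: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    df = phenotypes.merge(metadata, on="accession_id", how="left", validate="m:1")
    return df


def fit_factor_model(
    phenotypes: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: list[str],
    label: str | None = None,
) -> ModelFitSummary:
    """OLS of DHS on an additive set of categorical factors.

    The overall F tests the model against intercept-only.  Raises
    :class:`DegenerateModelError` for single-level factors and
    :class:`RankDeficiencyError` (naming the aliased dummy columns) for
    collinear factor combinations.
    """
    df = _merged(phenotypes, metadata)
    needed = [FACTOR_COLUMNS[f] for f in factors if f in FACTOR_COLUMNS]
    df = df.dropna(subset=[c for c in needed if c in df.columns] + ["dhs"])
    X = _design(df, list(factors))
    _check_rank(X)
    res = sm.OLS(df["dhs"].to_numpy(), X.to_numpy()).fit()
    return ModelFitSummary(
        label=label or " + ".join(factors),
        n=int(res.nobs),
        df_regression=int(res.df_model),
        df_error=int(res.df_resid),
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_value=float(res.fvalue),
        p_value=float(res.f_pvalue),
    )


def compare_models(
    phenotypes: pd.DataFrame,
    metadata: pd.DataFrame,
    factor_sets: list[list[str]],
) -> tuple[list[ModelFitSummary], ModelFitSummary]:
    """Fit each factor set on the identical complete-case sample.

    Returns the list of summaries (in input order) and the summary with the
    largest adjusted R².
    """
    if not factor_sets:
        raise ValueError("need at least one factor set")
    all_cols = sorted(
        {FACTOR_COLUMNS[f] for fs in factor_sets for f in fs if f in FACTOR_COLUMNS}
    )
    df = _merged(phenotypes, metadata)
    present = [c for c in all_cols if c in df.columns]
    df = df.dropna(subset=present + ["dhs"])
    phen_cc = df[["accession_id", "season_id", "dhs"]]
    meta_cc = df.drop(columns=["season_id", "dhs"]).drop_duplicates("accession_id")
    summaries = [fit_factor_model(phen_cc, meta_cc, fs) for fs in factor_sets]
    best = max(summaries, key=lambda s: s.adj_r2)
    return summaries, best


def summaries_to_frame(summaries: list[ModelFitSummary]) -> pd.DataFrame:
    """Table-shaped output: one row per model, d.f. and fit statistics."""
    return pd.DataFrame(
        [
            {
                "model": s.label,
                "n": s.n,
                "df_regression": s.df_regression,
                "df_error": s.df_error,
                "r2": s.r2,
                "adj_r2": s.adj_r2,
                "f_value": s.f_value,
                "p_value": s.p_value,
            }
            for s in summaries
        ]
    )
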