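"""Single-marker association, variable selection and SNP-based prediction.

SNP genotypes are accession-constant: one biallelic call per accession,
replicated across that accession's season records when season enters the
model.  All models are plain OLS — no kinship correction — with two-sided
t-tests on coefficients and raw (uncorrected) p-values, reported as
-log10(p) for scanning.

The accession-identity model is the in-sample prediction ceiling: accession
dummies span every accession-constant SNP coding, so the SNPs+season R² can
never exceed the accession+season R² on the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import GenotypeTable
from .variance_decomposition import ModelFitSummary, RankDeficiencyError


@dataclass(frozen=True)
class SNPAssociation:
    snp_id: str
    gene: str
    position: int
    coefficient: float
    p_value: float
    neg_log10_p: float
    testable: bool = True
    note: str = ""


@dataclass
class SelectionResult:
    """Outcome of deterministic variable selection over a SNP panel."""

    selected: list[str]
    removed: list[tuple[str, float]]  # (snp_id, p at removal), in removal order
    monomorphic: list[str]
    aliased: list[str]
    method: str
    threshold: float


@dataclass
class PredictionReport:
    """In-sample prediction of DHS and the predicted-vs-observed regression.

    For in-sample OLS the slope of predicted on observed equals the model
    R², as does the R² of that simple regression — an assertable identity.
    """

    model_label: str
    observed: np.ndarray = field(repr=False)
    predicted: np.ndarray = field(repr=False)
    obs_pred_slope: float = 0.0
    obs_pred_intercept: float = 0.0
    obs_pred_r2: float = 0.0
    model_r2: float = 0.0
    n: int = 0


# ---------------------------------------------------------------------------
# design construction


def _season_dummies(season_ids: pd.Series) -> pd.DataFrame:
    lv = pd.Categorical(season_ids.astype(str))
    d = pd.get_dummies(lv, prefix="season", drop_first=True, dtype=float)
    d.index = season_ids.index
    return d


def encode_design(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    snp_subset: list[str] | None = None,
    season_factor: bool = True,
) -> tuple[pd.Series, pd.DataFrame, dict]:
    """Numeric design for SNP models over the phenotype records.

    Returns (y, X, info): the DHS response, the design with an intercept,
    optional season dummies and one 0/1 column per testable SNP, and an
    info dict listing ``monomorphic`` SNPs (excluded) and ``columns``.
    SNPs are accession-constant; records of accessions with any missing
    call in the subset must have been filtered upstream.
    """
    if snp_subset is None:
        snp_subset = genotypes.snp_ids
    acc = phenotypes["accession_id"]
    missing_acc = set(acc) - set(genotypes.calls.index.astype(str))
    if missing_acc:
        raise ValueError(f"accessions without genotypes: {sorted(missing_acc)[:5]}")
    calls = genotypes.calls.loc[:, list(snp_subset)]
    sub = calls.loc[calls.index.astype(str).isin(set(acc))]
    monomorphic = [s for s in snp_subset if sub[s].nunique(dropna=True) < 2]
    testable = [s for s in snp_subset if s not in set(monomorphic)]

    parts = [pd.DataFrame({"Intercept": np.ones(len(phenotypes))},
                          index=phenotypes.index)]
    if season_factor:
        parts.append(_season_dummies(phenotypes["season_id"]))
    if testable:
        snp_block = calls.loc[acc, testable].to_numpy(dtype=float)
        parts.append(pd.DataFrame(snp_block, index=phenotypes.index, columns=testable))
    X = pd.concat(parts, axis=1)
    if X.isna().any().any():
        raise ValueError("design contains missing genotype calls; filter upstream")
    info = {"monomorphic": monomorphic, "testable": testable,
            "columns": list(X.columns)}
    return phenotypes["dhs"].astype(float), X, info


def _ols(X: np.ndarray, y: np.ndarray):
    """Full-rank OLS with coefficient SEs; returns (beta, se, df_resid, rss, tss)."""
    n, k = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise RankDeficiencyError(["<unnamed>"] * (k - rank))
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df if df > 0 else np.nan
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    tss = float(((y - y.mean()) ** 2).sum())
    return beta, se, df, rss, tss


def _coef_pvalues(beta, se, df):
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    return 2.0 * stats.t.sf(np.abs(t), df)


# ---------------------------------------------------------------------------
# single-marker scan


def single_marker_scan(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    season_factor: bool = True,
) -> list[SNPAssociation]:
    """Per-SNP OLS of DHS on one SNP (plus season dummies), t-test on the
    SNP coefficient, -log10(p) reported.

    Implemented by residualizing response and SNP column on the base design
    (intercept + season dummies) once, which reproduces the full joint OLS
    coefficient and t statistic exactly.  Monomorphic SNPs are flagged
    untestable; a perfect marker whose residual fit is exact is flagged
    ``separation-limit`` with p = 0.
    """
    y = phenotypes["dhs"].to_numpy(dtype=float)
    base = [np.ones((len(phenotypes), 1))]
    if season_factor:
        base.append(_season_dummies(phenotypes["season_id"]).to_numpy())
    Z = np.hstack(base)
    Q, _ = np.linalg.qr(Z)
    y_r = y - Q @ (Q.T @ y)
    df_resid = len(y) - Z.shape[1] - 1

    acc = phenotypes["accession_id"]
    results = []
    for snp_id in genotypes.snp_ids:
        gene = str(genotypes.snps.loc[snp_id, "gene"])
        pos = int(genotypes.snps.loc[snp_id, "position"])
        x = genotypes.calls.loc[acc, snp_id].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise ValueError(f"missing calls for SNP {snp_id!r}; filter upstream")
        if np.unique(x).size < 2:
            results.append(SNPAssociation(snp_id, gene, pos, np.nan, np.nan, np.nan,
                                          testable=False, note="monomorphic"))
            continue
        x_r = x - Q @ (Q.T @ x)
        sxx = float(x_r @ x_r)
        coef = float(x_r @ y_r) / sxx
        rss = float(y_r @ y_r) - coef * coef * sxx
        rss = max(rss, 0.0)
        scale = float(y_r @ y_r)
        if scale > 0 and rss <= scale * 1e-12:
            results.append(SNPAssociation(snp_id, gene, pos, coef, 0.0, np.inf,
                                          note="separation-limit"))
            continue
        se = np.sqrt(rss / df_resid / sxx)
        p = float(2.0 * stats.t.sf(abs(coef) / se, df_resid))
        nlp = float(-np.log10(p)) if p > 0 else np.inf
        results.append(SNPAssociation(snp_id, gene, pos, coef, p, nlp))
    return results


def scan_to_frame(results: list[SNPAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": r.snp_id, "gene": r.gene, "position": r.position,
                "coefficient": r.coefficient, "p_value": r.p_value,
                "neg_log10_p": r.neg_log10_p, "testable": r.testable,
                "note": r.note,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# variable selection


def _drop_aliased(calls: pd.DataFrame, snps: pd.DataFrame,
                  candidates: list[str]) -> tuple[list[str], list[str]]:
    """Remove SNPs perfectly collinear (r = ±1) with an earlier-position one."""
    keep: list[str] = []
    aliased: list[str] = []
    order = sorted(candidates, key=lambda s: int(snps.loc[s, "position"]))
    mat = calls[order].to_numpy(dtype=float)
    for j, snp in enumerate(order):
        x = mat[:, j]
        dup = False
        for kept in keep:
            y = calls[kept].to_numpy(dtype=float)
            r = np.corrcoef(x, y)[0, 1]
            if abs(r) >= 1.0 - 1e-12:
                dup = True
                break
        (aliased if dup else keep).append(snp)
    return keep, aliased


def select_variables(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    candidates: list[str] | None = None,
    method: str = "backward",
    threshold: float = 0.05,
    season_factor: bool = True,
) -> SelectionResult:
    """Deterministic SNP subset selection from a candidate panel.

    ``backward`` (default): joint OLS of DHS on all candidates (+ season),
    repeatedly removing the SNP with the largest coefficient p-value until
    all p <= threshold; ties broken by genomic position (larger position
    removed).  ``lasso``: season effects are projected out, SNP columns
    standardized, and an L1 path point at alpha = threshold selects the
    SNPs with nonzero coefficients.

    An empty selection is a valid result, not an exception.
    """
    if candidates is None:
        candidates = genotypes.snp_ids
    y, X, info = encode_design(phenotypes, genotypes, candidates, season_factor)
    monomorphic = info["monomorphic"]
    acc_ids = sorted(set(phenotypes["accession_id"]))
    acc_calls = genotypes.calls.loc[acc_ids]
    kept, aliased = _drop_aliased(acc_calls, genotypes.snps, info["testable"])

    if method == "backward":
        selected, removed = _backward_eliminate(
            phenotypes, genotypes, kept, threshold, season_factor
        )
    elif method == "lasso":
        selected, removed = _lasso_select(
            phenotypes, genotypes, kept, threshold, season_factor
        )
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return SelectionResult(
        selected=selected, removed=removed, monomorphic=monomorphic,
        aliased=aliased, method=method, threshold=threshold,
    )


def _backward_eliminate(phenotypes, genotypes, snps, threshold, season_factor):
    current = list(snps)
    removed: list[tuple[str, float]] = []
    positions = genotypes.snps["position"]
    while current:
        y, X, _ = encode_design(phenotypes, genotypes, current, season_factor)
        beta, se, df, _, _ = _ols(X.to_numpy(), y.to_numpy())
        pvals = _coef_pvalues(beta, se, df)
        cols = list(X.columns)
        snp_p = {s: pvals[cols.index(s)] for s in current}
        worst_p = max(snp_p.values())
        if worst_p <= threshold:
            break
        ties = [s for s, p in snp_p.items() if p == worst_p]
        victim = max(ties, key=lambda s: int(positions.loc[s]))
        current.remove(victim)
        removed.append((victim, float(worst_p)))
    return current, removed


def _lasso_select(phenotypes, genotypes, snps, alpha, season_factor):
    from sklearn.linear_model import Lasso

    if not snps:
        return [], []
    y, X, _ = encode_design(phenotypes, genotypes, snps, season_factor)
    yv = y.to_numpy()
    base_cols = [c for c in X.columns if c not in set(snps)]
    Z = X[base_cols].to_numpy()
    Q, _ = np.linalg.qr(Z)
    y_r = yv - Q @ (Q.T @ yv)
    S = X[list(snps)].to_numpy()
    S_r = S - Q @ (Q.T @ S)
    sd = S_r.std(axis=0)
    sd[sd == 0] = 1.0
    S_r = S_r / sd
    model = Lasso(alpha=alpha, fit_intercept=False, max_iter=50_000)
    model.fit(S_r, y_r)
    selected = [s for s, c in zip(snps, model.coef_) if c != 0.0]
    dropped = [(s, np.nan) for s in snps if s not in set(selected)]
    return selected, dropped


# ---------------------------------------------------------------------------
# prediction and multiple regression


def fit_prediction_model(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable | None = None,
    design_label: str = "accession+season",
    snp_subset: list[str] | None = None,
) -> PredictionReport:
    """In-sample DHS prediction from accession identity or SNP codes.

    ``accession+season`` — accession dummies + season dummies (the
    prediction ceiling); ``snps+season`` — 0/1 SNP columns + season dummies.
    Reports the regression of predicted on observed values.
    """
    y = phenotypes["dhs"].to_numpy(dtype=float)
    if design_label == "accession+season":
        lv = pd.Categorical(phenotypes["accession_id"].astype(str))
        accd = pd.get_dummies(lv, prefix="accession", drop_first=True, dtype=float)
        accd.index = phenotypes.index
        X = pd.concat(
            [pd.DataFrame({"Intercept": np.ones(len(phenotypes))},
                          index=phenotypes.index),
             accd, _season_dummies(phenotypes["season_id"])],
            axis=1,
        )
    elif design_label == "snps+season":
        if genotypes is None:
            raise ValueError("snps+season model needs a genotype table")
        _, X, _ = encode_design(phenotypes, genotypes, snp_subset, season_factor=True)
    else:
        raise ValueError(f"unknown design label {design_label!r}")

    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        from scipy.linalg import qr

        _, R, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[k]] for k in range(len(diag)) if diag[k] <= tol]
        raise RankDeficiencyError(aliased)
    beta, _, _, rss, tss = _ols(arr, y)
    predicted = arr @ beta
    model_r2 = 1.0 - rss / tss if tss > 0 else 0.0

    # regression of predicted on observed (the plotted line)
    xbar, ybar = y.mean(), predicted.mean()
    sxx = float(((y - xbar) ** 2).sum())
    sxy = float(((y - xbar) * (predicted - ybar)).sum())
    syy = float(((predicted - ybar) ** 2).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    r2 = (sxy * sxy) / (sxx * syy) if syy > 0 else 0.0
    return PredictionReport(
        model_label=design_label, observed=y, predicted=predicted,
        obs_pred_slope=float(slope), obs_pred_intercept=float(intercept),
        obs_pred_r2=float(r2), model_r2=float(model_r2), n=len(y),
    )


def _accession_mean_response(
    phenotypes: pd.DataFrame, genotypes: GenotypeTable, snp_subset
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Accession-level response (mean DHS over seasons) and SNP matrix.

    SNPs are accession-constant, so the accession mean over seasons is the
    response they can explain; season-replicated records would only dilute
    R² with within-accession variance.
    """
    if snp_subset is None:
        snp_subset = genotypes.snp_ids
    means = phenotypes.groupby("accession_id")["dhs"].mean().sort_index()
    S = genotypes.calls.loc[means.index, list(snp_subset)].to_numpy(dtype=float)
    if np.isnan(S).any():
        raise ValueError("missing genotype calls; filter upstream")
    return means.to_numpy(), S, list(snp_subset)


def standardized_coefficients(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    snp_subset: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Standardized partial regression coefficients of accession-mean DHS
    on the SNP subset, with t-test p-values and the model's multiple R².

    Response and predictors are z-scored (n-1 SD), so each coefficient is a
    scale-free effect size; with a single predictor it equals the Pearson r.
    """
    yv, S, names = _accession_mean_response(phenotypes, genotypes, snp_subset)
    const = [n for n, sd in zip(names, S.std(axis=0, ddof=1)) if sd == 0]
    if const:
        raise ValueError(f"constant predictors: {const}")
    yz = (yv - yv.mean()) / yv.std(ddof=1)
    Sz = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    X = np.hstack([np.ones((len(yz), 1)), Sz])
    beta, se, df, rss, tss = _ols(X, yz)
    pvals = _coef_pvalues(beta, se, df)
    table = pd.DataFrame(
        {"snp_id": names, "beta_std": beta[1:], "p_value": pvals[1:]}
    )
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return table, float(r2)


def refit_subset(
    phenotypes: pd.DataFrame,
    genotypes: GenotypeTable,
    snp_subset: list[str],
) -> ModelFitSummary:
    """OLS of accession-mean DHS on only the named SNPs; R², F, p.

    An empty subset yields the intercept-only model with R² = 0.
    """
    means = phenotypes.groupby("accession_id")["dhs"].mean().sort_index()
    yv = means.to_numpy()
    n = len(yv)
    if not snp_subset:
        return ModelFitSummary(
            label="snps:(none)", n=n, df_regression=0, df_error=n - 1,
            r2=0.0, adj_r2=0.0, f_value=np.nan, p_value=np.nan,
        )
    _, S, names = _accession_mean_response(phenotypes, genotypes, snp_subset)
    X = np.hstack([np.ones((n, 1)), S])
    beta, se, df, rss, tss = _ols(X, yv)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    k = len(names)
    f = (tss - rss) / k / (rss / df) if rss > 0 else np.inf
    p = float(stats.f.sf(f, k, df)) if np.isfinite(f) else 0.0
    adj = 1.0 - (1.0 - r2) * (n - 1) / df
    return ModelFitSummary(
        label="snps:" + "+".join(names), n=n, df_regression=k, df_error=df,
        r2=float(r2), adj_r2=float(adj), f_value=float(f), p_value=p,
    )
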