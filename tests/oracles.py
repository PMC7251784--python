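"""Independent brute-force oracles used by the test suite.

Deliberately naive: explicit loops and normal equations, sharing no code
with the package paths they check.
"""

import numpy as np
import pandas as pd


def ols_normal_equations(X: np.ndarray, y: np.ndarray) -> dict:
    """Solve (X'X) beta = X'y directly and derive fit statistics.

    X must include the intercept column and be full rank, <= 50 parameters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    fitted = X @ beta
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss
    df_reg = k - 1
    df_err = n - k
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df_err
    f = ((tss - rss) / df_reg) / (rss / df_err) if df_reg > 0 else np.nan
    return {
        "beta": beta, "fitted": fitted, "r2": r2, "adj_r2": adj_r2,
        "f": f, "df_regression": df_reg, "df_error": df_err, "rss": rss,
    }


def dummy_design(df: pd.DataFrame, columns: list[str]) -> np.ndarray:
    """Intercept + first-level-reference dummies, built by explicit loops."""
    n = len(df)
    cols = [np.ones(n)]
    for c in columns:
        levels = sorted(df[c].astype(str).unique())
        for lv in levels[1:]:
            cols.append((df[c].astype(str) == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def naive_column_means(phenotypes: pd.DataFrame) -> dict[str, float]:
    """Per-season mean DHS via an explicit loop."""
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for _, row in phenotypes.iterrows():
        s = row["season_id"]
        sums[s] = sums.get(s, 0.0) + row["dhs"]
        counts[s] = counts.get(s, 0) + 1
    return {s: sums[s] / counts[s] for s in sums}


def naive_simple_ols(x, y) -> tuple[float, float, float]:
    """Slope/intercept/r2 by accumulating sums in a loop."""
    n = len(x)
    sx = sum(x); sy = sum(y)
    sxx = sum(v * v for v in x); sxy = sum(a * b for a, b in zip(x, y))
    syy = sum(v * v for v in y)
    cxx = sxx - sx * sx / n
    cxy = sxy - sx * sy / n
    cyy = syy - sy * sy / n
    slope = cxy / cxx
    intercept = sy / n - slope * sx / n
    r2 = 0.0 if cyy == 0 else cxy * cxy / (cxx * cyy)
    return slope, intercept, r2


def naive_season_similarity(phenotypes: pd.DataFrame):
    """Pairwise r and MSE matrices via explicit accession loops."""
    wide = phenotypes.pivot(index="accession_id", columns="season_id", values="dhs")
    seasons = sorted(wide.columns)
    r = pd.DataFrame(index=seasons, columns=seasons, dtype=float)
    mse = pd.DataFrame(index=seasons, columns=seasons, dtype=float)
    for a in seasons:
        for b in seasons:
            xa = wide[a].to_numpy()
            xb = wide[b].to_numpy()
            d2 = [(u - v) ** 2 for u, v in zip(xa, xb)]
            mse.loc[a, b] = sum(d2) / len(d2)
            if a == b:
                r.loc[a, b] = 1.0
            else:
                _, _, r2 = naive_simple_ols(xa, xb)
                sign = 1.0 if naive_simple_ols(xa, xb)[0] >= 0 else -1.0
                r.loc[a, b] = sign * r2 ** 0.5
    return r, mse


def complete_accessions_bruteforce(phenotypes: pd.DataFrame,
                                   seasons: list[str]) -> list[str]:
    """Scan every accession's records against the required season list."""
    out = []
    for acc in sorted(phenotypes["accession_id"].unique()):
        have = set(phenotypes.loc[phenotypes["accession_id"] == acc, "season_id"])
        if all(s in have for s in seasons):
            out.append(acc)
    return out
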