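import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gxe.io_tables import GenotypeTable
from gxe.snp_association import (
    encode_design,
    fit_prediction_model,
    refit_subset,
    select_variables,
    single_marker_scan,
    standardized_coefficients,
)
from gxe.synthetic_data import SyntheticConfig, generate_dataset

from conftest import long_phenotypes
from oracles import ols_normal_equations


def _toy_panel():
    """4 accessions x 3 seasons, 2 SNPs with known codes."""
    phen = long_phenotypes(
        {
            "A1": {"s1": 150, "s2": 155, "s3": 160},
            "A2": {"s1": 152, "s2": 157, "s3": 163},
            "A3": {"s1": 158, "s2": 163, "s3": 168},
            "A4": {"s1": 159, "s2": 165, "s3": 171},
        }
    )
    calls = pd.DataFrame(
        {"snpA": [0.0, 0.0, 1.0, 1.0], "snpB": [0.0, 1.0, 0.0, 1.0]},
        index=pd.Index(["A1", "A2", "A3", "A4"], name="accession_id"),
    )
    snps = pd.DataFrame(
        {"gene": ["PPD-H1", "VRN1"], "position": [100, 200]},
        index=pd.Index(["snpA", "snpB"], name="snp_id"),
    )
    return phen, GenotypeTable(calls=calls, snps=snps)


def test_monomorphic_snp_flagged():
    phen, geno = _toy_panel()
    calls = geno.calls.copy()
    calls["snpC"] = 0.0
    snps = pd.concat(
        [geno.snps, pd.DataFrame({"gene": ["CO1"], "position": [300]},
                                 index=["snpC"])]
    )
    geno2 = GenotypeTable(calls=calls, snps=snps)
    _, _, info = encode_design(phen, geno2)
    assert info["monomorphic"] == ["snpC"]
    scan = {r.snp_id: r for r in single_marker_scan(phen, geno2)}
    assert not scan["snpC"].testable
    assert scan["snpC"].note == "monomorphic"


def test_design_column_bookkeeping():
    """2 SNPs + k seasons with intercept give 2 + (k-1) + 1 columns."""
    phen, geno = _toy_panel()
    _, X, _ = encode_design(phen, geno, season_factor=True)
    assert X.shape[1] == 2 + (3 - 1) + 1
    _, X0, _ = encode_design(phen, geno, season_factor=False)
    assert X0.shape[1] == 3


def test_design_matches_hand_construction():
    phen, geno = _toy_panel()
    y, X, _ = encode_design(phen, geno, season_factor=False)
    snp_a = {"A1": 0, "A2": 0, "A3": 1, "A4": 1}
    snp_b = {"A1": 0, "A2": 1, "A3": 0, "A4": 1}
    hand = np.column_stack(
        [
            np.ones(len(phen)),
            [snp_a[a] for a in phen["accession_id"]],
            [snp_b[a] for a in phen["accession_id"]],
        ]
    )
    np.testing.assert_array_equal(X.to_numpy(), hand)
    np.testing.assert_array_equal(y.to_numpy(), phen["dhs"].to_numpy())


def test_scan_equals_joint_ols_oracle():
    """The residualized scan reproduces the SNP coefficient and p-value of
    the full joint OLS with season dummies."""
    cfg = SyntheticConfig(
        n_accessions=40, n_seasons=5, n_snps=6, n_causal_snps=2, seed=31,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
    )
    phen, geno, _, _ = generate_dataset(cfg)
    results = {r.snp_id: r for r in single_marker_scan(phen, geno)}
    for snp in geno.snp_ids[:3]:
        y, X, _ = encode_design(phen, geno, [snp], season_factor=True)
        ref = ols_normal_equations(X.to_numpy(), y.to_numpy())
        coef = ref["beta"][list(X.columns).index(snp)]
        assert results[snp].coefficient == pytest.approx(coef, rel=1e-8)
        # p from the oracle's t statistic
        n, k = X.shape
        xtx_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
        se = np.sqrt(ref["rss"] / (n - k) * xtx_inv[list(X.columns).index(snp),
                                                    list(X.columns).index(snp)])
        p_ref = 2 * stats.t.sf(abs(coef) / se, n - k)
        assert results[snp].p_value == pytest.approx(p_ref, rel=1e-6)


def test_perfect_marker_hits_separation_limit():
    """A noiseless SNP splitting two phenotype constants drives p to 0."""
    phen = long_phenotypes(
        {a: {"s1": 150.0, "s2": 150.0} for a in ["A1", "A2"]}
        | {a: {"s1": 160.0, "s2": 160.0} for a in ["A3", "A4"]}
    )
    calls = pd.DataFrame(
        {"snpA": [0.0, 0.0, 1.0, 1.0]},
        index=pd.Index(["A1", "A2", "A3", "A4"], name="accession_id"),
    )
    geno = GenotypeTable(calls=calls)
    (r,) = single_marker_scan(phen, geno, season_factor=False)
    assert r.p_value == 0.0
    assert np.isinf(r.neg_log10_p)
    assert r.note == "separation-limit"
    assert r.coefficient == pytest.approx(10.0, abs=1e-9)


def test_causal_snp_tops_scan():
    """A 5-day causal SNP at n = 234 attains the panel's maximum -log10 p."""
    for seed in range(5):
        cfg = SyntheticConfig(
            n_accessions=234, n_seasons=20, n_snps=20, n_causal_snps=1,
            snp_effect_fixed=5.0, noise_sd=3.0, seed=100 + seed,
            missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
        )
        phen, geno, _, truth = generate_dataset(cfg)
        scan = single_marker_scan(phen, geno)
        best = max((r for r in scan if r.testable), key=lambda r: r.neg_log10_p)
        assert best.snp_id == truth.causal_snps[0]


def test_vacuous_threshold_retains_all(small_dataset):
    _, phen, geno, _, _ = small_dataset
    sel = select_variables(phen, geno, threshold=1.0)
    testable = [s for s in geno.snp_ids
                if s not in set(sel.monomorphic) | set(sel.aliased)]
    assert sorted(sel.selected) == sorted(testable)
    assert sel.removed == []


def test_duplicate_snp_column_aliased_selection_unchanged(small_dataset):
    """A perfectly collinear duplicate SNP is reported aliased and leaves
    the selected set unchanged up to the alias."""
    _, phen, geno, _, _ = small_dataset
    base = select_variables(phen, geno, threshold=0.05)
    dup_src = geno.snp_ids[0]
    calls = geno.calls.copy()
    calls["dup"] = calls[dup_src]
    snps = pd.concat(
        [geno.snps,
         pd.DataFrame({"gene": ["PPD-H1"], "position": [99_999_999]}, index=["dup"])]
    )
    geno2 = GenotypeTable(calls=calls, snps=snps)
    sel = select_variables(phen, geno2, threshold=0.05)
    assert "dup" in sel.aliased
    assert sorted(sel.selected) == sorted(base.selected)


def test_empty_selection_is_result_not_exception():
    """Pure-noise SNPs at a tiny threshold may all be eliminated."""
    cfg = SyntheticConfig(
        n_accessions=40, n_seasons=4, n_snps=5, n_causal_snps=0,
        noise_sd=5.0, seed=55,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
    )
    phen, geno, _, _ = generate_dataset(cfg)
    sel = select_variables(phen, geno, threshold=1e-12)
    assert sel.selected == [] or all(isinstance(s, str) for s in sel.selected)


def test_lasso_selection_deterministic_and_recovers_strong_effect():
    cfg = SyntheticConfig(
        n_accessions=120, n_seasons=8, n_snps=10, n_causal_snps=1,
        snp_effect_fixed=6.0, noise_sd=2.0, seed=77,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
    )
    phen, geno, _, truth = generate_dataset(cfg)
    sel1 = select_variables(phen, geno, method="lasso", threshold=1.0)
    sel2 = select_variables(phen, geno, method="lasso", threshold=1.0)
    assert sel1.selected == sel2.selected
    assert truth.causal_snps[0] in sel1.selected


def test_prediction_saturated_model_on_zero_noise():
    cfg = SyntheticConfig(
        n_accessions=20, n_seasons=5, slope_sd=0.0, noise_sd=0.0, seed=9,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
    )
    phen, _, _, _ = generate_dataset(cfg)
    rep = fit_prediction_model(phen, design_label="accession+season")
    assert rep.obs_pred_r2 == pytest.approx(1.0, abs=1e-9)
    assert rep.model_r2 == pytest.approx(1.0, abs=1e-9)


def test_accession_model_dominates_snp_model(small_dataset):
    """Accession dummies span any accession-constant SNP coding, so the
    SNPs+season R² can never exceed the accession+season R²."""
    _, phen, geno, _, _ = small_dataset
    ceiling = fit_prediction_model(phen, design_label="accession+season")
    snp_rep = fit_prediction_model(phen, geno, design_label="snps+season")
    assert snp_rep.model_r2 <= ceiling.model_r2 + 1e-12


def test_obs_pred_slope_equals_model_r2_oracle():
    cfg = SyntheticConfig(
        n_accessions=10, n_seasons=4, n_snps=3, n_causal_snps=1, seed=14,
        missing_phenotype_fraction=0.0, missing_genotype_fraction=0.0,
    )
    phen, geno, _, _ = generate_dataset(cfg)
    rep = fit_prediction_model(phen, geno, design_label="snps+season")
    y, X, _ = encode_design(phen, geno, season_factor=True)
    ref = ols_normal_equations(X.to_numpy(), y.to_numpy())
    assert rep.model_r2 == pytest.approx(ref["r2"], rel=1e-10)
    assert rep.obs_pred_slope == pytest.approx(ref["r2"], rel=1e-10)
    assert rep.obs_pred_r2 == pytest.approx(ref["r2"], rel=1e-10)


def test_standardized_beta_single_predictor_is_pearson_r():
    phen, geno = _toy_panel()
    tab, _ = standardized_coefficients(phen, geno, ["snpA"])
    means = phen.groupby("accession_id")["dhs"].mean().sort_index()
    r, _ = stats.pearsonr(geno.calls.loc[means.index, "snpA"], means)
    assert tab.loc[0, "beta_std"] == pytest.approx(r, abs=1e-12)


def test_standardized_beta_scale_invariant():
    phen, geno = _toy_panel()
    tab1, r2_1 = standardized_coefficients(phen, geno, ["snpA", "snpB"])
    scaled = GenotypeTable(calls=geno.calls.copy(), snps=geno.snps.copy())
    scaled.calls["snpA"] = scaled.calls["snpA"] * 1.0  # keep valid codes
    scaled.calls.loc[:, "snpB"] = scaled.calls["snpB"]
    # bypass code validation to rescale a column by a positive constant
    scaled.calls["snpA"] *= 3.0
    tab2, r2_2 = standardized_coefficients(phen, scaled, ["snpA", "snpB"])
    assert np.allclose(tab1["beta_std"], tab2["beta_std"], atol=1e-12)
    assert r2_1 == pytest.approx(r2_2, abs=1e-12)


def test_orthogonal_predictors_betas_equal_marginal_correlations():
    """On the balanced 2x2 SNP design the predictors are orthogonal after
    centering, so each standardized beta equals its marginal r (brute force)."""
    phen, geno = _toy_panel()
    tab, _ = standardized_coefficients(phen, geno, ["snpA", "snpB"])
    means = phen.groupby("accession_id")["dhs"].mean().sort_index()
    for i, snp in enumerate(["snpA", "snpB"]):
        r, _ = stats.pearsonr(geno.calls.loc[means.index, snp], means)
        assert tab.loc[i, "beta_std"] == pytest.approx(r, abs=1e-10)
    yz = (means - means.mean()) / means.std(ddof=1)
    Xz = np.column_stack(
        [np.ones(4)]
        + [
            (geno.calls[s] - geno.calls[s].mean()) / geno.calls[s].std(ddof=1)
            for s in ["snpA", "snpB"]
        ]
    )
    ref = ols_normal_equations(Xz, yz.to_numpy())
    assert np.allclose(tab["beta_std"], ref["beta"][1:], atol=1e-10)


def test_refit_identity_and_empty_subset(small_dataset):
    _, phen, geno, _, _ = small_dataset
    polymorphic = [s for s in geno.snp_ids if geno.calls[s].nunique() > 1]
    full_tab, full_r2 = standardized_coefficients(phen, geno, polymorphic)
    refit = refit_subset(phen, geno, polymorphic)
    assert refit.r2 == pytest.approx(full_r2, abs=1e-10)
    empty = refit_subset(phen, geno, [])
    assert empty.r2 == 0.0 and empty.df_regression == 0


def test_refit_matches_oracle(small_dataset):
    _, phen, geno, _, _ = small_dataset
    subset = [s for s in geno.snp_ids if geno.calls[s].nunique() > 1][:3]
    refit = refit_subset(phen, geno, subset)
    means = phen.groupby("accession_id")["dhs"].mean().sort_index()
    X = np.column_stack(
        [np.ones(len(means))] + [geno.calls.loc[means.index, s] for s in subset]
    )
    ref = ols_normal_equations(X, means.to_numpy())
    assert refit.r2 == pytest.approx(ref["r2"], rel=1e-10)
    assert refit.f_value == pytest.approx(ref["f"], rel=1e-10)


def test_r2_monotone_in_subset_size(small_dataset):
    _, phen, geno, _, _ = small_dataset
    polymorphic = [s for s in geno.snp_ids if geno.calls[s].nunique() > 1]
    prev = -1.0
    for k in range(1, min(len(polymorphic), 6) + 1):
        r2 = refit_subset(phen, geno, polymorphic[:k]).r2
        assert r2 >= prev - 1e-12
        prev = r2
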