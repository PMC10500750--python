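import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from prsoverlap.evalmetrics import (
    DeltaMetrics,
    ModelFit,
    ModelSpec,
    auc,
    delong_delta_auc,
    evaluate,
    extra_ss_test,
    fit_model,
    nagelkerke_r2,
    stratified_kfold,
)
from prsoverlap.formats import PhenotypeTable


def _pheno(y, trait="binary", **covars):
    tab = pd.DataFrame({"sample_id": [f"s{i}" for i in range(len(y))], "phenotype": y})
    for k, v in covars.items():
        tab[k] = v
    return PhenotypeTable(tab, trait)


# ---------------------------------------------------------------------------
# AUC


def test_auc_trivial_cases():
    labels = np.array([0, 0, 1, 1])
    assert auc(labels.astype(float), labels) == 1.0
    assert auc(np.zeros(4), labels) == 0.5  # all ties, midrank
    assert auc(1.0 - labels, labels) == 0.0


def test_auc_requires_both_classes():
    with pytest.raises(ValueError, match="class"):
        auc(np.arange(4.0), np.ones(4))


def test_auc_matches_trapezoidal_roc(rng):
    from sklearn.metrics import roc_auc_score

    for _ in range(5):
        scores = rng.standard_normal(200)
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert abs(auc(scores, labels) - roc_auc_score(labels, scores)) < 1e-10


# ---------------------------------------------------------------------------
# DeLong


def test_delong_identical_scores_is_degenerate():
    rng = np.random.default_rng(1)
    scores = rng.standard_normal(100)
    labels = rng.integers(0, 2, 100)
    labels[:2] = [0, 1]
    delta, p = delong_delta_auc(scores, scores, labels)
    assert delta == 0.0 and p == 1.0


def test_delong_detects_a_real_auc_gain():
    rng = np.random.default_rng(2)
    n = 600
    labels = rng.integers(0, 2, n)
    weak = 0.2 * labels + rng.standard_normal(n)
    strong = 1.5 * labels + rng.standard_normal(n)
    delta, p = delong_delta_auc(weak, strong, labels)
    assert delta > 0.1
    assert p < 1e-6


def test_delong_p_agrees_with_paired_bootstrap(rng):
    """DeLong's analytic p matched against a paired-bootstrap test on a
    200-sample fixture."""
    n = 200
    labels = rng.integers(0, 2, n)
    labels[:2] = [0, 1]
    common = rng.standard_normal(n)
    s2 = 0.45 * labels + common + 0.8 * rng.standard_normal(n)
    s3 = 0.75 * labels + common + 0.8 * rng.standard_normal(n)
    delta, p = delong_delta_auc(s2, s3, labels)

    boot = np.empty(2000)
    for b in range(2000):
        idx = rng.integers(0, n, n)
        if len(np.unique(labels[idx])) < 2:
            boot[b] = np.nan
            continue
        boot[b] = auc(s3[idx], labels[idx]) - auc(s2[idx], labels[idx])
    boot = boot[~np.isnan(boot)]
    se = boot.std(ddof=1)
    from scipy import stats as st

    p_boot = 2 * st.norm.sf(abs(delta) / se)
    assert abs(p - p_boot) < 0.02


# ---------------------------------------------------------------------------
# model fitting


def test_model_i_quant_recovers_identity():
    rng = np.random.default_rng(3)
    y = rng.standard_normal(100)
    pheno = _pheno(y, "quantitative")
    fit = fit_model(pheno, y, None, ModelSpec("I", trait_type="quantitative"))
    assert abs(fit.params["PRS"] - 1.0) < 1e-8
    assert abs(fit.params["const"]) < 1e-8


def test_model_ii_balanced_intercept_near_zero():
    y = np.tile([0, 1], 50)
    pheno = _pheno(y)
    fit = fit_model(pheno, None, None, ModelSpec("II", [], 0, "binary"))
    assert abs(fit.params["const"]) < 1e-8


def test_model_iii_matches_direct_likelihood_oracle():
    """Coefficients agree with an independent numeric ML fit on a 50-sample
    fixture."""
    rng = np.random.default_rng(4)
    n = 50
    age = rng.standard_normal(n)
    prs = rng.standard_normal(n)
    logit = 0.3 + 0.5 * age + 0.8 * prs
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    pheno = _pheno(y, "binary", age=age)
    fit = fit_model(pheno, prs, None, ModelSpec("III", ["age"], 0, "binary"))

    X = np.column_stack([np.ones(n), age, prs])

    def negll(b):
        eta = X @ b
        return np.sum(np.log1p(np.exp(eta))) - y @ eta

    oracle = optimize.minimize(negll, np.zeros(3), method="BFGS", tol=1e-12).x
    assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-6)


def test_collinear_design_errors_with_names():
    rng = np.random.default_rng(5)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    x = rng.standard_normal(40)
    pheno = _pheno(y, "binary", a=x, b=2 * x)
    with pytest.raises(ValueError, match="collinear"):
        fit_model(pheno, None, None, ModelSpec("II", ["a", "b"], 0, "binary"))


def test_constant_prs_dropped_with_warning():
    rng = np.random.default_rng(6)
    y = rng.integers(0, 2, 40)
    y[:2] = [0, 1]
    pheno = _pheno(y, "binary", age=rng.standard_normal(40))
    fit = fit_model(pheno, np.ones(40), None, ModelSpec("III", ["age"], 0, "binary"))
    assert fit.dropped_columns == ["PRS"]
    assert "PRS" not in fit.params.index


# ---------------------------------------------------------------------------
# Nagelkerke


def test_nagelkerke_null_fit_is_zero():
    rng = np.random.default_rng(7)
    y = rng.integers(0, 2, 60)
    y[:2] = [0, 1]
    pheno = _pheno(y)
    null = fit_model(pheno, None, None, ModelSpec("II", [], 0, "binary"))
    assert nagelkerke_r2(null, null) == 0.0


def test_nagelkerke_matches_hand_formula_on_small_fixture():
    rng = np.random.default_rng(8)
    n = 20
    x = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-1.2 * x))).astype(int)
    y[:2] = [0, 1]
    pheno = _pheno(y, "binary", x=x)
    full = fit_model(pheno, None, None, ModelSpec("II", ["x"], 0, "binary"))
    null = fit_model(pheno, None, None, ModelSpec("II", [], 0, "binary"))

    # direct-likelihood oracle: saturated-intercept and numeric full LLs
    p0 = y.mean()
    ll0 = np.sum(y * np.log(p0) + (1 - y) * np.log(1 - p0))
    X = np.column_stack([np.ones(n), x])

    def negll(b):
        eta = X @ b
        return np.sum(np.log1p(np.exp(eta))) - y @ eta

    ll1 = -optimize.minimize(negll, np.zeros(2), method="BFGS", tol=1e-13).fun
    expected = (1 - np.exp((2 / n) * (ll0 - ll1))) / (1 - np.exp((2 / n) * ll0))
    assert abs(nagelkerke_r2(full, null) - expected) < 1e-8


def test_nagelkerke_separating_covariate_approaches_one():
    y = np.tile([0, 1], 15)
    pheno = _pheno(y, "binary", x=y.astype(float))
    full = fit_model(pheno, None, None, ModelSpec("II", ["x"], 0, "binary"))
    null = fit_model(pheno, None, None, ModelSpec("II", [], 0, "binary"))
    assert nagelkerke_r2(full, null) > 0.99


def test_nagelkerke_nesting_violation_errors():
    fit = ModelFit(pd.Series(dtype=float), np.zeros(10), 10, True, "binary", llf=-9.0)
    null = ModelFit(pd.Series(dtype=float), np.zeros(10), 10, True, "binary", llf=-5.0)
    with pytest.raises(ValueError, match="nesting"):
        nagelkerke_r2(fit, null)


# ---------------------------------------------------------------------------
# extra sum of squares


def test_extra_ss_f_equals_squared_t():
    import statsmodels.api as sm

    rng = np.random.default_rng(9)
    n = 80
    age = rng.standard_normal(n)
    prs = rng.standard_normal(n)
    y = 0.4 * age + 0.3 * prs + rng.standard_normal(n)
    pheno = _pheno(y, "quantitative", age=age)
    fit2 = fit_model(pheno, prs, None, ModelSpec("II", ["age"], 0, "quantitative"))
    fit3 = fit_model(pheno, prs, None, ModelSpec("III", ["age"], 0, "quantitative"))
    tss = float(((y - y.mean()) ** 2).sum())
    _, F, p = extra_ss_test(fit2, fit3, tss)
    t = sm.OLS(y, sm.add_constant(np.column_stack([age, prs]))).fit().tvalues[2]
    assert abs(F - t**2) < 1e-8


def test_extra_ss_identical_models_give_f_zero_p_one():
    fit = ModelFit(pd.Series(dtype=float), np.zeros(30), 30, True, "quantitative",
                   rss=10.0, df_model=2)
    delta, F, p = extra_ss_test(fit, fit, tss=20.0)
    assert (delta, F, p) == (0.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# stratified folds


def test_stratified_kfold_balanced_binary():
    rng = np.random.default_rng(10)
    y = np.repeat([0, 1], 500)
    pheno = _pheno(rng.permutation(y))
    folds = stratified_kfold(pheno, ["phenotype"], k=10, seed=0)
    lookup = pheno.table.set_index("sample_id")["phenotype"]
    all_test = []
    for disc, test in folds:
        assert len(test) == 100
        cases = int(lookup.loc[test].sum())
        assert 49 <= cases <= 51
        assert set(disc) | set(test) == set(pheno.sample_ids)
        assert not set(disc) & set(test)
        all_test.extend(test)
    assert sorted(all_test) == sorted(pheno.sample_ids)


def test_stratified_kfold_deterministic_and_seed_sensitive():
    rng = np.random.default_rng(11)
    pheno = _pheno(rng.integers(0, 2, 200))
    a = stratified_kfold(pheno, k=5, seed=3)
    b = stratified_kfold(pheno, k=5, seed=3)
    c = stratified_kfold(pheno, k=5, seed=4)
    assert a == b
    assert a != c


def test_stratified_kfold_merges_tiny_strata():
    rng = np.random.default_rng(12)
    y = rng.integers(0, 2, 100)
    center = np.zeros(100)
    center[:3] = 1  # stratum of size 3 < k
    pheno = _pheno(y, "binary", center=center)
    folds = stratified_kfold(pheno, ["phenotype", "center"], k=5, seed=0)
    assert sum(len(t) for _, t in folds) == 100


# ---------------------------------------------------------------------------
# evaluate


def test_evaluate_zero_prs_gives_zero_deltas():
    rng = np.random.default_rng(13)
    y = rng.integers(0, 2, 120)
    y[:2] = [0, 1]
    pheno = _pheno(y, "binary", age=rng.standard_normal(120))
    dm = evaluate(np.zeros(120), pheno, None, "binary", ["age"], n_pcs=0)
    assert dm.delta_auc == 0.0
    assert dm.delta_r2 == 0.0


def test_evaluate_perfect_quant_prs():
    rng = np.random.default_rng(14)
    y = rng.standard_normal(150)
    pheno = _pheno(y, "quantitative", age=rng.standard_normal(150))
    dm = evaluate(y, pheno, None, "quantitative", ["age"], n_pcs=0)
    assert dm.r2_III > 0.999
    assert dm.delta_r2 > 0.9


def test_delta_metrics_affine_invariant_in_prs():
    rng = np.random.default_rng(15)
    n = 300
    y = rng.integers(0, 2, n)
    y[:2] = [0, 1]
    prs = 0.8 * y + rng.standard_normal(n)
    pheno = _pheno(y, "binary", age=rng.standard_normal(n))
    dm1 = evaluate(prs, pheno, None, "binary", ["age"], n_pcs=0)
    dm2 = evaluate(5.0 * prs - 7.0, pheno, None, "binary", ["age"], n_pcs=0)
    assert abs(dm1.delta_auc - dm2.delta_auc) < 1e-8
    assert abs(dm1.delta_r2 - dm2.delta_r2) < 1e-8
    assert abs(dm1.delong_p - dm2.delong_p) < 1e-8


def test_nagelkerke_monotone_when_regressors_added():
    rng = np.random.default_rng(16)
    n = 200
    age = rng.standard_normal(n)
    prs = rng.standard_normal(n)
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.5 * age + 0.5 * prs)))).astype(int)
    y[:2] = [0, 1]
    pheno = _pheno(y, "binary", age=age)
    dm = evaluate(prs, pheno, None, "binary", ["age"], n_pcs=0)
    assert 0.0 <= dm.r2_II <= dm.r2_III <= 1.0
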