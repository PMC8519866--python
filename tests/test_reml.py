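"""REML engine: closed forms, oracles, boundary tests, BIC, BLUPs."""

import numpy as np
import pytest
from scipy import stats

from mppqtl.models import estimate_parental_effects
from mppqtl.reml import (
    RandomTerm,
    bic,
    fit_reml,
    lrt_variance_component,
    wald_test_fixed,
)

from oracles import grid_search_reml, naive_reml_loglik


def _one_way(rng, groups=10, per_group=10, sd_between=1.5, sd_within=1.0):
    u = rng.normal(0, sd_between, groups)
    y = np.repeat(u, per_group) + rng.normal(0, sd_within, groups * per_group)
    Z = np.kron(np.eye(groups), np.ones((per_group, 1)))
    X = np.ones((groups * per_group, 1))
    return y, X, Z


def test_balanced_one_way_matches_anova_closed_form():
    rng = np.random.default_rng(42)
    y, X, Z = _one_way(rng)
    fit = fit_reml(y, X, [RandomTerm("group", factor=Z)])
    ybar = y.reshape(10, 10)
    msb = 10 * np.var(ybar.mean(axis=1), ddof=1)
    msw = float(np.mean(np.var(ybar, axis=1, ddof=1)))
    assert fit.varcomps["group"] == pytest.approx((msb - msw) / 10, abs=1e-6)
    assert fit.varcomps["residual"] == pytest.approx(msw, abs=1e-6)
    assert fit.converged


def test_constant_response_puts_variances_on_boundary():
    rng = np.random.default_rng(0)
    fit = fit_reml(
        np.ones(40), np.ones((40, 1)), [RandomTerm("q", factor=rng.normal(size=(40, 4)))]
    )
    assert fit.varcomps["q"] <= 1e-10
    assert fit.varcomps["residual"] <= 1e-10


def test_matches_grid_search_oracle_on_toy_problem():
    """12 observations, one QTL term + residual: 200x200 grid oracle."""
    rng = np.random.default_rng(5)
    n = 12
    M = rng.choice([0.0, 2.0], size=(n, 2))
    M[:, 1] = 2.0 - M[:, 0]
    y = M @ np.array([0.8, -0.8]) + rng.normal(0, 0.7, n)
    X = np.ones((n, 1))
    fit = fit_reml(y, X, [RandomTerm("qtl", factor=M)])
    structures = [M @ M.T, np.eye(n)]
    # square grids around the optimizer-free neighbourhood of the surface
    grids = [np.linspace(1e-6, 2.0, 200), np.linspace(0.05, 2.0, 200)]
    theta_grid, ll_grid = grid_search_reml(y, X, structures, grids)
    theta_fit = np.array([fit.varcomps["qtl"], fit.varcomps["residual"]])
    spacing = np.array([2.0 / 199, 1.95 / 199])
    assert np.all(np.abs(theta_fit - theta_grid) <= spacing + 1e-3)
    assert fit.loglik >= ll_grid - 1e-4
    assert fit.loglik == pytest.approx(
        naive_reml_loglik(y, X, structures, theta_fit), abs=1e-8
    )


def test_family_residual_variances_recovered_against_oracle():
    rng = np.random.default_rng(6)
    n = 12
    fam = np.repeat(["a", "b"], n // 2)
    y = np.concatenate([rng.normal(0, 0.5, 6), rng.normal(0, 2.0, 6)])
    X = np.ones((n, 1))
    fit = fit_reml(y, X, [], resid_groups=fam)
    d_a = np.diag((fam == "a").astype(float))
    d_b = np.diag((fam == "b").astype(float))
    grids = [np.linspace(0.01, 8.0, 200)] * 2
    theta_grid, ll_grid = grid_search_reml(y, X, [d_a, d_b], grids)
    theta_fit = np.array([fit.varcomps["residual[a]"], fit.varcomps["residual[b]"]])
    assert np.all(np.abs(theta_fit - theta_grid) <= 8.0 / 199 + 1e-3)
    assert fit.loglik >= ll_grid - 1e-4


def test_reml_invariant_to_location_shift():
    rng = np.random.default_rng(7)
    y, X, Z = _one_way(rng)
    f1 = fit_reml(y, X, [RandomTerm("g", factor=Z)])
    f2 = fit_reml(y + 57.3, X, [RandomTerm("g", factor=Z)])
    assert f1.varcomps["g"] == pytest.approx(f2.varcomps["g"], abs=1e-8)
    assert f1.varcomps["residual"] == pytest.approx(f2.varcomps["residual"], abs=1e-8)


def test_single_family_models_with_uniform_and_family_residual_agree():
    """With one family the family-specific residual degenerates to uniform."""
    rng = np.random.default_rng(8)
    n = 120
    M = 2.0 * np.column_stack([(rng.random((n, 4)) > 0.75)] ).reshape(n, 4)
    y = rng.normal(size=n) + M @ rng.normal(0, 0.5, 4)
    X = np.ones((n, 1))
    fit_u = fit_reml(y, X, [RandomTerm("qtl", factor=M)], resid_groups=None)
    fit_f = fit_reml(y, X, [RandomTerm("qtl", factor=M)], resid_groups=np.repeat("fam1", n))
    assert fit_u.loglik == pytest.approx(fit_f.loglik, abs=1e-8)
    assert fit_u.varcomps["qtl"] == pytest.approx(fit_f.varcomps["qtl"], abs=1e-8)


def test_dense_and_lowrank_backends_agree():
    from mppqtl.reml import _DenseEngine, _LowRankEngine, _build_comps

    rng = np.random.default_rng(9)
    n = 60
    F = rng.normal(size=(n, 4))
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.normal(size=n)
    comps, _ = _build_comps(
        [RandomTerm("q", factor=F), RandomTerm("d", diag=rng.random(n) + 0.1)],
        np.repeat(["a", "b"], n // 2),
        n,
    )
    theta = np.array([0.4, 0.9, 1.3, 0.6])
    ll_d, g_d, aux_d, ai_d = _DenseEngine(y, X, comps).value(theta, want_ai=True)
    ll_l, g_l, aux_l, ai_l = _LowRankEngine(y, X, comps).value(theta, want_ai=True)
    assert ll_d == pytest.approx(ll_l, abs=1e-9)
    assert np.allclose(g_d, g_l, atol=1e-9)
    assert np.allclose(ai_d, ai_l, atol=1e-9)
    assert np.allclose(aux_d["beta"], aux_l["beta"], atol=1e-9)


def test_agrees_with_statsmodels_random_intercept():
    import statsmodels.api as sm

    rng = np.random.default_rng(10)
    y, X, Z = _one_way(rng, groups=8, per_group=6, sd_between=1.0)
    fit = fit_reml(y, X, [RandomTerm("group", factor=Z)])
    groups = np.repeat(np.arange(8), 6)
    sm_fit = sm.MixedLM(y, X, groups=groups).fit(reml=True)
    assert fit.varcomps["group"] == pytest.approx(float(np.asarray(sm_fit.cov_re)[0, 0]), rel=1e-4)
    assert fit.varcomps["residual"] == pytest.approx(float(sm_fit.scale), rel=1e-4)


def test_singular_fixed_design_rejected():
    with pytest.raises(ValueError):
        fit_reml(np.arange(6.0), np.ones((6, 2)), [])


# ---------------------------------------------------------------------------
# likelihood-ratio test of a boundary variance
# ---------------------------------------------------------------------------


def test_lrt_boundary_mixture_reference_values():
    rng = np.random.default_rng(11)
    y, X, Z = _one_way(rng)
    null = fit_reml(y, X, [])
    alt = fit_reml(y, X, [RandomTerm("g", factor=Z)])
    t = lrt_variance_component(null, alt)
    assert t.statistic >= 0.0
    # closed-form mixture quantile: p = 0.5 P(chi2_1 >= 2.705543) = 0.05
    assert 0.5 * stats.chi2.sf(2.705543, 1) == pytest.approx(0.05, abs=1e-6)
    # degenerate comparison: identical fits give LRT 0 and p 1
    t0 = lrt_variance_component(alt, alt)
    assert t0.statistic == 0.0 and t0.p_value == 1.0


def test_lrt_rejects_mismatched_data():
    rng = np.random.default_rng(12)
    y, X, Z = _one_way(rng)
    f1 = fit_reml(y, X, [])
    f2 = fit_reml(y + 1.0, X, [])
    with pytest.raises(ValueError):
        lrt_variance_component(f1, f2)


def test_alternative_likelihood_never_below_null():
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = 50
        M = 2.0 * (rng.random((n, 4)) > 0.7)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        null = fit_reml(y, X, [])
        alt = fit_reml(y, X, [RandomTerm("qtl", factor=M)])
        assert alt.loglik >= null.loglik - 1e-7


# ---------------------------------------------------------------------------
# Wald test of a fixed marker effect
# ---------------------------------------------------------------------------


def test_wald_equals_ols_t_square_under_identity_covariance():
    rng = np.random.default_rng(14)
    n = 80
    x = rng.normal(size=n)
    y = 0.3 * x + rng.normal(size=n)
    X = np.column_stack([np.ones(n), x])
    fit = fit_reml(y, X, [])  # V = sigma^2 I
    t = wald_test_fixed(fit, coef_index=1)
    # closed form: (beta_hat / se)^2 from GLS with scalar covariance
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    sigma2 = fit.varcomps["residual"]
    se2 = sigma2 * xtx_inv[1, 1]
    assert t.statistic == pytest.approx(beta[1] ** 2 / se2, rel=1e-10)


def test_wald_null_p_values_are_uniform():
    rng = np.random.default_rng(15)
    n, n_markers = 300, 400
    base = np.exp(-np.abs(np.subtract.outer(np.arange(n), np.arange(n))) / 30.0)
    L = np.linalg.cholesky(base + 1e-6 * np.eye(n))
    y = L @ rng.normal(size=n) + rng.normal(size=n)
    kin = base
    term = [RandomTerm("polygenic", gram=kin)]
    X = np.ones((n, 1))
    null = fit_reml(y, X, term)
    th_g, th_e = null.varcomps["polygenic"], null.varcomps["residual"]
    V = th_g * kin + th_e * np.eye(n)
    Vinv = np.linalg.inv(V)
    ps = []
    for _ in range(n_markers):
        xq = rng.binomial(2, 0.4, size=n).astype(float)  # independent of y
        X_aug = np.column_stack([X, xq])
        cov = np.linalg.inv(X_aug.T @ Vinv @ X_aug)
        beta = cov @ (X_aug.T @ (Vinv @ y))
        w = beta[1] ** 2 / cov[1, 1]
        ps.append(stats.chi2.sf(w, 1))
    assert stats.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------


def test_bic_formula_values():
    assert bic(3, 2, 300, 3, -500.0) == pytest.approx(5 * np.log(300) + 1000.0)
    # one extra variance parameter at equal likelihood costs ln(n - r + DFf)
    delta = bic(3, 3, 300, 3, -500.0) - bic(3, 2, 300, 3, -500.0)
    assert delta == pytest.approx(np.log(300))
    assert bic(1, 0, 100, 1, -10.0) == pytest.approx(np.log(100) + 20.0)
    with pytest.raises(ValueError):
        bic(0, 1, 5, 6, -1.0)


# ---------------------------------------------------------------------------
# variance recovery and parental-effect BLUPs
# ---------------------------------------------------------------------------


def test_qtl_variance_recovered_across_replicates():
    rng = np.random.default_rng(16)
    n, true_var = 1000, 0.16
    estimates = []
    for _ in range(200):
        # inbred-style predictors: each row has one founder column at 2
        assign = rng.integers(0, 4, n)
        M = np.zeros((n, 4))
        M[np.arange(n), assign] = 2.0
        a = rng.normal(0.0, np.sqrt(true_var), 4)
        y = M @ a + rng.normal(size=n)
        fit = fit_reml(y, np.ones((n, 1)), [RandomTerm("qtl", factor=M)])
        estimates.append(fit.varcomps["qtl"])
    assert abs(np.mean(estimates) - true_var) / true_var < 0.15


def test_parental_effect_blups_recover_signs():
    rng = np.random.default_rng(17)
    hits = 0
    for _ in range(100):
        n = 200
        assign = rng.integers(0, 4, n)
        M = np.zeros((n, 4))
        M[np.arange(n), assign] = 2.0
        effects = np.array([0.5, 0.5, -0.5, -0.5])
        y = M @ effects + rng.normal(size=n)
        table, fit = estimate_parental_effects(
            y, "IBD.SQM_U", np.repeat("MAGIC1", n), {"q": M}
        )
        blups = table.loc["q"].to_numpy()
        if np.all(blups[:2] > 0) and np.all(blups[2:] < 0):
            hits += 1
    assert hits >= 95


def test_blups_are_zero_when_variance_is_zero_and_shrink_otherwise():
    rng = np.random.default_rng(18)
    n = 150
    assign = rng.integers(0, 4, n)
    M = np.zeros((n, 4))
    M[np.arange(n), assign] = 2.0
    X = np.ones((n, 1))

    y_null = rng.normal(size=n)  # no QTL effect
    fit0 = fit_reml(y_null, X, [RandomTerm("qtl", factor=M)])
    if fit0.varcomps["qtl"] == 0.0:
        assert np.all(fit0.blups["qtl"] == 0.0)

    y = M @ np.array([0.6, -0.2, 0.1, -0.5]) + rng.normal(size=n)
    fit = fit_reml(y, X, [RandomTerm("qtl", factor=M)])
    # shrinkage: BLUPs no larger in magnitude than GLS estimates of the
    # same contrasts (QTL columns as fixed effects, drop the intercept to
    # keep the design full rank)
    gls = np.linalg.lstsq(M, y - y.mean(), rcond=None)[0]
    assert np.max(np.abs(fit.blups["qtl"])) <= np.max(np.abs(gls)) + 1e-9
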