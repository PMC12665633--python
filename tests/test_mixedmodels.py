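"""Unit tests for mixed models, model selection and classical tests."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

import mesotox.mixedmodels as mm


# ---------------------------------------------------------------------------
# binomial GLMM (Laplace) against independent oracles


def _quadrature_negll(params, X, y, n, gidx, n_groups, nodes=25):
    """Adaptive Gauss-Hermite marginal negative log-likelihood oracle."""
    from scipy.special import gammaln, log_expit
    from scipy.optimize import minimize_scalar

    beta, log_sigma = params[:-1], params[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    t, w = np.polynomial.hermite_e.hermegauss(nodes)
    total = 0.0
    const = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    for g in range(n_groups):
        m = gidx == g

        def negj(u):
            z = eta[m] + u
            lp = log_expit(z)
            return -(const[m] + y[m] * lp + (n[m] - y[m]) * (lp - z)).sum() \
                + 0.5 * u * u / sigma ** 2

        res = minimize_scalar(negj, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-10})
        uhat = res.x
        # adaptive: curvature-scaled nodes around the conditional mode
        p = expit(eta[m] + uhat)
        h = (n[m] * p * (1 - p)).sum() + 1.0 / sigma ** 2
        sd = 1.0 / np.sqrt(h)
        u = uhat + sd * t
        z = eta[m][:, None] + u[None, :]
        lp = log_expit(z)
        ll = (const[m][:, None] + y[m][:, None] * lp
              + (n[m] - y[m])[:, None] * (lp - z)).sum(axis=0)
        # integrand f(u) phi(u; 0, sigma), substituted u = uhat + sd * t,
        # against the probabilists' GH weight exp(-t^2/2)
        dens = ll - 0.5 * u ** 2 / sigma ** 2 - np.log(sigma) + 0.5 * t ** 2
        total += np.log(np.sum(w * np.exp(dens))) + np.log(sd) - 0.5 * np.log(2 * np.pi)
    return -total


def _simulate_overdispersed(rng, n_groups=60, trials=25, sigma=0.6, b0=-0.3, b1=0.5):
    x = rng.uniform(0, 2, n_groups)
    u = rng.normal(0, sigma, n_groups)
    p = expit(b0 + b1 * x + u)
    y = rng.binomial(trials, p)
    return pd.DataFrame({"y": y, "n": trials, "x": x,
                         "g": [f"g{i}" for i in range(n_groups)]})


def test_laplace_glmm_matches_quadrature_oracle(rng):
    df = _simulate_overdispersed(rng)
    spec = mm.ModelSpec(response=("y", "n"), family="binomial",
                        fixed=(("x", "identity"),), group="g")
    fit = mm.fit_binomial_glmm(spec, df, seed=0)
    X = np.column_stack([np.ones(len(df)), df["x"]])
    gidx = pd.factorize(df["g"])[0]
    from scipy.optimize import minimize
    start = np.concatenate([fit.coefficients["estimate"].to_numpy(),
                            [0.5 * np.log(max(fit.re_var, 1e-4))]])
    res = minimize(_quadrature_negll, start,
                   args=(X, df["y"].to_numpy(float), df["n"].to_numpy(float),
                         gidx, len(set(gidx))),
                   method="Nelder-Mead", options={"xatol": 1e-8, "fatol": 1e-10,
                                                  "maxiter": 4000})
    oracle_beta = res.x[:-1]
    np.testing.assert_allclose(fit.coefficients["estimate"].to_numpy(),
                               oracle_beta, atol=1e-3)


def test_glmm_zero_variance_reduces_to_glm(rng):
    """With the random-effect variance forced to 0 the fit equals plain GLM."""
    import statsmodels.api as sm
    df = _simulate_overdispersed(rng, n_groups=80, sigma=0.0)
    spec = mm.ModelSpec(response=("y", "n"), family="binomial",
                        fixed=(("x", "identity"),), group="g")
    fit = mm.fit_binomial_glmm(spec, df, seed=1, sigma_fixed=0.0)
    X = np.column_stack([np.ones(len(df)), df["x"]])
    Y = np.column_stack([df["y"], df["n"] - df["y"]]).astype(float)
    glm = sm.GLM(Y, X, family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.coefficients["estimate"].to_numpy(),
                               np.asarray(glm.params), atol=1e-6)
    # unconstrained fit on no-overdispersion data lands near the boundary too
    free = mm.fit_binomial_glmm(spec, df, seed=1)
    np.testing.assert_allclose(free.coefficients["estimate"].to_numpy(),
                               np.asarray(glm.params), atol=0.05)


# ---------------------------------------------------------------------------
# Gaussian LMM


def test_lmm_balanced_design_closed_form(rng):
    """Balanced one-way layout: intercept = grand mean; variance components
    match the classical ANOVA method-of-moments estimators (REML equals them
    exactly in the balanced case)."""
    g, m = 12, 6
    sig_a, sig_e = 0.8, 0.5
    a = rng.normal(0, sig_a, g)
    y = (a[:, None] + rng.normal(0, sig_e, (g, m))).ravel()
    df = pd.DataFrame({"y": y, "tank": np.repeat([f"t{i}" for i in range(g)], m)})
    fit = mm.fit_lmm(mm.ModelSpec(response="y", fixed=(), group="tank",
                                  estimation="REML"), df)
    assert fit.coef("(Intercept)") == pytest.approx(y.mean(), abs=1e-6)
    ybar = y.reshape(g, m).mean(axis=1)
    msa = m * ybar.var(ddof=1)
    mse = (y.reshape(g, m) - ybar[:, None]).var() * g * m / (g * (m - 1))
    assert fit.resid_var == pytest.approx(mse, rel=1e-3)
    assert fit.re_var == pytest.approx((msa - mse) / m, rel=1e-2)


def test_lmm_recovers_slope(rng):
    tanks = [f"t{i}" for i in range(30)]
    x = rng.uniform(0, 10, 30)
    u = rng.normal(0, 0.5, 30)
    rows = []
    for i, t in enumerate(tanks):
        for _ in range(8):
            rows.append({"y": 2 ** (1.0 + 0.2 * x[i] + u[i] + rng.normal(0, 0.4)),
                         "x": x[i], "tank": t})
    df = pd.DataFrame(rows)
    fit = mm.fit_lmm(mm.ModelSpec(response="y", fixed=(("x", "identity"),),
                                  group="tank", estimation="REML",
                                  log2_response=True), df)
    row = fit.coefficients.set_index("term").loc["x"]
    assert row["ci_low"] < 0.2 < row["ci_high"]


# ---------------------------------------------------------------------------
# AICc


def test_aicc_identity_and_comparison():
    f1 = mm.FitResult(spec=mm.ModelSpec(response="y"), coefficients=pd.DataFrame(),
                      re_var=0, resid_var=1, loglik=-50.0, n=40, k=3, converged=True)
    expected = 100 + 6 + 2 * 3 * 4 / (40 - 4)
    assert f1.aicc == pytest.approx(expected)
    tab = mm.aicc_compare({"a": f1, "b": f1})
    assert np.allclose(tab["delta_aicc"], 0)
    assert tab["equivalent"].all()
    # n >> k: AICc -> AIC
    f2 = mm.FitResult(spec=mm.ModelSpec(response="y"), coefficients=pd.DataFrame(),
                      re_var=0, resid_var=1, loglik=-50.0, n=10**6, k=3, converged=True)
    assert f2.aicc == pytest.approx(f2.aic, abs=1e-4)


def test_aicc_refuses_mixed_rows():
    f1 = mm.FitResult(spec=mm.ModelSpec(response="y"), coefficients=pd.DataFrame(),
                      re_var=0, resid_var=1, loglik=-50.0, n=40, k=3, converged=True)
    f2 = mm.FitResult(spec=mm.ModelSpec(response="y"), coefficients=pd.DataFrame(),
                      re_var=0, resid_var=1, loglik=-48.0, n=41, k=3, converged=True)
    with pytest.raises(ValueError):
        mm.aicc_compare({"a": f1, "b": f2})


# ---------------------------------------------------------------------------
# ANOVA + Tukey, Kruskal-Wallis


def test_anova_two_groups_equals_t_squared(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 15)
    vals = np.concatenate([a, b])
    grp = np.array(["a"] * 12 + ["b"] * 15)
    F, df, p, _ = mm.anova_tukey(vals, grp)
    t, pt = stats.ttest_ind(a, b)
    assert F == pytest.approx(t ** 2, rel=1e-10)
    assert p == pytest.approx(pt, rel=1e-10)
    assert df == (1, 25)


def test_anova_constant_data():
    vals = np.ones(12)
    grp = np.repeat(["a", "b", "c"], 4)
    F, df, p, pair = mm.anova_tukey(vals, grp)
    assert F == 0.0 and p == 1.0


def test_kruskal_identical_groups():
    vals = np.ones(10)
    grp = np.repeat(["a", "b"], 5)
    assert mm.kruskal_wallis(vals, grp) == (0.0, 1.0)


def test_kruskal_matches_scipy(rng):
    vals = rng.normal(0, 1, 30)
    grp = np.repeat(["a", "b", "c"], 10)
    H, p = mm.kruskal_wallis(vals, grp)
    Hs, ps = stats.kruskal(vals[:10], vals[10:20], vals[20:])
    assert (H, p) == (pytest.approx(Hs), pytest.approx(ps))


# ---------------------------------------------------------------------------
# BCa bootstrap


def test_bca_constant_input():
    est, lo, hi = mm.bca_bootstrap_ci(np.full(10, 2.5), B=1000, seed=1)
    assert (est, lo, hi) == (2.5, 2.5, 2.5)


def test_bca_reduces_to_percentile_on_symmetric_data(rng):
    vals = rng.normal(10, 2, 1500)
    est, lo, hi = mm.bca_bootstrap_ci(vals, B=2000, seed=2)
    boot = np.array([rng.choice(vals, vals.size).mean() for _ in range(2000)])
    plo, phi = np.quantile(boot, [0.025, 0.975])
    # symmetric data: z0 ~ 0 and a ~ 0, so BCa ~ percentile interval
    width = phi - plo
    assert lo == pytest.approx(plo, abs=0.25 * width)
    assert hi == pytest.approx(phi, abs=0.25 * width)


def test_bca_deterministic_under_seed(rng):
    vals = rng.lognormal(1, 0.8, 25)
    r1 = mm.bca_bootstrap_ci(vals, B=2000, seed=9)
    r2 = mm.bca_bootstrap_ci(vals, B=2000, seed=9)
    assert r1 == r2


# ---------------------------------------------------------------------------
# Holm-Bonferroni


def test_holm_worked_example():
    np.testing.assert_allclose(mm.holm_bonferroni([0.01, 0.04]), [0.02, 0.04])


def test_holm_single_p_unchanged():
    np.testing.assert_allclose(mm.holm_bonferroni([0.3]), [0.3])


def test_holm_properties(rng):
    p = rng.uniform(0, 1, 20)
    adj = mm.holm_bonferroni(p)
    assert np.all(adj >= p)
    # order invariance
    perm = rng.permutation(20)
    assert np.allclose(mm.holm_bonferroni(p[perm]), adj[perm])
    # matches the step-down definition computed directly
    order = np.argsort(p)
    m = len(p)
    direct = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        direct[idx] = running
    assert np.allclose(adj, direct)


# ---------------------------------------------------------------------------
# sex-ratio model


def test_sex_ratio_gosner_filter_boundary(default_dataset, conc):
    td = default_dataset.tadpoles
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mm.fit_sex_ratio_glmm(td, conc, seed=3)
    n_eligible = int(((td["gosner_stage"] >= 36) & td["survived"]).sum())
    assert fit.n == n_eligible
    # stage 35 must be excluded, stage 36 included
    assert (td[td["gosner_stage"] == 35.0].shape[0] == 0
            or fit.n < int(td["survived"].sum()))


def test_sex_ratio_null_effect(default_dataset, conc):
    """Sexes are assigned 50:50 independently of dose, so no effect is found."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = mm.fit_sex_ratio_glmm(default_dataset.tadpoles, conc, seed=3)
    row = fit.coefficients.set_index("term").loc["log2(conc+1)"]
    assert abs(row["estimate"]) < 3 * row["se"] + 0.5
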