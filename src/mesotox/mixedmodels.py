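"""Likelihood-based mixed models and classical tests for endpoint analyses.

Covers the amphipod growth/reproduction and tadpole endpoints: binomial GLMMs
with a single random intercept (including observation-level random effects for
overdispersion), Gaussian LMMs, AICc model selection, one-way ANOVA with Tukey
HSD, Kruskal-Wallis, BCa bootstrap intervals and Holm-Bonferroni adjustment.

The binomial GLMM uses a Laplace-approximated marginal likelihood maximized by
bounded quasi-Newton with random restarts.  Gaussian LMMs are profiled REML/ML
fits via statsmodels MixedLM.  Model transforms follow the experiment's
conventions: concentrations enter as log2(c + 1) ("log2_plus1"), so slopes are
per-doubling effects; "poly2" adds a centered quadratic term for curvature in
Gosner stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, log_expit

__all__ = [
    "ModelSpec",
    "FitResult",
    "fit_binomial_glmm",
    "fit_lmm",
    "aicc_compare",
    "anova_tukey",
    "kruskal_wallis",
    "bca_bootstrap_ci",
    "holm_bonferroni",
    "fit_sex_ratio_glmm",
    "development_rate",
    "hepatosomatic_index",
]

TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda v: v,
    "log2_plus1": lambda v: np.log2(np.asarray(v, float) + 1.0),
}


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``fixed`` is a list of (column, transform) pairs; transform is one of
    "identity", "log2_plus1", "poly2" (centered linear + quadratic terms).
    ``response``: column name (gaussian) or (successes, trials) pair
    (binomial; trials may be a column name or an integer for Bernoulli rows).
    """
    response: str | tuple
    family: str = "gaussian"
    fixed: tuple = ()
    group: str | None = None
    estimation: str = "ML"          # ML | REML (gaussian); Laplace (binomial)
    log2_response: bool = False

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "binomial" and not isinstance(self.response, (tuple, list)):
            raise ValueError("binomial family requires (successes, trials) response")


@dataclass
class FitResult:
    spec: ModelSpec
    coefficients: pd.DataFrame       # term, estimate, se, ci_low, ci_high, p
    re_var: float                    # random-intercept variance
    resid_var: float | None
    loglik: float
    n: int
    k: int
    converged: bool
    fitted: np.ndarray | None = None
    notes: list[str] = field(default_factory=list)

    @property
    def aicc(self) -> float:
        n, k = self.n, self.k
        if n <= k + 1:
            return np.inf
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.k

    def coef(self, term: str) -> float:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["estimate"])


def _design(data: pd.DataFrame, fixed: Sequence) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for col, transform in fixed:
        v = np.asarray(data[col], dtype=float)
        if transform == "poly2":
            c = v - v.mean()
            cols.extend([c, c ** 2])
            names.extend([col, f"{col}^2"])
        elif transform in TRANSFORMS:
            cols.append(TRANSFORMS[transform](v))
            names.append(col if transform == "identity" else f"log2({col}+1)")
        else:
            raise ValueError(f"unknown transform {transform!r}")
    return np.column_stack(cols), names


def _resolve_binomial(data: pd.DataFrame, response) -> tuple[np.ndarray, np.ndarray]:
    succ_col, trials = response
    y = np.asarray(data[succ_col], dtype=float)
    n = (np.full(len(data), float(trials)) if isinstance(trials, (int, float))
         else np.asarray(data[trials], dtype=float))
    if np.any(y < 0) or np.any(n < y):
        raise ValueError("need trials >= successes >= 0")
    return y, n


# ---------------------------------------------------------------------------
# binomial GLMM via Laplace approximation


class _LaplaceBinomial:
    def __init__(self, X, y, n, groups):
        self.X, self.y, self.n = X, y, n
        self.gidx, self.glabels = pd.factorize(groups)
        self.G = len(self.glabels)
        order = np.argsort(self.gidx, kind="stable")
        self.order = order
        self.Xs, self.ys, self.ns = X[order], y[order], n[order]
        self.gs = self.gidx[order]
        self.starts = np.searchsorted(self.gs, np.arange(self.G))
        self.binom_const = (gammaln(self.ns + 1) - gammaln(self.ys + 1)
                            - gammaln(self.ns - self.ys + 1))

    def _gsum(self, v):
        return np.add.reduceat(v, self.starts)

    def neg_marginal(self, params: np.ndarray) -> float:
        beta, log_sigma = params[:-1], params[-1]
        sigma2 = np.exp(2.0 * log_sigma)
        eta0 = self.Xs @ beta
        u = np.zeros(self.G)
        for _ in range(100):
            z = eta0 + u[self.gs]
            p = expit(z)
            g = self._gsum(self.ys - self.ns * p) - u / sigma2
            h = self._gsum(self.ns * p * (1 - p)) + 1.0 / sigma2
            step = g / h
            u += np.clip(step, -2.0, 2.0)
            if np.max(np.abs(step)) < 1e-12:
                break
        z = eta0 + u[self.gs]
        lp = log_expit(z)
        ll = self.binom_const + self.ys * lp + (self.ns - self.ys) * (lp - z)
        h = self._gsum(self.ns * expit(z) * expit(-z)) + 1.0 / sigma2
        lap = (self._gsum(ll) - 0.5 * u ** 2 / sigma2
               - 0.5 * np.log(sigma2 * h))
        return -float(lap.sum())


def fit_binomial_glmm(spec: ModelSpec, data: pd.DataFrame,
                      n_restarts: int = 5, seed: int = 0,
                      sigma_fixed: float | None = None) -> FitResult:
    """Binomial GLMM with one random intercept, Laplace maximum likelihood.

    With ``spec.group=None`` an observation-level random effect is used (one
    intercept per row), the standard device for extra-binomial variation.
    ``sigma_fixed=0`` constrains the random-intercept standard deviation to
    zero, reducing the model to a plain binomial GLM.  Coefficients are on the
    logit scale; ``predict_conditional`` on the result is the u = 0
    (average-group) probability at the fitted coefficients.
    """
    y, n = _resolve_binomial(data, spec.response)
    X, names = _design(data, spec.fixed)
    groups = (data[spec.group].to_numpy() if spec.group is not None
              else np.arange(len(data)))
    mod = _LaplaceBinomial(X, y, n, groups)
    if sigma_fixed is not None and sigma_fixed == 0.0:
        return _fit_glm_fixed(spec, mod, X, names, data)

    # plain GLM start
    import statsmodels.api as sm
    glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
    try:
        glm_res = glm.fit()
        beta0 = np.asarray(glm_res.params)
    except Exception:
        beta0 = np.zeros(X.shape[1])
    beta0 = np.clip(beta0, -10, 10)

    rng = np.random.default_rng(seed)
    best = None
    p0s = [np.concatenate([beta0, [np.log(0.5)]])]
    for _ in range(n_restarts - 1):
        p0s.append(np.concatenate([beta0 + rng.normal(0, 0.5, len(beta0)),
                                   [rng.normal(-0.5, 0.8)]]))
    for p0 in p0s:
        res = optimize.minimize(mod.neg_marginal, p0, method="L-BFGS-B",
                                bounds=[(-30, 30)] * len(beta0) + [(-8, 3)])
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    converged = bool(best.success) or np.isfinite(best.fun)
    params = best.x
    beta, sigma = params[:-1], float(np.exp(params[-1]))

    se = _wald_se(mod.neg_marginal, params)[: len(beta)]
    zval = beta / np.where(se > 0, se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(zval))
    coefs = pd.DataFrame({
        "term": names, "estimate": beta, "se": se,
        "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se, "p": pvals,
    })
    fitted = expit(X @ beta)
    notes = []
    if sigma < 1e-4:
        notes.append("singular fit: random-intercept variance at boundary (~0)")
    if np.any(np.abs(beta) > 15):
        notes.append("possible complete separation: extreme coefficient")
        warnings.warn("possible complete separation in binomial GLMM", stacklevel=2)
    return FitResult(spec=spec, coefficients=coefs, re_var=sigma ** 2,
                     resid_var=None, loglik=-float(best.fun), n=len(data),
                     k=len(beta) + 1, converged=converged, fitted=fitted,
                     notes=notes)


def _fit_glm_fixed(spec: ModelSpec, mod: _LaplaceBinomial, X: np.ndarray,
                   names: list[str], data: pd.DataFrame) -> FitResult:
    """Degenerate sigma = 0 case: iteratively reweighted plain GLM."""
    import statsmodels.api as sm
    y, n = mod.y, mod.n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(np.column_stack([y, n - y]), X,
                     family=sm.families.Binomial()).fit()
    beta, se = np.asarray(res.params), np.asarray(res.bse)
    coefs = pd.DataFrame({
        "term": names, "estimate": beta, "se": se,
        "ci_low": beta - 1.96 * se, "ci_high": beta + 1.96 * se,
        "p": 2 * stats.norm.sf(np.abs(beta / se)),
    })
    return FitResult(spec=spec, coefficients=coefs, re_var=0.0, resid_var=None,
                     loglik=float(res.llf), n=len(data), k=len(beta),
                     converged=True, fitted=expit(X @ beta),
                     notes=["sigma fixed at 0 (plain GLM)"])


def predict_conditional(fit: FitResult, data: pd.DataFrame) -> np.ndarray:
    """Conditional (u = 0, average group) predicted probabilities/means."""
    X, _ = _design(data, fit.spec.fixed)
    eta = X @ fit.coefficients["estimate"].to_numpy()
    return expit(eta) if fit.spec.family == "binomial" else eta


def _wald_se(negll: Callable, params: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Standard errors from a central-difference Hessian of the negative log-lik."""
    k = len(params)
    H = np.zeros((k, k))
    f0 = negll(params)
    steps = h * np.maximum(1.0, np.abs(params))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            if i == j:
                H[i, i] = (negll(params + ei) - 2 * f0 + negll(params - ei)) / steps[i] ** 2
            else:
                fpp = negll(params + ei + ej); fpm = negll(params + ei - ej)
                fmp = negll(params - ei + ej); fmm = negll(params - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(k, np.nan)
    return se


# ---------------------------------------------------------------------------
# Gaussian LMM (statsmodels MixedLM behind the module surface)


def fit_lmm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Gaussian LMM with one random intercept (REML or ML).

    When response and/or concentration predictors are log2-scaled, a slope b
    on a log2 predictor is a per-doubling effect: each doubling of the
    predictor multiplies the response by 2**b (i.e. a 100*(2**b - 1) percent
    change).
    """
    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires a gaussian response")
    y = np.asarray(data[spec.response], dtype=float)
    if spec.log2_response:
        if np.any(y <= 0):
            raise ValueError("log2 response requires positive values")
        y = np.log2(y)
    X, names = _design(data, spec.fixed)
    reml = spec.estimation.upper() == "REML"
    notes: list[str] = []

    if spec.group is None:
        raise ValueError("fit_lmm requires one random-intercept grouping column")
    import statsmodels.api as sm
    groups = data[spec.group].to_numpy()
    # scale non-intercept columns to unit sd for conditioning; undo afterwards
    scale = np.ones(X.shape[1])
    for j in range(1, X.shape[1]):
        sd = X[:, j].std()
        if sd > 0:
            scale[j] = sd
    Xs = X / scale
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = sm.MixedLM(y, Xs, groups=groups)
        try:
            res = mod.fit(reml=reml, method="lbfgs")
            if not res.converged:
                raise RuntimeError("lbfgs did not converge")
        except Exception:
            res = mod.fit(reml=reml, method="powell")
    re_var = float(np.asarray(res.cov_re).ravel()[0])
    resid_var = float(res.scale)
    if re_var < 1e-8 * max(resid_var, 1.0):
        notes.append("singular fit: random-intercept variance ~ 0")
    params = np.asarray(res.fe_params) / scale
    se = np.asarray(res.bse_fe) / scale
    zval = params / se
    pvals = 2 * stats.norm.sf(np.abs(zval))
    coefs = pd.DataFrame({
        "term": names, "estimate": params, "se": se,
        "ci_low": params - 1.96 * se, "ci_high": params + 1.96 * se, "p": pvals,
    })
    k = len(params) + 2  # + random-intercept var + residual var
    return FitResult(spec=spec, coefficients=coefs, re_var=re_var,
                     resid_var=resid_var, loglik=float(res.llf), n=len(data), k=k,
                     converged=bool(res.converged), fitted=np.asarray(X @ params),
                     notes=notes)


# ---------------------------------------------------------------------------
# model selection and classical tests


def aicc_compare(fits: dict[str, FitResult], equivalence: float = 2.0) -> pd.DataFrame:
    """Rank models by AICc; models within ``equivalence`` of the best are
    flagged as providing essentially equivalent fits."""
    rows = []
    ns = {f.n for f in fits.values()}
    if len(ns) > 1:
        raise ValueError("AICc comparison requires identical response rows")
    if any(f.spec.estimation.upper() == "REML" for f in fits.values()):
        fixed = {tuple(f.spec.fixed) for f in fits.values()}
        if len(fixed) > 1:
            raise ValueError("cannot compare REML fits with different fixed effects; refit with ML")
    for name, f in fits.items():
        rows.append({"model": name, "aicc": f.aicc, "loglik": f.loglik, "k": f.k})
    tab = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    tab["equivalent"] = tab["delta_aicc"] < equivalence
    return tab


def anova_tukey(values: np.ndarray, groups: np.ndarray
                ) -> tuple[float, tuple[int, int], float, pd.DataFrame]:
    """One-way ANOVA F with Tukey HSD pairwise comparisons.

    Returns (F, (df_between, df_within), p, pairwise table).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    samples = [values[groups == g] for g in labels]
    if len(samples) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs >= 2 observations")
    N, g = len(values), len(labels)
    df = (g - 1, N - g)
    if np.allclose(values, values[0]):
        pair = pd.DataFrame(columns=["group_a", "group_b", "diff", "p_adj"])
        return 0.0, df, 1.0, pair
    F, p = stats.f_oneway(*samples)
    res = stats.tukey_hsd(*samples)
    rows = []
    for i in range(g):
        for j in range(i + 1, g):
            rows.append({"group_a": labels[i], "group_b": labels[j],
                         "diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                         "p_adj": float(res.pvalue[i, j])})
    return float(F), df, float(p), pd.DataFrame(rows)


def kruskal_wallis(values: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H (tie-corrected) with chi-square p-value."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    samples = [values[groups == gl] for gl in labels]
    if np.allclose(values, values[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), float(p)


def bca_bootstrap_ci(values: np.ndarray, statistic: Callable = np.mean,
                     B: int = 9999, seed: int = 0, level: float = 0.95
                     ) -> tuple[float, float, float]:
    """Bias-corrected and accelerated bootstrap CI (deterministic under seed)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need n >= 3")
    if B < 1000:
        raise ValueError("need B >= 1000 resamples")
    est = float(statistic(values))
    if np.allclose(values, values[0]):
        return est, est, est
    rng = np.random.default_rng(seed)
    res = stats.bootstrap((values,), statistic, n_resamples=B, method="BCa",
                          confidence_level=level, vectorized=False, rng=rng)
    return est, float(res.confidence_interval.low), float(res.confidence_interval.high)


def holm_bonferroni(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, in the original order."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    from statsmodels.stats.multitest import multipletests
    return multipletests(p, method="holm")[1]


# ---------------------------------------------------------------------------
# endpoint helpers


def hepatosomatic_index(wet_mass_g, liver_mass_g) -> np.ndarray:
    """HSI = 100 * liver mass / body mass (standard convention)."""
    return 100.0 * np.asarray(liver_mass_g, float) / np.asarray(wet_mass_g, float)


def development_rate(final_stage, days_elapsed, initial_stage: float = 25.0) -> np.ndarray:
    """Gosner stages incremented per day since release (default release stage 25)."""
    return (np.asarray(final_stage, float) - initial_stage) / np.asarray(days_elapsed, float)


def fit_sex_ratio_glmm(tadpoles: pd.DataFrame, conc: pd.Series,
                       gosner_min: int = 36, seed: int = 0) -> FitResult:
    """Sex-ratio (female vs. not) model restricted to Gosner stages >= 36.

    Morphological sex is unreliable earlier in development, so earlier stages
    are excluded.  A tank random intercept is attempted first; if that fit is
    singular or fails to converge the model falls back to a plain binomial GLM
    (mirroring the common failure of tank-level variance estimation when
    between-tank variation is negligible).
    """
    df = tadpoles[(tadpoles["gosner_stage"] >= gosner_min) & tadpoles["survived"]].copy()
    if df.empty:
        raise ValueError("no tadpoles at or above the Gosner threshold")
    df["female"] = (df["sex"] == "F").astype(int)
    df["conc"] = df["tank_id"].map(conc).astype(float)
    spec = ModelSpec(response=("female", 1), family="binomial",
                     fixed=(("conc", "log2_plus1"), ("gosner_stage", "identity")),
                     group="tank_id")
    fit = fit_binomial_glmm(spec, df, seed=seed)
    if not fit.converged or any("singular" in n for n in fit.notes):
        import statsmodels.api as sm
        X, names = _design(df, spec.fixed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(df["female"].to_numpy(), X, family=sm.families.Binomial()).fit()
        params, se = np.asarray(res.params), np.asarray(res.bse)
        coefs = pd.DataFrame({
            "term": names, "estimate": params, "se": se,
            "ci_low": params - 1.96 * se, "ci_high": params + 1.96 * se,
            "p": 2 * stats.norm.sf(np.abs(params / se)),
        })
        fit = FitResult(spec=spec, coefficients=coefs, re_var=0.0, resid_var=None,
                        loglik=float(res.llf), n=len(df), k=len(params),
                        converged=True, fitted=np.asarray(res.fittedvalues),
                        notes=["tank random effect removed (GLM fallback)"])
    if df["female"].nunique() == 1:
        fit.notes.append("separation: all one sex")
        warnings.warn("sex-ratio data are all one sex", stacklevel=2)
    return fit
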