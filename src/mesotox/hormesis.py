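"""Bayesian hormetic concentration-response model for caged-amphipod survival.

Survival counts are binomial with a quadratic polynomial on the logit scale in
transformed dose x = log2(c + 1), plus a normal random intercept per tank to
absorb extra-binomial variation:

    n_alive ~ Binomial(n_atrisk, p),
    logit(p) = beta0[week] + beta1 * x + beta2 * x^2 + u_tank,
    u_tank ~ Normal(0, sigma_tank^2).

The quadratic-logit family captures hormesis (survival rising at low doses,
falling at high doses, when beta1 > 0 and beta2 < 0) while keeping every
toxicity metric of interest available in closed form from the quadratic
equation: LCx on the descending limb, the peak (vertex) concentration, and the
limiting concentration of stimulation where survival returns to the control
level.

Sampling strategy: the tank effects are integrated out by Gauss-Hermite
quadrature, and the low-dimensional marginal posterior over
(beta, sigma_tank) is sampled with an affine-invariant ensemble sampler run
as several independent ensembles ("chains") for split-R-hat diagnostics.
Tank effects are then reconstructed per posterior draw by exact inverse-CDF
sampling of their one-dimensional conditionals, which restores the full joint
posterior and per-observation log-likelihoods.  Weakly-informative priors:
Normal(0, 2.5) on each beta, half-Normal(0, 1) on sigma_tank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln, log_expit, logit, logsumexp

__all__ = [
    "SurvivalObservation",
    "HormesisModelSpec",
    "HormesisPosterior",
    "DerivedMetricSummary",
    "LooComparison",
    "ConvergenceError",
    "transform_concentration",
    "fit_hormetic_model",
    "control_survival",
    "lethal_concentration",
    "stimulation_limit",
    "peak_concentration",
    "exact_loo_compare",
    "hdi",
    "observations_from_table",
]

_GH_NODES = 21


class ConvergenceError(RuntimeError):
    """MCMC diagnostics failed the convergence gate."""


@dataclass(frozen=True)
class SurvivalObservation:
    """One cage x week binomial record."""
    tank_id: str
    conc: float        # µg/L diquat
    week: int          # exposure duration, weeks
    n_alive: int
    n_atrisk: int

    def __post_init__(self):
        if not (0 <= self.n_alive <= self.n_atrisk):
            raise ValueError(f"{self.tank_id}: need 0 <= n_alive <= n_atrisk")
        if self.conc < 0:
            raise ValueError("conc must be >= 0")


@dataclass(frozen=True)
class HormesisModelSpec:
    """Model variant and sampler settings.

    form: "null" (intercept only), "linear", or "quadratic".
    week_structure: "separate_fits" fits one week of data at a time;
        "shared_slopes_week_intercepts" fits all weeks jointly with a
        week-specific intercept and shared dose slopes.
    """
    form: str = "quadratic"
    week_structure: str = "separate_fits"
    prior_beta_scale: float = 2.5
    prior_sigma_scale: float = 1.0
    chains: int = 4
    warmup: int = 600
    draws: int = 1000
    thin: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.form not in ("null", "linear", "quadratic"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.week_structure not in ("separate_fits", "shared_slopes_week_intercepts"):
            raise ValueError(f"unknown week_structure {self.week_structure!r}")
        if self.chains < 2:
            raise ValueError("need chains >= 2 for split-R-hat")


@dataclass
class HormesisPosterior:
    """Posterior draws, diagnostics and pointwise log-likelihood."""
    spec: HormesisModelSpec
    weeks: list[int]                 # week labels for beta0 columns
    beta0: np.ndarray                # (ndraw, n_weeks)
    beta1: np.ndarray | None         # (ndraw,) or None for null form
    beta2: np.ndarray | None
    sigma_tank: np.ndarray           # (ndraw,)
    u_tank: np.ndarray               # (ndraw, n_tanks)
    tank_ids: list[str]
    obs: list[SurvivalObservation]
    log_lik: np.ndarray              # (ndraw, n_obs) conditional on u
    rhat: dict[str, float]
    ess: dict[str, float]
    separation_warning: bool = False

    @property
    def ndraw(self) -> int:
        return self.beta0.shape[0]

    def beta0_for_week(self, week: int) -> np.ndarray:
        return self.beta0[:, self.weeks.index(week)]

    def b1(self) -> np.ndarray:
        return self.beta1 if self.beta1 is not None else np.zeros(self.ndraw)

    def b2(self) -> np.ndarray:
        return self.beta2 if self.beta2 is not None else np.zeros(self.ndraw)


@dataclass
class DerivedMetricSummary:
    metric: str
    week: int | None
    median: float
    hdi_low: float
    hdi_high: float
    fraction_defined: float
    unit: str = "ug/L"

    def as_dict(self) -> dict:
        return {
            "metric": self.metric, "week": self.week, "median": self.median,
            "hdi_low": self.hdi_low, "hdi_high": self.hdi_high,
            "fraction_defined": self.fraction_defined, "unit": self.unit,
        }


@dataclass
class LooComparison:
    elpd: dict[str, float]
    pointwise: dict[str, np.ndarray]
    ranking: list[str]

    def diff_table(self) -> pd.DataFrame:
        """Pairwise elpd differences (row minus column) with standard errors."""
        names = self.ranking
        rows = []
        for a in names:
            for b in names:
                d = self.pointwise[a] - self.pointwise[b]
                rows.append({
                    "model_a": a, "model_b": b,
                    "elpd_diff": float(d.sum()),
                    "se_diff": float(np.sqrt(len(d) * d.var(ddof=1))) if len(d) > 1 and a != b else 0.0,
                })
        return pd.DataFrame(rows)


def transform_concentration(c) -> np.ndarray | float:
    """x = log2(c + 1); the control (c = 0) maps to the model intercept."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    out = np.log2(c + 1.0)
    return float(out) if out.ndim == 0 else out


def inverse_transform(x) -> np.ndarray | float:
    """c = 2**x - 1, inverse of :func:`transform_concentration`."""
    x = np.asarray(x, dtype=float)
    out = np.exp2(x) - 1.0
    return float(out) if out.ndim == 0 else out


def observations_from_table(amphipods: pd.DataFrame, conc: pd.Series,
                            week: int | None = None) -> list[SurvivalObservation]:
    """Build observations from the amphipods table and per-tank concentrations."""
    df = amphipods if week is None else amphipods[amphipods["week"] == week]
    return [
        SurvivalObservation(tank_id=str(r.tank_id), conc=float(conc[r.tank_id]),
                            week=int(r.week), n_alive=int(r.n_alive),
                            n_atrisk=int(r.n_atrisk))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# likelihood machinery


class _ModelData:
    """Pre-indexed observation arrays for vectorized likelihood evaluation."""

    def __init__(self, obs: Sequence[SurvivalObservation], form: str, week_structure: str):
        if not obs:
            raise ValueError("no observations")
        obs = sorted(obs, key=lambda o: (o.tank_id, o.week))
        self.obs = list(obs)
        self.weeks = sorted({o.week for o in obs})
        if week_structure == "separate_fits" and len(self.weeks) > 1:
            raise ValueError(
                "week_structure='separate_fits' requires observations from a single "
                "week; filter first or use 'shared_slopes_week_intercepts'")
        self.tank_ids = sorted({o.tank_id for o in obs})
        self.tank_idx = np.array([self.tank_ids.index(o.tank_id) for o in obs])
        self.week_idx = np.array([self.weeks.index(o.week) for o in obs])
        self.y = np.array([o.n_alive for o in obs], dtype=float)
        self.n = np.array([o.n_atrisk for o in obs], dtype=float)
        if np.any(self.n <= 0):
            raise ValueError("n_atrisk must be positive")
        self.x = transform_concentration(np.array([o.conc for o in obs]))
        ncoef = {"null": 0, "linear": 1, "quadratic": 2}[form]
        if ncoef >= 1 and len(np.unique(self.x)) < 2:
            raise ValueError("linear form needs >= 2 distinct concentrations")
        if ncoef == 2 and len(np.unique(self.x)) < 3:
            raise ValueError("quadratic form needs >= 3 distinct concentrations")
        self.form = form
        self.ncoef = ncoef
        self.ndim = len(self.weeks) + ncoef + 1  # beta0 per week, slopes, sigma
        self.binom_const = (gammaln(self.n + 1) - gammaln(self.y + 1)
                            - gammaln(self.n - self.y + 1))
        # tank segment boundaries (obs sorted by tank)
        self.tank_starts = np.searchsorted(self.tank_idx, np.arange(len(self.tank_ids)))
        # probabilists' Gauss-Hermite rule: sum_k w_k f(t_k) ~ integral f(u) e^{-u^2/2} du,
        # so w_k / sqrt(2 pi) are the weights of the N(0,1) mixing density
        t, w = np.polynomial.hermite_e.hermegauss(_GH_NODES)
        self.gh_t = t
        self.gh_logw = np.log(w) - 0.5 * np.log(2.0 * np.pi)

    def split_params(self, theta: np.ndarray):
        """theta (..., ndim) -> (beta0 (...,W), beta1, beta2, sigma)."""
        W = len(self.weeks)
        beta0 = theta[..., :W]
        k = W
        beta1 = theta[..., k] if self.ncoef >= 1 else None
        beta2 = theta[..., k + 1] if self.ncoef >= 2 else None
        sigma = theta[..., -1]
        return beta0, beta1, beta2, sigma

    def eta(self, theta: np.ndarray) -> np.ndarray:
        """Fixed-effect linear predictor per observation, shape (..., n_obs)."""
        beta0, beta1, beta2, _ = self.split_params(theta)
        eta = np.take(beta0, self.week_idx, axis=-1)
        if beta1 is not None:
            eta = eta + beta1[..., None] * self.x
        if beta2 is not None:
            eta = eta + beta2[..., None] * self.x ** 2
        return eta

    def pointwise_loglik(self, eta_u: np.ndarray) -> np.ndarray:
        """Binomial log-pmf at logit eta_u (broadcast over leading dims)."""
        log_p = log_expit(eta_u)
        log_q = log_p - eta_u  # log(1 - p) = log_expit(-z) = log_expit(z) - z
        return self.binom_const + self.y * log_p + (self.n - self.y) * log_q

    def tank_sums(self, ll: np.ndarray) -> np.ndarray:
        """Sum pointwise log-lik within tanks along the last axis."""
        return np.add.reduceat(ll, self.tank_starts, axis=-1)

    def marginal_loglik(self, theta: np.ndarray) -> np.ndarray:
        """Tank-effect-marginalized log-likelihood, theta (..., ndim)."""
        _, _, _, sigma = self.split_params(theta)
        eta = self.eta(theta)                                   # (..., N)
        u = sigma[..., None] * self.gh_t                        # (..., Q)
        z = eta[..., None, :] + u[..., :, None]                 # (..., Q, N)
        ll = self.pointwise_loglik(z)                           # (..., Q, N)
        per_tank = self.tank_sums(ll)                           # (..., Q, T)
        lw = self.gh_logw[..., :, None]
        return logsumexp(per_tank + lw, axis=-2).sum(axis=-1)   # (...,)

    def log_posterior(self, theta: np.ndarray, prior_beta_scale: float,
                      prior_sigma_scale: float) -> np.ndarray:
        theta = np.atleast_2d(theta)
        sigma = theta[..., -1]
        out = np.full(theta.shape[0], -np.inf)
        ok = sigma > 0
        if not ok.any():
            return out
        th = theta[ok]
        betas = th[..., :-1]
        lp = -0.5 * np.sum((betas / prior_beta_scale) ** 2, axis=-1)
        lp = lp - 0.5 * (th[..., -1] / prior_sigma_scale) ** 2  # half-normal
        out[ok] = lp + self.marginal_loglik(th)
        return out


def _run_ensembles(md: _ModelData, spec: HormesisModelSpec,
                   init: np.ndarray | None = None) -> np.ndarray:
    """Sample the marginal posterior; returns draws (chains, draws, ndim).

    ``init`` optionally provides candidate starting points (e.g. posterior
    draws from a closely related fit) to warm-start the walkers.
    """
    import emcee

    ndim = md.ndim
    nwalkers = max(2 * ndim + 2, 16)
    steps_keep = int(np.ceil(spec.draws / nwalkers)) * spec.thin
    chains = []
    for c in range(spec.chains):
        rng = np.random.RandomState((spec.seed + 104729 * (c + 1)) % (2 ** 31))
        p0 = np.empty((nwalkers, ndim))
        if init is not None and len(init) >= nwalkers:
            p0[:] = init[rng.choice(len(init), nwalkers, replace=False)]
            p0[:, :-1] += rng.normal(0.0, 0.01, size=(nwalkers, ndim - 1))
            p0[:, -1] = np.abs(p0[:, -1] + rng.normal(0.0, 0.01, nwalkers)) + 1e-3
        else:
            p0[:, :-1] = rng.normal(0.0, 1.0, size=(nwalkers, ndim - 1))
            p0[:, -1] = np.abs(rng.normal(0.4, 0.2, size=nwalkers)) + 0.01
        # differential-evolution moves handle the strong beta1/beta2 correlation
        moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
        sampler = emcee.EnsembleSampler(
            nwalkers, ndim,
            lambda th: md.log_posterior(th, spec.prior_beta_scale, spec.prior_sigma_scale),
            moves=moves, vectorize=True)
        sampler.random_state = np.random.RandomState(
            (spec.seed + 15485863 * (c + 1)) % (2 ** 31)).get_state()
        state = sampler.run_mcmc(p0, spec.warmup)
        sampler.reset()
        sampler.run_mcmc(state, steps_keep, thin_by=1)
        chain = sampler.get_chain(thin=spec.thin)        # (steps, walkers, ndim)
        flat = chain.reshape(-1, ndim)[-spec.draws:]
        chains.append(flat)
    return np.stack(chains)                               # (chains, draws, ndim)


def _diagnostics(draws: np.ndarray, names: list[str]) -> tuple[dict, dict]:
    import arviz as az
    data = {nm: draws[:, :, j] for j, nm in enumerate(names)}
    idata = az.convert_to_dataset(data)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    return ({nm: float(rhat[nm].values) for nm in names},
            {nm: float(ess[nm].values) for nm in names})


def _conditional_u_draws(md: _ModelData, theta_flat: np.ndarray,
                         seed: int, grid_size: int = 96) -> np.ndarray:
    """Exact inverse-CDF draws of each tank effect given (theta, data).

    The conditional of one tank's intercept is 1-D and log-concave, so a
    trapezoid CDF on a grid around the Laplace mode is effectively exact.
    """
    rng = np.random.default_rng(seed % (2 ** 31))
    ndraw = theta_flat.shape[0]
    T = len(md.tank_ids)
    _, _, _, sigma = md.split_params(theta_flat)
    eta = md.eta(theta_flat)                         # (D, N)
    u_out = np.empty((ndraw, T))
    chunk = 512
    for lo in range(0, ndraw, chunk):
        hi = min(lo + chunk, ndraw)
        et, sg = eta[lo:hi], sigma[lo:hi]
        D = hi - lo
        # Newton for conditional mode per (draw, tank)
        u = np.zeros((D, T))
        for _ in range(30):
            z = et + u[:, md.tank_idx]
            p = expit(z)
            grad_obs = md.y - md.n * p
            g = md.tank_sums(grad_obs) - u / sg[:, None] ** 2
            h = md.tank_sums(md.n * p * (1 - p)) + 1.0 / sg[:, None] ** 2
            step = g / h
            u += np.clip(step, -1.0, 1.0)
            if np.max(np.abs(step)) < 1e-10:
                break
        sd = 1.0 / np.sqrt(h)
        # grid of standardized offsets around the mode
        s = np.linspace(-7.0, 7.0, grid_size)
        ug = u[..., None] + sd[..., None] * s                      # (D, T, G)
        zg = et[:, md.tank_idx, None] + ug[:, md.tank_idx, :]      # (D, N, G)
        llg = md.pointwise_loglik(np.moveaxis(zg, -1, 1))          # (D, G, N)
        per_tank = md.tank_sums(llg)                               # (D, G, T)
        logpost = np.moveaxis(per_tank, 1, 2) - 0.5 * (ug / sg[:, None, None]) ** 2
        logpost -= logpost.max(axis=-1, keepdims=True)
        dens = np.exp(logpost)
        cdf = np.cumsum((dens[..., 1:] + dens[..., :-1]) * 0.5, axis=-1)
        cdf /= cdf[..., -1:]
        r = rng.random((D, T, 1))
        idx = (cdf < r).sum(axis=-1)
        # linear interpolation inside the chosen cell
        c_lo = np.where(idx > 0, np.take_along_axis(cdf, np.maximum(idx - 1, 0)[..., None], -1)[..., 0], 0.0)
        c_hi = np.take_along_axis(cdf, np.minimum(idx, grid_size - 2)[..., None], -1)[..., 0]
        frac = np.clip((r[..., 0] - c_lo) / np.maximum(c_hi - c_lo, 1e-300), 0.0, 1.0)
        g_lo = np.take_along_axis(ug, idx[..., None], -1)[..., 0]
        g_hi = np.take_along_axis(ug, np.minimum(idx + 1, grid_size - 1)[..., None], -1)[..., 0]
        u_out[lo:hi] = g_lo + frac * (g_hi - g_lo)
    return u_out


def fit_hormetic_model(obs: Sequence[SurvivalObservation], spec: HormesisModelSpec,
                       check_convergence: bool = True,
                       ess_floor: float = 100.0,
                       tank_effect_draws: bool = True,
                       diagnostics: bool = True) -> HormesisPosterior:
    """Fit the binomial quadratic-logit model with tank random intercepts.

    Raises :class:`ConvergenceError` when any split-R-hat >= 1.01 or any bulk
    ESS falls below ``ess_floor`` (override with ``check_convergence=False``).
    A separation warning is attached when the data are all-dead or all-alive
    at some concentration level (the fit still proceeds; priors regularize).
    ``tank_effect_draws=False`` / ``diagnostics=False`` skip the conditional
    tank-effect reconstruction and the R-hat/ESS computation, for bulk
    simulation studies where only the regression coefficients are needed.
    """
    md = _ModelData(obs, spec.form, spec.week_structure)
    names = [f"beta0_w{w}" for w in md.weeks]
    if md.ncoef >= 1:
        names.append("beta1")
    if md.ncoef >= 2:
        names.append("beta2")
    names.append("sigma_tank")

    draws = _run_ensembles(md, spec)
    if diagnostics or check_convergence:
        rhat, ess = _diagnostics(draws, names)
    else:
        rhat, ess = {}, {}
    if check_convergence:
        bad_rhat = {k: v for k, v in rhat.items() if not v < 1.01}
        bad_ess = {k: v for k, v in ess.items() if v < ess_floor}
        if bad_rhat or bad_ess:
            raise ConvergenceError(
                f"MCMC diagnostics failed: R-hat >= 1.01 for {bad_rhat or 'none'}; "
                f"ESS < {ess_floor} for {bad_ess or 'none'}")

    flat = draws.reshape(-1, md.ndim)
    beta0, beta1, beta2, sigma = md.split_params(flat)
    if tank_effect_draws:
        u = _conditional_u_draws(md, flat, seed=spec.seed + 7)
        eta = md.eta(flat) + u[:, md.tank_idx]
        log_lik = md.pointwise_loglik(eta)
    else:
        u = np.empty((flat.shape[0], 0))
        log_lik = np.empty((flat.shape[0], 0))

    sep = False
    grp = pd.DataFrame({"x": md.x, "y": md.y, "n": md.n}).groupby("x").sum()
    if ((grp["y"] == 0) | (grp["y"] == grp["n"])).any():
        sep = True
        warnings.warn("complete separation: some concentration level is all-dead "
                      "or all-alive; posterior is prior-regularized", stacklevel=2)

    return HormesisPosterior(
        spec=spec, weeks=md.weeks, beta0=beta0,
        beta1=beta1, beta2=beta2, sigma_tank=sigma, u_tank=u,
        tank_ids=md.tank_ids, obs=md.obs, log_lik=log_lik,
        rhat=rhat, ess=ess, separation_warning=sep)


# ---------------------------------------------------------------------------
# derived toxicity metrics (closed-form posterior quantities)


def hdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass * n)`` sorted draws.

    Ties in window width are broken by taking the leftmost window.
    """
    draws = np.asarray(draws, dtype=float)
    draws = draws[np.isfinite(draws)]
    if draws.size == 0:
        raise ValueError("hdi: empty input")
    if draws.size < 50:
        raise ValueError("hdi: need at least 50 draws")
    if not (0 < mass <= 1):
        raise ValueError("mass must be in (0, 1]")
    s = np.sort(draws)
    n = s.size
    m = int(np.ceil(mass * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1:] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns first (leftmost) minimum
    return float(s[i]), float(s[i + m - 1])


def _summarize(metric: str, week: int | None, values_c: np.ndarray,
               defined: np.ndarray, unit: str = "ug/L",
               mass: float = 0.95) -> DerivedMetricSummary:
    frac = float(defined.mean()) if defined.size else 0.0
    vals = values_c[defined]
    if vals.size < 50:
        return DerivedMetricSummary(metric, week, np.nan, np.nan, np.nan, frac, unit)
    lo, hi = hdi(vals, mass)
    if frac < 0.9:
        warnings.warn(f"{metric}: defined in only {frac:.1%} of draws", stacklevel=3)
    return DerivedMetricSummary(metric, week, float(np.median(vals)), lo, hi, frac, unit)


def control_survival(post: HormesisPosterior, week: int | None = None) -> DerivedMetricSummary:
    """Posterior control survival probability for an average tank (u = 0)."""
    week = week if week is not None else post.weeks[0]
    p0 = expit(post.beta0_for_week(week))
    return _summarize("control_survival", week, p0, np.ones(len(p0), bool), unit="probability")


def _lcx_x(beta0: np.ndarray, beta1: np.ndarray, beta2: np.ndarray,
           f: float, relative_to_control: bool = True) -> np.ndarray:
    """Transformed-dose solution of the LCx equation per draw (nan = undefined).

    Solves beta2 x^2 + beta1 x + (beta0 - target) = 0 where
    target = logit((1 - f) * p0) (relative to control survival) or
    logit(1 - f) (absolute), taking the root on the descending limb.
    """
    p0 = expit(beta0)
    target = logit((1.0 - f) * p0) if relative_to_control else np.full_like(beta0, logit(1.0 - f))
    a, b, c = beta2, beta1, beta0 - target
    x = np.full(beta0.shape, np.nan)

    lin = np.abs(a) < 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        x_lin = -c / b
    ok_lin = lin & (b < 0) & (x_lin >= 0)
    x[ok_lin] = x_lin[ok_lin]

    quad = ~lin
    with np.errstate(invalid="ignore"):
        disc = b ** 2 - 4 * a * c
    has = quad & (disc >= 0)
    sq = np.sqrt(np.where(has, disc, 0.0))
    # numerically stable pair of roots
    q = -0.5 * (b + np.sign(b + (b == 0)) * sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = q / a
        r2 = c / q
    best = np.full(beta0.shape, np.nan)
    with np.errstate(invalid="ignore"):
        for r in (r1, r2):
            slope = b + 2 * a * r
            cand = has & np.isfinite(r) & (r >= 0) & (slope < 0)
            best = np.where(cand & (np.isnan(best) | (r > best)), r, best)
    x[quad] = best[quad]
    return x


def lethal_concentration(post: HormesisPosterior, f: float, week: int | None = None,
                         relative_to_control: bool = True) -> DerivedMetricSummary:
    """LCx: concentration causing a fraction-f reduction in survival.

    By default the reduction is relative to the control survival probability
    (survival falls to (1 - f) * p0 on the descending limb of the curve);
    ``relative_to_control=False`` uses the absolute probability 1 - f.
    """
    if not (0 < f < 1):
        raise ValueError("f must be in (0, 1)")
    week = week if week is not None else post.weeks[0]
    x = _lcx_x(post.beta0_for_week(week), post.b1(), post.b2(), f, relative_to_control)
    defined = np.isfinite(x)
    c = inverse_transform(np.where(defined, x, 0.0))
    return _summarize(f"LC{round(100 * f)}", week, np.asarray(c), defined)


def stimulation_limit(post: HormesisPosterior, week: int | None = None) -> DerivedMetricSummary:
    """Concentration where survival returns to the control level.

    The nonzero root of beta1 x + beta2 x^2 = 0, i.e. x_lim = -beta1/beta2,
    defined for hormetic draws (beta1 > 0, beta2 < 0).
    """
    if post.spec.form != "quadratic":
        raise ValueError("stimulation_limit requires the quadratic form")
    week = week if week is not None else post.weeks[0]
    b1, b2 = post.b1(), post.b2()
    defined = (b1 > 0) & (b2 < 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = -b1 / b2
    c = inverse_transform(np.where(defined, x, 0.0))
    return _summarize("stimulation_limit", week, np.asarray(c), defined)


def peak_concentration(post: HormesisPosterior, week: int | None = None
                       ) -> tuple[DerivedMetricSummary, DerivedMetricSummary]:
    """Vertex of the hormetic curve: (peak concentration, peak survival)."""
    if post.spec.form != "quadratic":
        raise ValueError("peak_concentration requires the quadratic form")
    week = week if week is not None else post.weeks[0]
    b0 = post.beta0_for_week(week)
    b1, b2 = post.b1(), post.b2()
    defined = b2 < 0
    with np.errstate(divide="ignore", invalid="ignore"):
        xs = -b1 / (2.0 * b2)
    xs = np.where(defined, xs, 0.0)
    c = inverse_transform(xs)
    p = expit(b0 + b1 * xs + b2 * xs ** 2)
    return (_summarize("peak_conc", week, np.asarray(c), defined),
            _summarize("peak_survival", week, p, defined, unit="probability"))


def derived_metrics_table(post: HormesisPosterior, week: int | None = None) -> pd.DataFrame:
    """All derived toxicity metrics for one fitted week as a tidy table."""
    week = week if week is not None else post.weeks[0]
    rows = [control_survival(post, week).as_dict()]
    for f in (0.10, 0.25, 0.50):
        rows.append(lethal_concentration(post, f, week).as_dict())
    if post.spec.form == "quadratic":
        rows.append(stimulation_limit(post, week).as_dict())
        pc, ps = peak_concentration(post, week)
        rows.extend([pc.as_dict(), ps.as_dict()])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exact leave-one-out cross-validation


def _loo_lpd_one(md_full: _ModelData, i: int, spec: HormesisModelSpec,
                 rhat_gate: float = 1.05,
                 init: np.ndarray | None = None) -> float:
    """Refit without observation i; log predictive density of observation i."""
    obs = md_full.obs
    held = obs[i]
    rest = [o for j, o in enumerate(obs) if j != i]
    md = _ModelData(rest, spec.form, spec.week_structure)
    names = [str(j) for j in range(md.ndim)]
    draws = None
    # screening gate only (refits run at reduced settings, where the R-hat
    # estimate itself is noisy); retry with longer chains before giving up
    for attempt, thin_mult in enumerate((1, 2, 4)):
        sub_spec = replace(spec, seed=spec.seed + 1009 * (i + 1) + 31 * attempt,
                           thin=spec.thin * thin_mult)
        try:
            cand = _run_ensembles(md, sub_spec, init=init)
        except Exception as e:  # pragma: no cover
            raise ConvergenceError(f"refit without observation {i} failed: {e}") from e
        rhat, _ = _diagnostics(cand, names)
        if all(v < rhat_gate for v in rhat.values()):
            draws = cand
            break
    if draws is None:
        raise ConvergenceError(f"refit without observation {i} did not converge")
    flat = draws.reshape(-1, md.ndim)

    _, _, _, sigma = md.split_params(flat)
    eta_rest = md.eta(flat)                      # (D, N_rest)
    # fixed-effect predictor for the held-out cage
    th_b = flat[:, :-1]
    W = len(md.weeks)
    eta_i = th_b[:, md.weeks.index(held.week)]
    xh = transform_concentration(held.conc)
    if md.ncoef >= 1:
        eta_i = eta_i + th_b[:, W] * xh
    if md.ncoef >= 2:
        eta_i = eta_i + th_b[:, W + 1] * xh ** 2

    t, w = md.gh_t, md.gh_logw
    u = sigma[:, None] * t                       # (D, Q)
    # conditional weights of u given the held-out cage's tank-mates
    if held.tank_id in md.tank_ids:
        tix = md.tank_ids.index(held.tank_id)
        mask = md.tank_idx == tix
        z = eta_rest[:, None, mask] + u[:, :, None]
        log_p = log_expit(z)
        ll_rest = (md.binom_const[mask] + md.y[mask] * log_p
                   + (md.n[mask] - md.y[mask]) * (log_p - z))
        logw_cond = w + ll_rest.sum(axis=-1)     # (D, Q)
    else:
        logw_cond = np.broadcast_to(w, u.shape).copy()
    logw_cond = logw_cond - logsumexp(logw_cond, axis=-1, keepdims=True)

    z_i = eta_i[:, None] + u                     # (D, Q)
    lc = (gammaln(held.n_atrisk + 1) - gammaln(held.n_alive + 1)
          - gammaln(held.n_atrisk - held.n_alive + 1))
    log_p = log_expit(z_i)
    ll_i = lc + held.n_alive * log_p + (held.n_atrisk - held.n_alive) * (log_p - z_i)
    per_draw = logsumexp(logw_cond + ll_i, axis=-1)       # (D,)
    return float(logsumexp(per_draw) - np.log(per_draw.size))


def exact_loo_compare(obs: Sequence[SurvivalObservation],
                      specs: dict[str, HormesisModelSpec]) -> LooComparison:
    """Exact leave-one-out cross-validation over candidate model forms.

    For every spec and every observation, the model is refit on the data with
    that observation removed and scored by the log of its mean posterior
    predictive probability; elpd is the sum of these log pointwise predictive
    densities.  Standard errors of pairwise elpd differences come from the
    pointwise contributions.
    """
    pointwise: dict[str, np.ndarray] = {}
    for name, spec in specs.items():
        md = _ModelData(obs, spec.form, spec.week_structure)
        # full-data posterior warm-starts every leave-one-out refit
        full = _run_ensembles(md, spec).reshape(-1, md.ndim)
        lpd = np.array([_loo_lpd_one(md, i, spec, init=full)
                        for i in range(len(md.obs))])
        pointwise[name] = lpd
    elpd = {k: float(v.sum()) for k, v in pointwise.items()}
    ranking = sorted(elpd, key=elpd.get, reverse=True)
    return LooComparison(elpd=elpd, pointwise=pointwise, ranking=ranking)
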