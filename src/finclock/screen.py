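"""Per-site binomial GLMM screen for age-correlated methylation.

For each CpG site the odds of a read being methylated are modelled as

    Meth_f ~ Binomial(Total_f, p_f),   logit(p_f) = beta0 + beta1 * Age_f + u_f,
    u_f ~ Normal(0, sigma_fish^2),

one observation per fish. Because each fish contributes a single binomial
count per site, the fish random intercept is an observation-level
over-dispersion term and can be integrated out exactly to quadrature
precision: the marginal likelihood per fish is a 1-D Gaussian integral,
evaluated here with Gauss-Hermite quadrature. That leaves a three-parameter
posterior over (beta0, beta1, log sigma_fish).

Two engines share this marginal posterior:

- ``laplace`` (default): posterior mode plus a curvature-based normal
  approximation; fast enough to screen thousands of sites.
- ``mcmc`` (reference): 4 independent chains of univariate slice sampling,
  4000 iterations each with the first half discarded as warm-up;
  convergence requires effective sample size > 2000 and Gelman-Rubin
  R-hat < 1.01 for every parameter.

A site is significant when its 95% credible interval for beta1 excludes
zero (and, for the MCMC engine, the convergence gates pass). Priors are
weakly informative: Normal(0, 2.5) on the intercept after centring age,
Normal(0, 2.5 / sd(age)) on the slope, Exponential(1) on sigma_fish.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import log_expit

from ._utils import logger, rng_for
from .qc import IMPUTED, MISSING, OBSERVED, PercentMethylationMatrix

_GH_NODES, _GH_WEIGHTS = hermgauss(16)
_GH_LOGW = np.log(_GH_WEIGHTS / np.sqrt(np.pi))

try:  # compiled likelihood core; the numpy path below is the reference
    from numba import njit as _njit

    @_njit(nogil=True, fastmath=True)
    def _marg_loglik_core(b0, b1, sigma, m, n, age_c, nodes, logw):
        total = 0.0
        s2 = 1.4142135623730951 * sigma
        k_nodes = nodes.shape[0]
        vals = np.empty(k_nodes)
        for f in range(m.shape[0]):
            eta = b0 + b1 * age_c[f]
            mx = -1e300
            for k in range(k_nodes):
                th = eta + s2 * nodes[k]
                if th >= 0.0:
                    lse = -np.log1p(np.exp(-th))
                    lsm = -th + lse
                else:
                    lsm = -np.log1p(np.exp(th))
                    lse = th + lsm
                v = m[f] * lse + (n[f] - m[f]) * lsm + logw[k]
                vals[k] = v
                if v > mx:
                    mx = v
            acc = 0.0
            for k in range(k_nodes):
                acc += np.exp(vals[k] - mx)
            total += mx + np.log(acc)
        return total

    @_njit(nogil=True)
    def _logpost_core(b0, b1, t, m, n, age_c, nodes, logw, slope_prior_sd):
        sigma = np.exp(t)
        lp = _marg_loglik_core(b0, b1, sigma, m, n, age_c, nodes, logw)
        lp += -0.5 * (b0 / 2.5) ** 2
        lp += -0.5 * (b1 / slope_prior_sd) ** 2
        lp += -sigma + t
        return lp

    @_njit(nogil=True)
    def _slice_chain_core(seed, x0, widths, n_iter, warmup,
                          m, n, age_c, nodes, logw, slope_prior_sd):
        np.random.seed(seed)
        x = x0.copy()
        draws = np.empty((n_iter - warmup, 3))
        lp_cur = _logpost_core(x[0], x[1], x[2], m, n, age_c, nodes, logw,
                               slope_prior_sd)
        for it in range(n_iter):
            for i in range(3):
                log_y = lp_cur + np.log(np.random.random())
                w = widths[i]
                xi0 = x[i]
                lo = xi0 - w * np.random.random()
                hi = lo + w
                for _ in range(20):
                    x[i] = lo
                    if _logpost_core(x[0], x[1], x[2], m, n, age_c, nodes, logw,
                                     slope_prior_sd) <= log_y:
                        break
                    lo -= w
                for _ in range(20):
                    x[i] = hi
                    if _logpost_core(x[0], x[1], x[2], m, n, age_c, nodes, logw,
                                     slope_prior_sd) <= log_y:
                        break
                    hi += w
                accepted = False
                for _ in range(100):
                    x[i] = lo + (hi - lo) * np.random.random()
                    lp_try = _logpost_core(x[0], x[1], x[2], m, n, age_c, nodes,
                                           logw, slope_prior_sd)
                    if lp_try > log_y:
                        accepted = True
                        lp_cur = lp_try
                        break
                    if x[i] < xi0:
                        lo = x[i]
                    else:
                        hi = x[i]
                if not accepted:
                    x[i] = xi0
            if it >= warmup:
                draws[it - warmup] = x
        return draws

    _HAVE_COMPILED = True
except ImportError:  # pragma: no cover - numba is optional
    _HAVE_COMPILED = False


@dataclass
class ParamSummary:
    mean: float
    low: float
    high: float


@dataclass
class SiteAgeModel:
    """Posterior summaries and diagnostics for one site's age model."""

    site_id: str
    beta0: ParamSummary
    beta1: ParamSummary
    sigma_fish: ParamSummary
    engine: str
    n_eff: dict[str, float] | None = None
    rhat: dict[str, float] | None = None
    converged: bool = True
    significant: bool = False
    n_fish: int = 0
    message: str = ""


class _MarginalPosterior:
    """Negative log posterior of (beta0, beta1, log sigma) with ages centred."""

    def __init__(self, meth: np.ndarray, total: np.ndarray, ages: np.ndarray):
        obs = total > 0
        self.m = meth[obs].astype(float)
        self.n = total[obs].astype(float)
        self.age_mean = float(ages[obs].mean())
        self.age_c = ages[obs] - self.age_mean
        sd = float(self.age_c.std())
        self.slope_prior_sd = 2.5 / sd if sd > 0 else 2.5
        self.n_fish = int(obs.sum())

    def _marginal_loglik(self, b0: float, b1: float, sigma: float) -> float:
        if _HAVE_COMPILED:
            return float(
                _marg_loglik_core(b0, b1, sigma, self.m, self.n, self.age_c,
                                  _GH_NODES, _GH_LOGW)
            )
        eta = b0 + b1 * self.age_c
        theta = eta[:, None] + np.sqrt(2.0) * sigma * _GH_NODES[None, :]
        ll = (
            self.m[:, None] * log_expit(theta)
            + (self.n - self.m)[:, None] * log_expit(-theta)
            + _GH_LOGW[None, :]
        )
        # log-sum-exp over quadrature nodes, per fish
        mx = ll.max(axis=1)
        marg = mx + np.log(np.exp(ll - mx[:, None]).sum(axis=1))
        return float(marg.sum())

    def logpost(self, params: np.ndarray) -> float:
        b0, b1, t = params
        sigma = np.exp(t)
        lp = self._marginal_loglik(float(b0), float(b1), float(sigma))
        lp += -0.5 * (b0 / 2.5) ** 2
        lp += -0.5 * (b1 / self.slope_prior_sd) ** 2
        lp += -sigma + t  # Exponential(1) prior on sigma, log-scale Jacobian
        return float(lp)

    def neg_logpost(self, params: np.ndarray) -> float:
        return -self.logpost(params)

    def start(self) -> np.ndarray:
        p = np.clip(self.m / self.n, 1e-3, 1 - 1e-3)
        z = np.log(p / (1 - p))
        b1 = 0.0
        var = self.age_c @ self.age_c
        if var > 0:
            b1 = float(self.age_c @ (z - z.mean()) / var)
        return np.array([float(z.mean()), b1, np.log(0.3)])


def _hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = np.empty((k, k))
    steps = step * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            h[i, j] = h[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * steps[i] * steps[j])
    return h


def _laplace_fit(post: _MarginalPosterior) -> tuple[np.ndarray, np.ndarray, bool]:
    """Return (mode, covariance, ok)."""
    res = optimize.minimize(post.neg_logpost, post.start(), method="Nelder-Mead",
                            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    res = optimize.minimize(post.neg_logpost, res.x, method="BFGS",
                            options={"gtol": 1e-6, "maxiter": 500})
    mode = res.x
    hess = _hessian(post.neg_logpost, mode)
    try:
        cov = np.linalg.inv(hess)
        ok = bool(np.all(np.linalg.eigvalsh(hess) > 0))
    except np.linalg.LinAlgError:
        cov = np.full((3, 3), np.nan)
        ok = False
    return mode, cov, ok


def _slice_sample_coord(logp, x: np.ndarray, i: int, w: float, rng) -> None:
    """One stepping-out slice-sampling update of coordinate i, in place."""
    lp0 = logp(x)
    log_y = lp0 + np.log(rng.random())
    x0 = x[i]
    lo = x0 - w * rng.random()
    hi = lo + w
    for _ in range(20):  # stepping out
        x[i] = lo
        if logp(x) <= log_y:
            break
        lo -= w
    for _ in range(20):
        x[i] = hi
        if logp(x) <= log_y:
            break
        hi += w
    for _ in range(100):  # shrinkage
        x[i] = lo + (hi - lo) * rng.random()
        if logp(x) > log_y:
            return
        if x[i] < x0:
            lo = x[i]
        else:
            hi = x[i]
    x[i] = x0  # pathological slice; keep current value


def _mcmc_fit(
    post: _MarginalPosterior,
    mode: np.ndarray,
    cov: np.ndarray,
    seed: int,
    n_chains: int = 4,
    n_iter: int = 4000,
):
    """Slice-sampling chains on the marginal posterior; returns draws (c, d, 3)."""
    import arviz as az

    rng = np.random.default_rng(seed)
    se = np.sqrt(np.abs(np.diag(cov)))
    se[~np.isfinite(se) | (se == 0)] = 0.5
    widths = 2.5 * se
    warmup = n_iter // 2
    draws = np.empty((n_chains, n_iter - warmup, 3))
    for c in range(n_chains):
        x = mode + rng.normal(0, 1, 3) * se
        if _HAVE_COMPILED:
            chain_seed = int(rng.integers(2**31 - 1))
            draws[c] = _slice_chain_core(
                chain_seed, x, widths, n_iter, warmup,
                post.m, post.n, post.age_c, _GH_NODES, _GH_LOGW,
                post.slope_prior_sd,
            )
            continue
        for it in range(n_iter):
            for i in range(3):
                _slice_sample_coord(post.logpost, x, i, widths[i], rng)
            if it >= warmup:
                draws[c, it - warmup] = x
    names = ["beta0", "beta1", "log_sigma"]
    n_eff = {nm: float(az.ess(np.ascontiguousarray(draws[:, :, i]))) for i, nm in enumerate(names)}
    rhat = {nm: float(az.rhat(np.ascontiguousarray(draws[:, :, i]))) for i, nm in enumerate(names)}
    return draws, n_eff, rhat


def _summary_from_draws(x: np.ndarray) -> ParamSummary:
    return ParamSummary(float(x.mean()), float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))


def fit_site_age_model(
    meth,
    total,
    ages,
    engine: str = "laplace",
    site_id: str = "site",
    seed: int | None = None,
    mcmc_chains: int = 4,
    mcmc_iterations: int = 4000,
) -> SiteAgeModel:
    """Fit the binomial random-intercept age model at one site.

    Missing cells (total == 0) are dropped. Complete separation (every
    observed methylation fraction is 0 or 1) yields a model flagged
    non-converged rather than an exception.
    """
    meth = np.asarray(meth)
    total = np.asarray(total)
    ages = np.asarray(ages, dtype=float)
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    obs = total > 0
    if obs.sum() < 2:
        raise ValueError(f"site {site_id}: fewer than 2 fish with reads")
    if engine not in ("laplace", "mcmc"):
        raise ValueError(f"unknown engine {engine!r}")

    post = _MarginalPosterior(meth, total, ages)
    frac = post.m / post.n
    separated = bool(np.all((frac == 0.0) | (frac == 1.0)))

    mode, cov, ok = _laplace_fit(post)
    b0_c, b1, t = mode

    def back_b0(b0_centered: float, slope: float) -> float:
        return b0_centered - slope * post.age_mean

    if engine == "laplace":
        se = np.sqrt(np.abs(np.diag(cov)))
        z = 1.959963984540054
        beta1 = ParamSummary(b1, b1 - z * se[1], b1 + z * se[1])
        beta0 = ParamSummary(back_b0(b0_c, b1), back_b0(b0_c - z * se[0], b1),
                             back_b0(b0_c + z * se[0], b1))
        sigma = ParamSummary(float(np.exp(t)), float(np.exp(t - z * se[2])),
                             float(np.exp(t + z * se[2])))
        converged = ok and not separated
        significant = converged and (beta1.low > 0 or beta1.high < 0)
        return SiteAgeModel(
            site_id=site_id, beta0=beta0, beta1=beta1, sigma_fish=sigma,
            engine="laplace", converged=converged, significant=significant,
            n_fish=post.n_fish,
            message="complete separation" if separated else "",
        )

    if seed is None:
        seed = 0
    draws, n_eff, rhat = _mcmc_fit(post, mode, cov, seed, mcmc_chains, mcmc_iterations)
    b0_draws = draws[:, :, 0].ravel() - draws[:, :, 1].ravel() * post.age_mean
    b1_draws = draws[:, :, 1].ravel()
    sig_draws = np.exp(draws[:, :, 2].ravel())
    beta1 = _summary_from_draws(b1_draws)
    converged = (
        all(v > 2000 for v in n_eff.values())
        and all(v < 1.01 for v in rhat.values())
        and not separated
    )
    significant = converged and (beta1.low > 0 or beta1.high < 0)
    return SiteAgeModel(
        site_id=site_id,
        beta0=_summary_from_draws(b0_draws),
        beta1=beta1,
        sigma_fish=_summary_from_draws(sig_draws),
        engine="mcmc",
        n_eff=n_eff,
        rhat=rhat,
        converged=converged,
        significant=significant,
        n_fish=post.n_fish,
        message="complete separation" if separated else "",
    )


def fit_age_screen(
    matrix,
    ages,
    engine: str = "laplace",
    seed: int = 0,
    progress: bool = False,
) -> list[SiteAgeModel]:
    """Fit the age model at every site of a MethylationCountMatrix.

    Sites are independent; each draws its own seed from (seed, site_id), so
    results do not depend on site order or execution order.
    """
    ages = np.asarray(ages, dtype=float)
    models = []
    site_ids = matrix.site_ids
    for j, site_id in enumerate(site_ids):
        models.append(
            fit_site_age_model(
                matrix.meth[:, j], matrix.total[:, j], ages,
                engine=engine, site_id=site_id,
                seed=rng_for(seed, site_id).integers(2**31 - 1) if engine == "mcmc" else None,
            )
        )
        if progress and (j + 1) % 200 == 0:
            logger.info("age screen: %d/%d sites fitted", j + 1, len(site_ids))
    return models


def select_age_sites(models: list[SiteAgeModel], require_convergence: bool = True) -> list[str]:
    """Site ids whose beta1 credible interval excludes zero (converged fits)."""
    out = []
    for m in models:
        if require_convergence and not m.converged:
            continue
        if m.beta1.low > 0 or m.beta1.high < 0:
            out.append(m.site_id)
    return out


def screen_results_frame(models: list[SiteAgeModel]) -> pd.DataFrame:
    """Tabular screen output (one row per site)."""
    return pd.DataFrame(
        {
            "site_id": [m.site_id for m in models],
            "beta1_mean": [m.beta1.mean for m in models],
            "beta1_low": [m.beta1.low for m in models],
            "beta1_high": [m.beta1.high for m in models],
            "sigma_fish": [m.sigma_fish.mean for m in models],
            "n_eff_min": [min(m.n_eff.values()) if m.n_eff else np.nan for m in models],
            "rhat_max": [max(m.rhat.values()) if m.rhat else np.nan for m in models],
            "converged": [m.converged for m in models],
            "significant": [m.significant for m in models],
        }
    )


def mask_overdispersed_cells(
    pmatrix: PercentMethylationMatrix,
    selected_sites: list[str],
    max_width: float = 0.85,
) -> PercentMethylationMatrix:
    """Set cells with CI width > ``max_width`` to missing at the given sites."""
    out = pmatrix.copy()
    col = {s: j for j, s in enumerate(out.site_ids)}
    idx = [col[s] for s in selected_sites if s in col]
    width = out.ci_width()[:, idx]
    wide = np.zeros(out.p.shape, dtype=bool)
    wide[:, idx] = np.nan_to_num(width, nan=0.0) > max_width
    out.p[wide] = np.nan
    out.ci_low[wide] = np.nan
    out.ci_high[wide] = np.nan
    out.provenance[wide] = MISSING
    return out


def impute_missing_cells(
    pmatrix: PercentMethylationMatrix, integer_ages
) -> PercentMethylationMatrix:
    """Median-by-age imputation of missing methylation fractions.

    A missing cell takes the median of observed values at that site among
    fish of the same integer (otolith-derived) age; if none exist, among fish
    at the smallest absolute age difference, pooling ties. Observed cells are
    never altered; the result has no missing cells.
    """
    ages = np.asarray(integer_ages)
    if ages.shape[0] != len(pmatrix.fish_ids):
        raise ValueError("integer_ages must align with fish_ids")
    out = pmatrix.copy()
    observed = out.provenance == OBSERVED
    empty = ~observed.any(axis=0)
    if empty.any():
        names = [out.site_ids[j] for j in np.flatnonzero(empty)]
        raise ValueError(f"sites with zero observed cells cannot be imputed: {names}")
    unique_ages = np.unique(ages)
    for j in range(out.p.shape[1]):
        miss = np.flatnonzero(~observed[:, j])
        if miss.size == 0:
            continue
        obs_mask = observed[:, j]
        for f in miss:
            donors = obs_mask & (ages == ages[f])
            if not donors.any():
                diffs = np.abs(unique_ages - ages[f])
                # restrict to ages with observed donors at this site
                has = np.array([bool((obs_mask & (ages == a)).any()) for a in unique_ages])
                best = diffs[has].min()
                pool_ages = unique_ages[has & (diffs == best)]
                donors = obs_mask & np.isin(ages, pool_ages)
            out.p[f, j] = np.median(out.p[donors, j])
            out.provenance[f, j] = IMPUTED
            out.ci_low[f, j] = np.nan
            out.ci_high[f, j] = np.nan
    return out
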