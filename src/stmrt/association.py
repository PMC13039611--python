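"""Association between spectrotemporal sensitivity and speech-in-noise perception.

Four analyses relate the ripple reaction-time measures to speech-reception
thresholds (SRT):

* a Spearman rank-correlation matrix (one cell per stimulus) with
  Holm-Bonferroni family-wise error control over the 17-test family;
* Bayesian 95% credible intervals for Pearson's r computed on promptness
  (1/RT), whose distribution is approximately Gaussian, via MCMC over the
  bivariate-normal correlation;
* the standardized regression ``SRT = b1*z(Age) + b2*z(Pr) +
  b3*[z(Age)*z(Pr)]`` fitted by least squares, with an optional stepwise
  term-selection variant;
* a simplified Bayesian hierarchical model of the censored log reaction
  times with main effects of implementation, stimulus and participant plus
  all first-order interactions, estimated by MAP with a Laplace (Gaussian)
  posterior approximation under weakly-informative normal priors.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import emcee
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.stats import norm, spearmanr

__all__ = [
    "CorrelationCell",
    "RegressionResult",
    "spearman_matrix",
    "spearman_pvalue",
    "holm_bonferroni",
    "bayes_pearson_ci",
    "fit_srt_regression",
    "fit_hierarchical_rt_model",
    "HierarchicalRTResult",
]


# ---------------------------------------------------------------------------
# Spearman matrix with Holm-Bonferroni control


def holm_bonferroni(p_values, alpha: float = 0.05, family_size: int | None = None) -> np.ndarray:
    """Holm step-down significance flags for a family of tests.

    ``family_size`` may exceed the number of supplied p-values (tests missing
    from the input still count toward the correction); the step-down
    thresholds are ``alpha / (m - rank)`` with ``m`` the family size.
    """
    p = np.asarray(p_values, float)
    m = family_size if family_size is not None else len(p)
    if m < len(p):
        raise ValueError("family_size smaller than number of p-values")
    order = np.argsort(p)
    significant = np.zeros(len(p), bool)
    for rank, idx in enumerate(order):
        if np.isnan(p[idx]) or p[idx] > alpha / (m - rank):
            break
        significant[idx] = True
    return significant


@functools.lru_cache(maxsize=8)
def _spearman_null_quantiles(n: int, k: int = 200_000, seed: int = 12345) -> np.ndarray:
    """Monte-Carlo null distribution of |Spearman rho| for sample size n.

    Under independence (and no ties) the distribution of rho depends only on
    n, so one cached table serves every test at that size.  The table is
    seeded for determinism.
    """
    rng = np.random.default_rng(seed)
    ident = np.arange(1, n + 1)
    perms = np.argsort(rng.random((k, n)), axis=1) + 1
    d2 = ((perms - ident) ** 2).sum(axis=1)
    rho = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    return np.sort(np.abs(rho))


def spearman_pvalue(rho: float, n: int, method: str = "auto") -> float:
    """Two-sided p-value for Spearman's rho.

    ``"permutation"`` uses the cached Monte-Carlo permutation null (add-one
    corrected, hence never anticonservative); ``"t"`` the large-sample t
    approximation; ``"auto"`` switches from permutation to t above n = 50,
    where the approximation's far-tail error becomes negligible.
    """
    if method == "auto":
        method = "permutation" if n <= 50 else "t"
    if method == "t":
        tt = rho * np.sqrt((n - 2) / max(1.0 - rho**2, 1e-300))
        from scipy.stats import t as t_dist

        return float(2.0 * t_dist.sf(abs(tt), n - 2))
    table = _spearman_null_quantiles(n)
    k = len(table)
    count = k - np.searchsorted(table, abs(rho) - 1e-12, side="left")
    return float((count + 1) / (k + 1))


@dataclass
class CorrelationCell:
    stimulus_id: str
    r_spearman: float
    p_raw: float
    holm_significant: bool
    n: int
    r_pearson_promptness: float = np.nan
    ci95: tuple[float, float] = (np.nan, np.nan)


def spearman_matrix(
    medians: pd.DataFrame,
    srt: pd.DataFrame,
    family_size: int = 17,
    value_col: str = "median_rt_s",
    alpha: float = 0.05,
    p_method: str = "auto",
) -> pd.DataFrame:
    """Spearman correlation between the per-participant RT measure and SRT,
    one cell per stimulus, with Holm-Bonferroni control over the family.

    ``medians`` must have columns (participant, stimulus_id, ``value_col``);
    ``srt`` columns (participant, srt_db).  Ties are handled by midranks.
    At cohort-sized n the p-values come from the permutation null of rho
    (see :func:`spearman_pvalue`), which keeps the far tail honest where the
    t approximation is anticonservative.  Cells with a constant SRT or RT
    vector get an undefined correlation flag (NaN) rather than an exception.
    """
    merged = medians.merge(srt, on="participant")
    rows = []
    for sid, grp in merged.groupby("stimulus_id"):
        x = grp[value_col].to_numpy(dtype=float)
        y = grp["srt_db"].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        x, y = x[ok], y[ok]
        if len(x) < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((sid, np.nan, np.nan, len(x)))
            continue
        r, _ = spearmanr(x, y)
        p = spearman_pvalue(float(r), len(x), method=p_method)
        rows.append((sid, float(r), float(p), len(x)))
    out = pd.DataFrame(rows, columns=["stimulus_id", "r_spearman", "p_raw", "n"])
    out["holm_significant"] = holm_bonferroni(
        out["p_raw"].to_numpy(), alpha=alpha, family_size=max(family_size, len(out))
    )
    return out


# ---------------------------------------------------------------------------
# Bayesian credible interval for Pearson's r on promptness


def _bivariate_normal_logpost(theta, x, y):
    mu1, mu2, log_s1, log_s2, z = theta
    if abs(z) > 7.0 or not (np.isfinite(log_s1) and np.isfinite(log_s2)):
        return -np.inf
    s1, s2 = np.exp(log_s1), np.exp(log_s2)
    rho = np.tanh(z)
    dx = (x - mu1) / s1
    dy = (y - mu2) / s2
    one_m = 1.0 - rho**2
    n = len(x)
    ll = (
        -n * (log_s1 + log_s2)
        - 0.5 * n * np.log(one_m)
        - 0.5 * np.sum(dx**2 - 2 * rho * dx * dy + dy**2) / one_m
    )
    # Jeffreys-type scale prior; uniform prior on rho via the tanh Jacobian
    return ll + np.log(one_m)


@dataclass
class PearsonPosterior:
    r_median: float
    ci95: tuple[float, float]
    samples: np.ndarray
    ess: float
    ess_warning: bool

    @property
    def excludes_zero(self) -> bool:
        return self.ci95[0] > 0.0 or self.ci95[1] < 0.0


def bayes_pearson_ci(
    promptness,
    srt,
    burn_in: int = 500,
    samples: int = 1000,
    seed: int | None = None,
    n_walkers: int = 16,
) -> PearsonPosterior:
    """Posterior 95% credible interval for the bivariate-normal Pearson r.

    Affine-invariant ensemble MCMC over (means, log-SDs, atanh r) with a
    uniform prior on r; ``burn_in`` steps are discarded and the chain is run
    until at least ``samples`` posterior draws are collected.  An effective
    sample size below 100 sets a warning flag.
    """
    x = np.asarray(promptness, float)
    y = np.asarray(srt, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need at least 5 paired observations")
    rng = np.random.default_rng(seed)
    r0 = float(np.corrcoef(x, y)[0, 1])
    r0 = np.clip(r0, -0.99, 0.99)
    center = np.array(
        [x.mean(), y.mean(), np.log(x.std() + 1e-12), np.log(y.std() + 1e-12), np.arctanh(r0)]
    )
    p0 = center + 1e-3 * rng.standard_normal((n_walkers, 5))
    sampler = emcee.EnsembleSampler(n_walkers, 5, _bivariate_normal_logpost, args=(x, y))
    sampler._random = np.random.RandomState(rng.integers(2**31))
    n_steps = burn_in + int(np.ceil(samples / n_walkers))
    sampler.run_mcmc(p0, n_steps, progress=False)
    z = sampler.get_chain(discard=burn_in, flat=True)[:, 4]
    rho = np.tanh(z)[:samples] if samples <= len(z) else np.tanh(z)
    try:
        tau = float(sampler.get_autocorr_time(discard=burn_in, tol=0)[4])
        ess = n_walkers * (n_steps - burn_in) / max(tau, 1.0)
    except Exception:
        ess = float(len(rho))
    lo, hi = np.quantile(rho, [0.025, 0.975])
    return PearsonPosterior(
        r_median=float(np.median(rho)),
        ci95=(float(lo), float(hi)),
        samples=rho,
        ess=ess,
        ess_warning=ess < 100,
    )


# ---------------------------------------------------------------------------
# SRT ~ age + promptness regression (with stepwise selection)


@dataclass
class RegressionResult:
    betas: dict[str, float]
    p_values: dict[str, float]
    adjusted_r2: float
    selected_terms: list[str]
    intercept: float = np.nan


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=0)


def fit_srt_regression(
    age, promptness, srt, stepwise: bool = False, p_enter: float = 0.05, p_remove: float = 0.10
) -> RegressionResult:
    """Standardized linear model of SRT on age and median promptness.

    Fits ``SRT = b0 + b1*z(Age) + b2*z(Pr) + b3*[z(Age)*z(Pr)]`` by ordinary
    least squares on z-scored predictors.  With ``stepwise=True``, terms are
    entered/removed by p-value thresholds (enter below ``p_enter``, remove
    above ``p_remove``), mirroring classic stepwise regression defaults.
    """
    age = np.asarray(age, float)
    pr = np.asarray(promptness, float)
    srt = np.asarray(srt, float)
    if np.isnan(age).any() or np.isnan(pr).any() or np.isnan(srt).any():
        raise ValueError("missing values among included participants")
    z_age = _zscore(age)
    z_pr = _zscore(pr)
    if abs(np.corrcoef(z_age, z_pr)[0, 1]) > 0.999:
        raise ValueError("collinear predictors: |r(age, promptness)| > 0.999")
    terms = {"z_age": z_age, "z_pr": z_pr, "z_age:z_pr": z_age * z_pr}

    def ols(selected: list[str]):
        X = sm.add_constant(
            np.column_stack([terms[t] for t in selected]) if selected else np.empty((len(srt), 0))
        )
        return sm.OLS(srt, X).fit()

    if not stepwise:
        selected = list(terms)
    else:
        selected = []
        while True:
            changed = False
            # forward step: best candidate below p_enter
            best_t, best_p = None, p_enter
            for t in terms:
                if t in selected:
                    continue
                res = ols(selected + [t])
                p = res.pvalues[-1]
                if p < best_p:
                    best_t, best_p = t, p
            if best_t is not None:
                selected.append(best_t)
                changed = True
            # backward step: drop worst term above p_remove
            if selected:
                res = ols(selected)
                pvals = res.pvalues[1:]
                worst = int(np.argmax(pvals))
                if pvals[worst] > p_remove:
                    selected.pop(worst)
                    changed = True
            if not changed:
                break
    res = ols(selected)
    betas = dict(zip(selected, np.asarray(res.params)[1:]))
    pvals = dict(zip(selected, np.asarray(res.pvalues)[1:]))
    return RegressionResult(
        betas=betas,
        p_values=pvals,
        adjusted_r2=float(res.rsquared_adj) if selected else 0.0,
        selected_terms=selected,
        intercept=float(np.asarray(res.params)[0]),
    )


# ---------------------------------------------------------------------------
# hierarchical censored log-RT model (MAP + Laplace)


@dataclass
class HierarchicalRTResult:
    """Posterior summaries of the censored log-RT model.

    One row per effect in ``summary``: term, level, posterior mean, SD and
    95% credible bounds from the Laplace (Gaussian) approximation at the
    MAP under weakly-informative Normal(0, prior_sd) priors on all effects.
    """

    summary: pd.DataFrame
    sigma: float
    converged: bool
    log_posterior: float
    flags: list[str] = field(default_factory=list)


def _sum_code(labels: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero (deviation) coding: k levels -> k-1 columns.

    The dropped (last) level's effect is minus the sum of the others.
    """
    levels = sorted(labels.unique())
    k = len(levels)
    idx = labels.map({lv: i for i, lv in enumerate(levels)}).to_numpy()
    X = np.zeros((len(labels), k - 1))
    for j in range(k - 1):
        X[idx == j, j] = 1.0
    X[idx == k - 1, :] = -1.0
    return X, levels


def fit_hierarchical_rt_model(
    clean: pd.DataFrame,
    ceiling_s: float = 2.5,
    prior_sd: float = 1.0,
    include_interactions: bool = True,
) -> HierarchicalRTResult:
    """Bayesian regression of log RT with right-censoring at log(ceiling).

    Main effects of implementation, stimulus and participant (sum-to-zero
    coded) plus all first-order interactions.  Observed trials contribute the
    normal density of log RT; censored trials the survival function.  All
    effects carry Normal(0, ``prior_sd``) priors; the intercept and log noise
    SD are unpenalized.  The posterior is summarized by its Laplace
    approximation at the MAP (mean = MAP, covariance = inverse Hessian).
    """
    for col in ("rt_s", "censored"):
        if col not in clean.columns:
            raise ValueError("expected a preprocessed table with rt_s and censored")
    factors = {}
    for name in ("implementation", "stimulus_id", "participant"):
        if clean[name].nunique() < 1:
            raise ValueError(f"factor {name} has no levels")
        factors[name] = name
    y = np.log(clean["rt_s"].to_numpy(dtype=float))
    cens = clean["censored"].to_numpy(dtype=bool)
    c_log = np.log(ceiling_s)

    blocks: list[tuple[str, list[str], np.ndarray]] = []
    mains: dict[str, tuple[np.ndarray, list[str]]] = {}
    for name in factors:
        X, levels = _sum_code(clean[name])
        mains[name] = (X, levels)
        if X.shape[1] > 0:
            blocks.append((name, [str(lv) for lv in levels[:-1]], X))
    if include_interactions:
        names = list(factors)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                Xi, li = mains[names[i]]
                Xj, lj = mains[names[j]]
                if Xi.shape[1] == 0 or Xj.shape[1] == 0:
                    continue
                cols, labels = [], []
                for a in range(Xi.shape[1]):
                    for b in range(Xj.shape[1]):
                        cols.append(Xi[:, a] * Xj[:, b])
                        labels.append(f"{li[a]}:{lj[b]}")
                blocks.append((f"{names[i]}x{names[j]}", labels, np.column_stack(cols)))

    X = np.column_stack([np.ones(len(y))] + [b[2] for b in blocks])
    p = X.shape[1]
    penal = np.ones(p)
    penal[0] = 0.0  # intercept unpenalized

    def neg_log_post(theta):
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        z = (y - eta) / sigma
        ll = np.sum(norm.logpdf(z[~cens])) - (~cens).sum() * log_sigma
        if cens.any():
            u = (eta[cens] - c_log) / sigma
            ll += np.sum(norm.logcdf(u))
        lp = -0.5 * np.sum(penal * beta**2) / prior_sd**2
        return -(ll + lp)

    def grad(theta):
        beta, log_sigma = theta[:p], theta[p]
        sigma = np.exp(log_sigma)
        eta = X @ beta
        g_beta = np.zeros(p)
        z_obs = (y[~cens] - eta[~cens]) / sigma
        g_beta += X[~cens].T @ z_obs / sigma
        g_sig = np.sum(z_obs**2 - 1.0)
        if cens.any():
            u = (eta[cens] - c_log) / sigma
            lam = np.exp(norm.logpdf(u) - norm.logcdf(u))
            g_beta += X[cens].T @ lam / sigma
            g_sig += np.sum(-lam * u)
        g_beta -= penal * beta / prior_sd**2
        return -np.concatenate([g_beta, [g_sig]])

    theta0 = np.zeros(p + 1)
    theta0[0] = float(np.mean(y))
    theta0[p] = float(np.log(np.std(y) + 1e-6))
    res = minimize(neg_log_post, theta0, jac=grad, method="L-BFGS-B", options={"maxiter": 2000})
    flags = [] if res.success else [f"optimizer: {res.message}"]

    # Laplace covariance from a finite-difference Hessian of the gradient
    theta = res.x
    eps = 1e-5
    H = np.zeros((p + 1, p + 1))
    g0 = grad(theta)
    for i in range(p + 1):
        step = np.zeros(p + 1)
        step[i] = eps
        H[:, i] = (grad(theta + step) - g0) / eps
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        sds = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        sds = np.full(p + 1, np.nan)
        flags.append("singular Hessian")

    rows = [("intercept", "", theta[0], sds[0])]
    k = 1
    for term, labels, Xb in blocks:
        for lab in labels:
            rows.append((term, lab, theta[k], sds[k]))
            k += 1
    summary = pd.DataFrame(rows, columns=["term", "level", "post_mean", "post_sd"])
    summary["ci_lo"] = summary["post_mean"] - 1.96 * summary["post_sd"]
    summary["ci_hi"] = summary["post_mean"] + 1.96 * summary["post_sd"]
    return HierarchicalRTResult(
        summary=summary,
        sigma=float(np.exp(theta[p])),
        converged=bool(res.success),
        log_posterior=-float(res.fun),
        flags=flags,
    )
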