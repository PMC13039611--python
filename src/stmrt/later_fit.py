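"""Reciprobit construction and censoring-aware LATER parameter estimation.

Under the LATER model, promptness (1/RT) is Gaussian, so plotting the
cumulative response probability on a probit scale against promptness yields
a straight line (the reciprobit plot).  Right-censored trials (non-responses
and RTs coded at the 2.5 s ceiling) correspond to promptness below the
reciprocal ceiling; they contribute no plotted point but count in the
denominator of the empirical CDF, depressing the asymptote, and enter the
maximum-likelihood fit through the normal CDF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = ["ReciprobitFit", "reciprobit_points", "fit_later", "fit_later_table"]


@dataclass
class ReciprobitFit:
    """Fitted promptness distribution for one (participant x stimulus) cell."""

    mu_p_hat: float  # median promptness, s^-1
    sigma_p_hat: float  # SD of promptness, s^-1
    n_used: int
    n_censored: int
    r2_line: float  # goodness of the probit-vs-promptness line
    method: str  # "mle_censored" or "ls_line"
    converged: bool = True
    message: str = ""


def reciprobit_points(
    rts_s: np.ndarray, censored: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Reciprobit coordinates: (promptness, probit of cumulative probability).

    Uncensored RTs are sorted ascending; the empirical CDF uses the Hazen
    plotting position (i - 0.5)/n with n counting ALL trials, censored
    included, so misses depress the reachable asymptote.  Censored trials
    contribute no point.  The promptness axis is conventionally plotted
    flipped (fast responses on the left).
    """
    rts_s = np.asarray(rts_s, float)
    censored = (
        np.zeros(len(rts_s), bool) if censored is None else np.asarray(censored, bool)
    )
    obs = np.sort(rts_s[~censored])
    n_total = len(rts_s)
    if len(obs) < 2:
        raise ValueError("need at least 2 uncensored responses for a reciprobit plot")
    cdf = (np.arange(1, len(obs) + 1) - 0.5) / n_total
    return 1.0 / obs, norm.ppf(cdf)


def _line_fit(promptness: np.ndarray, probit: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line probit = a + b*promptness; returns (a, b, r2)."""
    b, a = np.polyfit(promptness, probit, 1)
    resid = probit - (a + b * promptness)
    ss_tot = float(np.sum((probit - probit.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return a, b, r2


def fit_later(
    rts_s: np.ndarray,
    censored: np.ndarray | None = None,
    method: str = "mle_censored",
    ceiling_s: float = 2.5,
) -> ReciprobitFit:
    """Estimate (mu_p, sigma_p) of the promptness distribution.

    ``mle_censored`` (default) maximizes the likelihood of promptness ~
    Normal(mu_p, sigma_p) where each censored trial contributes
    ``Phi((1/ceiling - mu_p)/sigma_p)`` (its promptness lies below the
    reciprocal ceiling).  ``ls_line`` back-solves the parameters from the
    least-squares reciprobit line, ignoring censoring beyond its effect on
    the plotting positions: with probit(P(RT <= rt)) = -(p - mu)/sigma as a
    function of promptness p, the slope is -1/sigma.

    Non-convergence is reported via flags on the returned fit, not raised.
    """
    rts_s = np.asarray(rts_s, float)
    censored = (
        np.zeros(len(rts_s), bool) if censored is None else np.asarray(censored, bool)
    )
    obs_p = 1.0 / rts_s[~censored]
    n_cens = int(censored.sum())
    n_obs = len(obs_p)

    # reciprobit line (also the r2 diagnostic for the MLE)
    try:
        x, y = reciprobit_points(rts_s, censored)
        # y = probit(P(RT<=rt)) = -(p - mu)/sigma  =>  slope -1/sigma
        a, b, r2 = _line_fit(x, y)
    except ValueError:
        a = b = np.nan
        r2 = np.nan

    if method == "ls_line":
        if not np.isfinite(b) or b >= 0:
            return ReciprobitFit(
                np.nan, np.nan, n_obs, n_cens, r2, method, False, "degenerate line fit"
            )
        sigma = -1.0 / b
        mu = a * sigma
        return ReciprobitFit(float(mu), float(sigma), n_obs, n_cens, r2, method)

    if method != "mle_censored":
        raise ValueError(f"unknown method {method!r}")
    if n_obs < 5:
        raise ValueError("mle_censored needs at least 5 uncensored responses")

    p_c = 1.0 / ceiling_s
    mu0 = float(np.mean(obs_p))
    s0 = float(np.std(obs_p)) or 0.1 * mu0

    def nll(theta):
        mu, log_s = theta
        s = np.exp(log_s)
        ll = np.sum(norm.logpdf(obs_p, mu, s))
        if n_cens:
            ll += n_cens * norm.logcdf((p_c - mu) / s)
        return -ll

    res = minimize(nll, [mu0, np.log(s0)], method="Nelder-Mead")
    mu_hat, sigma_hat = float(res.x[0]), float(np.exp(res.x[1]))
    ok = bool(res.success) and mu_hat > 0
    return ReciprobitFit(
        mu_hat, sigma_hat, n_obs, n_cens, r2, method, ok, "" if ok else str(res.message)
    )


def fit_later_table(
    clean: pd.DataFrame, method: str = "mle_censored", min_uncensored: int = 5
) -> pd.DataFrame:
    """LATER fits for every (participant, implementation, stimulus) cell."""
    rows = []
    for key, grp in clean.groupby(["participant", "implementation", "stimulus_id"]):
        rts = grp["rt_s"].to_numpy()
        cens = grp["censored"].to_numpy()
        if (~cens).sum() < min_uncensored:
            rows.append((*key, np.nan, np.nan, int((~cens).sum()), int(cens.sum()), np.nan, False))
            continue
        fit = fit_later(rts, cens, method=method)
        rows.append(
            (*key, fit.mu_p_hat, fit.sigma_p_hat, fit.n_used, fit.n_censored, fit.r2_line, fit.converged)
        )
    return pd.DataFrame(
        rows,
        columns=[
            "participant",
            "implementation",
            "stimulus_id",
            "mu_p_hat",
            "sigma_p_hat",
            "n_used",
            "n_censored",
            "r2_line",
            "converged",
        ],
    )
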