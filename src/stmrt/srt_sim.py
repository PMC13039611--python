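"""Adaptive speech-in-noise (matrix test) simulation.

The matrix test presents 5-word sentences in stationary noise; the listener
selects one word per column of a 10 x 5 matrix, so chance performance is
1/10 per word.  The word-correct probability follows a psychometric function

    P(snr) = guess + (1 - guess - lapse) * logistic((snr - srt50)/s)

with ``srt50`` the midpoint (the adaptively tracked 50% speech-reception
threshold) and the internal scale ``s`` set so that the slope at the
midpoint equals the configured probability-per-dB value.

The adaptive run starts at +10 dB SNR and initially steps down by 2 dB
whenever at least three of five words are correct (up by 2 dB otherwise).
Once the responses bracket the threshold, a maximum-likelihood logistic fit
to all (SNR, words-correct) data so far places each subsequent sentence at
the current midpoint estimate.  After 20 sentences the final fit yields the
threshold; if the fit error is large (binomial deviance above 1.5 x its
degrees of freedom) or the fit is unidentifiable, the mean of the final 8
presented SNRs is used instead and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, xlogy

__all__ = ["MatrixListener", "AdaptiveRun", "respond_sentence", "run_adaptive", "simulate_srt_measurement"]

WORDS_PER_SENTENCE = 5
GUESS_DEFAULT = 0.1


@dataclass(frozen=True)
class MatrixListener:
    """Psychometric word-level model of a matrix-test listener."""

    srt50_db: float
    slope: float = 0.15  # probability/dB at the midpoint
    guess: float = GUESS_DEFAULT
    lapse: float = 0.0

    def p_word(self, snr_db) -> np.ndarray:
        """Word-correct probability at the given SNR(s)."""
        span = 1.0 - self.guess - self.lapse
        s = span / (4.0 * self.slope)  # slope at midpoint = span/(4 s)
        return self.guess + span * expit((np.asarray(snr_db, float) - self.srt50_db) / s)


@dataclass
class AdaptiveRun:
    snr_track: list[float] = field(default_factory=list)
    words_correct: list[int] = field(default_factory=list)
    srt_est_db: float = np.nan
    fit_ok: bool = False
    fallback_used: bool = False


def respond_sentence(
    listener: MatrixListener, snr_db: float, seed: int | np.random.Generator | None = None
) -> int:
    """Number of correctly reported words (0-5): independent Bernoulli draws."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return int(rng.binomial(WORDS_PER_SENTENCE, listener.p_word(snr_db)))


def _fit_logistic_ml(
    snrs: np.ndarray, k: np.ndarray, guess: float = GUESS_DEFAULT
) -> tuple[float, float, float, bool]:
    """ML logistic fit with fixed guessing floor.

    Fits (midpoint, scale) of ``P = guess + (1-guess)*logistic((snr-mid)/s)``
    to words-correct counts; returns (mid, s, deviance, identifiable).
    """
    snrs = np.asarray(snrs, float)
    k = np.asarray(k, float)
    n = WORDS_PER_SENTENCE
    # identifiability needs performance on both sides of the threshold
    if not ((k >= 3).any() and (k < 3).any()):
        return np.nan, np.nan, np.inf, False

    span = 1.0 - guess

    def nll(theta):
        mid, log_s = theta
        p = guess + span * expit((snrs - mid) / np.exp(log_s))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -float(np.sum(xlogy(k, p) + xlogy(n - k, 1 - p)))

    x0 = [float(np.mean(snrs)), np.log(2.0)]
    res = minimize(nll, x0, method="Nelder-Mead")
    mid, s = float(res.x[0]), float(np.exp(res.x[1]))
    # binomial deviance vs the saturated model
    p_hat = np.clip(guess + span * expit((snrs - mid) / s), 1e-9, 1 - 1e-9)
    ll_fit = float(np.sum(xlogy(k, p_hat) + xlogy(n - k, 1 - p_hat)))
    p_sat = np.clip(k / n, 1e-9, 1 - 1e-9)
    ll_sat = float(np.sum(xlogy(k, p_sat) + xlogy(n - k, 1 - p_sat)))
    deviance = 2.0 * (ll_sat - ll_fit)
    return mid, s, deviance, bool(res.success)


def run_adaptive(
    listener: MatrixListener,
    n_sentences: int = 20,
    start_snr_db: float = 10.0,
    seed: int | np.random.Generator | None = None,
    step_db: float = 2.0,
    fallback_n: int = 8,
    deviance_criterion: float = 1.5,
    snr_limits: tuple[float, float] = (-30.0, 30.0),
) -> AdaptiveRun:
    """One adaptive matrix-test list of ``n_sentences`` sentences.

    SNR placement follows the initial up/down rule (down by ``step_db`` when
    at least 3 of 5 words are correct) until the ML fit is identifiable, then
    tracks the running maximum-likelihood midpoint.  The final threshold is
    the 20-sentence ML midpoint, falling back to the mean of the last
    ``fallback_n`` presented SNRs when the fit fails or its deviance exceeds
    ``deviance_criterion`` times the residual degrees of freedom.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    run = AdaptiveRun()
    snr = float(start_snr_db)
    for _ in range(n_sentences):
        snr = float(np.clip(snr, *snr_limits))
        k = respond_sentence(listener, snr, rng)
        run.snr_track.append(snr)
        run.words_correct.append(k)
        mid, _, _, identifiable = _fit_logistic_ml(run.snr_track, run.words_correct)
        if identifiable and np.isfinite(mid):
            snr = mid
        else:
            snr = snr - step_db if k >= 3 else snr + step_db
    mid, _, deviance, identifiable = _fit_logistic_ml(run.snr_track, run.words_correct)
    dof = max(n_sentences - 2, 1)
    run.fit_ok = identifiable and np.isfinite(mid) and deviance <= deviance_criterion * dof
    if run.fit_ok:
        run.srt_est_db = float(mid)
    else:
        run.srt_est_db = float(np.mean(run.snr_track[-fallback_n:]))
        run.fallback_used = True
    return run


def simulate_srt_measurement(
    listener: MatrixListener,
    n_lists: int = 2,
    seed: int | np.random.Generator | None = None,
    **kwargs,
) -> tuple[float, list[AdaptiveRun]]:
    """Mean threshold over ``n_lists`` adaptive lists (the per-participant SRT)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    runs = [run_adaptive(listener, seed=rng, **kwargs) for _ in range(n_lists)]
    return float(np.mean([r.srt_est_db for r in runs])), runs
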