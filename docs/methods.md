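# Methods

This note documents the models, algorithms, numerical choices and known
limitations of the `stmrt` package: a toolkit for spectrotemporal-modulation
reaction-time (STM-RT) testing, covering stimulus synthesis, listener
simulation, censored reaction-time analysis, adaptive speech-in-noise
threshold simulation, and the association analyses linking the two domains.

## Stimulus synthesis (`stmrt.ripple_synth`)

### Carrier

The carrier is pink noise (power spectral density proportional to 1/f),
generated by spectral shaping of seeded white Gaussian noise (amplitude
proportional to 1/sqrt(f), DC removed) and then band-passed from 0.1 to
8.7 kHz with a **first-order Butterworth** filter applied once, causally.
Synthesis is at 44.1 kHz. Identical (spec, seed, calibration) inputs produce
bit-identical audio.

Because a first-order filter has gentle skirts, roughly 12% of the carrier
power lies outside the nominal 0.1–8.7 kHz passband, and the in-passband
response is not perfectly flat. Two measurement conventions follow from
this:

* **Calibration** references the carrier's power *inside* the nominal
  passband: "noise at 60 dB SPL" means the 0.1–8.7 kHz band level is
  60 dB SPL. Under this convention the accentuated broadband and
  narrowband stimuli measure 74.1 and 68.0 dB SPL overall, within 0.2 dB of
  the closed-form octave-power arithmetic
  `60 + 10*log10((N - k + k*10^(G/10))/N)` with N = log2(8700/100) ≈ 6.44
  octaves, k the accentuated octaves (5 broadband, 1 narrowband) and
  G = 15 dB.
* **Verification oracles** (PSD slope, band-power fractions, accentuation
  gain) compensate measured spectra with the full carrier model
  1/f × |H_butter(f)|², not the bare pink slope; the log-log PSD slope is
  fitted on a log-spaced frequency grid (≈ −3.16 dB/octave between 0.3 and
  6 kHz; a linear-frequency-weighted fit would be dominated by the filter
  rolloff near 6 kHz).

### Spectrotemporal modulation

A ripple with temporal rate w (Hz) and spectral density Ω (cycles/octave)
multiplies the time–frequency envelope by

    g(f, t) = 1 + m · sin(2π·(w·(t − t₀) + s·Ω·log2(f / f_lo)) + φ₀)

inside the target band for t ≥ t₀ (the randomized onset), with unity gain
elsewhere. Depth m = 0.82 by default, applied on a **linear amplitude
scale** (not dB); φ₀ = 0 at the band's lower edge f_lo at onset; s = ±1 is
an exposed drift-direction flag (default +1, downward drift for positive w
and Ω). The modulation starts instantaneously, without ramping.

The gain is imposed in the short-time Fourier domain: square-root Hann
analysis windows of 2048 samples (~46 ms) with 75% overlap, the canonical
dual window for synthesis (perfect reconstruction at unity gain; the
depth-0 residual is below −300 dB). The gain is evaluated at each bin's
center frequency and frame's center time. Overlap-add smears the temporal
modulation with an ~46 ms Hann kernel, attenuating the effective depth by a
factor ≈ 0.978 at 4 Hz (measured envelope depth ~80% for m = 82%) and more
at 16 Hz; spectral smearing similarly limits very high densities at low
frequencies. These are inherent trade-offs of the analysis/synthesis
window; the window length is exposed for sensitivity analysis.

### Accentuation

The modulated band is boosted by 15 dB relative to the surrounding noise
for the **full** stimulus duration. The dB-gain-versus-frequency profile is
flat inside the band with raised-cosine (Hanning) transitions of 100 Hz
width in linear frequency, centered on the band edges (so the gain at the
exact edge is half the accent). Being time-invariant, the accentuation is
applied as a zero-phase spectral multiplication; it commutes with the
modulation gain (measured order effect < 0.001 dB).

### Trial assembly and stimulus set

A trial is: pink carrier → 60 dB SPL calibration → accentuation →
modulation from an onset drawn uniformly from {0.7, 0.8, …, 1.2} s, lasting
at most 3 s. The canonical set has 17 conditions: four 1-octave narrowband
ripples ([4 Hz, 2 c/o] at 500/1000/2000/4000 Hz), twelve broadband
combinations ([0 Hz]×{2, 1, 0.5, 0.25}, [4 Hz]×{2, 1, 0.5, 0},
[8 Hz]×{1, 0.5, 0}, [16 Hz]×{0.25} c/o), and one broadband catch stimulus
([0 Hz, 0 c/o]) that is processed identically but contains no modulation.

The automatic-gain-control stand-in is a deliberately simple documented
gain trajectory (unity until 0.4 s, raised-cosine transition to a fixed
steady-state attenuation); it reproduces the timing property that matters
for the paradigm — the level is stable before the earliest modulation
onset — and nothing else. Its output levels are not design targets.

## Listener simulation (`stmrt.trial_sim`)

Reaction times follow the LATER model (Linear Approach to Threshold with
Ergodic Rate): a decision signal rises linearly at a rate drawn per trial
from a Gaussian, so **promptness** (1/RT) is normally distributed. Because
threshold distance and rise rate are not separately identifiable from RTs,
the model is parameterized directly on the promptness scale as
(mu_p, sigma_p); draws are truncated to positive promptness (negligible
mass for realistic parameters, mu_p/sigma_p ≥ 3).

On top of the LATER unit each trial can end as:

* a **lapse** (non-response) with probability `lapse_rate` (default 0.03);
* a **false positive**: a homogeneous Poisson process (default 0.02 s⁻¹)
  runs from noise onset and races the LATER response — the earliest event
  wins. Catch trials contain no ripple onset, so they can only end in a
  false positive or a non-response; raising the false-positive rate
  monotonically raises catch-trial response probability.
* a **premature** response (false positive before modulation onset):
  the trial is reiterated, mirroring the test procedure; the count is kept.

Responses later than 3 s after onset (the stimulus end) are non-responses.

Cohort defaults emulate the study conditions: 20 participants, 17 stimuli
× 10 trials × 2 blocks × 2 implementations (680 trials per participant),
and a fixed 470 ms technical delay added to App-recorded reaction times.
Per-stimulus baseline median RTs span 0.42–0.90 s (well-perceived
broadband ripples fastest, narrowband and high-density spectral ripples
slowest), sigma_p/mu_p = 0.3, matching the range of published reciprobit
geometry for this paradigm. A standard-normal latent
spectrotemporal-sensitivity trait multiplies promptness by
exp(loading × trait); loadings default to 0.2, with 0.35 for three
speech-relevant stimuli ([0 Hz, 0.25 c/o], [8 Hz, 0.5 c/o], narrowband
4 kHz) and 0 for the purely temporal [8 Hz, 0 c/o] stimulus, which is thus
trait-independent by construction. The true speech-reception threshold is
`SRT = b_trait·trait + b_age·z(age) + ε` with defaults b_trait = −1.5,
b_age = 0.5, ε ~ N(0, 0.8 dB): sensitive listeners respond faster *and*
understand speech at worse SNRs, giving downstream association analyses a
known ground truth.

What the generator does **not** emulate: age-related motor slowing,
learning or fatigue across blocks, express-response limbs, non-stationary
false-positive rates, and any dependence of the technical delay on trial or
stimulus. Passing tests therefore demonstrate that the analysis chain
recovers a known LATER-world ground truth — not that real cohort data meet
these assumptions.

## Reaction-time pipeline (`stmrt.rt_pipeline`)

* Censoring: RTs above 2.5 s and non-responses are coded at exactly 2.5 s
  with a censored flag. Responses faster than 140 ms are removed as
  anticipatory (exclusive floor: exactly 140 ms is retained).
* Delay correction: subtracted from raw App RTs *before* the censor/floor
  re-check, so a corrected RT below 140 ms is removed.
* Block pooling: a two-sample Kolmogorov–Smirnov check per
  (participant × implementation × stimulus) with the asymptotic p-value
  (simulated type-I error 4.2% at 10 trials/block; the exact small-sample
  method is markedly conservative here, 1.3%). Blocks are pooled
  regardless; the check is diagnostic.
* Medians are computed over the pooled coded values (censored codes
  included; a fully-censored cell is flagged, not dropped); even counts use
  the mean-of-central-pair convention.
* The technical delay is the group-level mean of per-participant
  App-minus-Laptop differences of median RTs over three well-perceived
  reference stimuli ([4 Hz, 0.5 c/o], [8 Hz, 0 c/o], [16 Hz, 0.25 c/o]).
  On 20-participant synthetic cohorts the estimator is unbiased with a
  seed-to-seed SD of ~8 ms. Group-level (not per-participant) subtraction
  is the default; per-participant correction is available for sensitivity
  analysis.

## Reciprobit analysis (`stmrt.later_fit`)

Reciprobit points plot probit(empirical CDF) against promptness, using the
Hazen plotting position (i − 0.5)/n with n counting **all** trials,
censored included — misses depress the reachable asymptote, mirroring their
lumping at the response ceiling, while contributing no point. Two
estimators of (mu_p, sigma_p):

* `mle_censored` (default): promptness ~ Normal(mu_p, sigma_p); each
  censored trial contributes Φ((1/2.5 − mu_p)/sigma_p). Nelder–Mead on
  (mu, log sigma), initialized at the uncensored moments. At 20 trials and
  30% censoring the bias is below 1% (mu) and 3% (sigma).
* `ls_line`: back-solves the parameters from the least-squares reciprobit
  line (slope = −1/sigma). With the all-trials plotting positions this is
  only mildly biased under censoring; a naive variant whose denominator
  drops censored trials is measurably worse (shown in tests).

Truncation at zero promptness is ignored in the likelihood (negligible for
realistic parameters). Express/early-response limbs are not modeled;
sub-140 ms responses are removed upstream.

## Estimation statistics (`stmrt.estimation_stats`)

`bootstrap_mean_diff` draws 5000 paired resamples (default) and reports the
difference of means with a 95% **BCa** interval: bias correction z₀ from
the fraction of bootstrap replicates below the point estimate (ties split),
acceleration a from the jackknife skewness over both samples. With z₀ = 0
and a = 0 the interval reduces exactly to the percentile interval. The
two-sided bootstrap p is the smaller tail fraction beyond zero, doubled,
floored at 2/n_boot. Null coverage at n = 40 is ~0.94 (the well-known
small-sample behavior of BCa), within the 0.95 ± 0.02 calibration band.

The MTF table reports per-stimulus means over **all** retained trials
across participants (censored codes included by default, since
non-detections carry sensitivity information; excludable by flag), with
percentile-bootstrap CIs, and slices into iso-velocity, iso-density and
narrowband-by-center-frequency views. Implementation comparisons pool all
individual data points rather than per-participant medians.

## Speech-in-noise simulation (`stmrt.srt_sim`)

The word-correct probability is
`P(snr) = g + (1 − g − λ)·logistic((snr − SRT50)/s)` with guessing floor
g = 1/10 (one word per 10-row matrix column), lapse λ (default 0), and
internal scale s chosen so the slope at the midpoint equals the configured
probability-per-dB (default 0.15/dB). Words within a sentence are
independent (5 Bernoulli draws).

The adaptive list starts at +10 dB SNR, steps −2 dB when ≥ 3 of 5 words are
correct (+2 dB otherwise) until the maximum-likelihood logistic fit to all
(SNR, count) data becomes identifiable (responses on both sides of the
3-word criterion), then places each next sentence at the running ML
midpoint. After 20 sentences the final ML midpoint is the threshold; if the
binomial deviance exceeds 1.5× its degrees of freedom or the fit is
unidentifiable, the mean of the last 8 presented SNRs is used and flagged.
The step sizes and the deviance criterion are documented stand-ins (the
original procedure's internals are not public) and are configurable.
Over 500 simulated lists the estimator is unbiased to < 0.05 dB with a
run-to-run SD of ~0.44 dB; ML placement is considerably more efficient
than a plain staircase. A participant's SRT is the mean of two lists.

## Association analyses (`stmrt.association`)

* **Spearman matrix**: rank correlation between the per-participant median
  RT (or promptness) and SRT, one cell per stimulus, with Holm–Bonferroni
  step-down control over the 17-test family (the family size counts tests,
  not available cells). For n ≤ 50 the p-values come from a cached,
  seeded Monte-Carlo permutation null of rho (200k permutations, add-one
  corrected) rather than the t approximation, whose far-tail
  anticonservatism at cohort size (P(p < 0.0029) ≈ 0.004 at n = 19) would
  inflate the family-wise error to ~0.06; with the permutation null the
  simulated FWER is ~0.047.
* **Bayesian Pearson CI on promptness**: affine-invariant ensemble MCMC
  (emcee) over the bivariate-normal parameters (means, log-SDs, atanh r)
  with a uniform prior on r and Jeffreys scale priors; 500 burn-in steps,
  ≥ 1000 posterior draws; an effective sample size below 100 raises a
  warning flag. Association is claimed when the 95% interval excludes zero.
* **SRT regression**: `SRT = β₁·z(Age) + β₂·z(Pr) + β₃·[z(Age)·z(Pr)]` by
  OLS on z-scored predictors; the stepwise variant enters terms below
  p = 0.05 and removes above p = 0.10 (classic defaults; the thresholds are
  parameters).
* **Hierarchical censored log-RT model**: normal regression on log RT with
  right-censoring at log 2.5 (observed trials contribute the density,
  censored trials the survival function), sum-to-zero coded main effects of
  implementation, stimulus and participant plus all pairwise interactions,
  Normal(0, 1) priors on all effects (intercept and log sigma flat).
  The posterior is summarized by its **Laplace approximation at the MAP**
  (L-BFGS with analytic gradients; covariance from a finite-difference
  Hessian). This is a deliberate simplification: it is fast, deterministic
  and accurate for the large-n, log-concave posteriors arising here, but it
  reports no sampler diagnostics and would understate uncertainty for
  strongly non-Gaussian posteriors. A log-normal RT likelihood is used
  here (location on log RT) rather than the reciprocal-normal LATER form;
  for a single cell the exponentiated location agrees with the censored
  LATER fit's median RT to within a few percent at moderate sigma.

## Problem sizes used in the validation suite

Calibration and recovery simulations use: 500 replicates of 20 trials for
LATER parameter recovery; 20-participant cohorts (13,600 trials) for the
delay round trip and the end-to-end correlation pattern; 1000 null
replicates at n = 40 (5000 resamples each) for BCa coverage; 500 adaptive
lists for SRT recovery; 1000 17-test families for the Holm FWER. Acoustic
checks use 10 s stimuli (60 s for the PSD-slope check).

## Known limitations

* The STFT envelope attenuates high temporal rates (≈ 2% at 4 Hz, more at
  16 Hz) and high spectral densities at low frequencies.
* The AGC stand-in models timing, not compression dynamics.
* The adaptive speech-test rules are plausible stand-ins, not a
  reconstruction of the original procedure.
* The hierarchical model's Laplace posterior is an approximation; the
  LATER likelihood and the log-normal likelihood are different tail models
  for the same censored data.
* Synthetic cohorts share one trait dimension; real listeners likely have
  multidimensional sensitivity profiles.
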