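"""Synthetic cohorts of LATER-model listeners for the ripple reaction-time test.

Each listener responds to the onset of spectrotemporal modulation with a
reaction time governed by the LATER model: a decision signal rises linearly
at a rate drawn per trial from a Gaussian, so promptness (1/RT) is normally
distributed.  On top of the LATER unit, trials can end in

* a lapse (no response despite an audible ripple),
* a false positive -- a stimulus-independent response arising from a
  homogeneous Poisson process that races the LATER unit (catch trials, which
  contain no modulation, can only end this way or in a non-response),
* a premature response (false positive before modulation onset), in which
  case the trial is reiterated, mirroring the test procedure.

A latent spectrotemporal-sensitivity trait links a participant's promptness
(for trait-loaded stimuli) to their true speech-reception threshold, giving
downstream association analyses a known ground truth.  App-recorded reaction
times carry a fixed technical delay relative to the Laptop implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ripple_synth import ONSET_GRID_S, RippleSpec, build_stimulus_table

__all__ = [
    "LATERParams",
    "ParticipantProfile",
    "CohortConfig",
    "simulate_later_rts",
    "simulate_cohort",
    "link_srt",
    "make_profiles",
    "DELAY_REFERENCE_STIMULI",
    "RESPONSE_WINDOW_S",
]

#: response window after modulation onset (s); the stimulus ends after 3 s
RESPONSE_WINDOW_S = 3.0

#: well-perceived stimuli used for App-vs-Laptop delay alignment
DELAY_REFERENCE_STIMULI = ("bb_4Hz_0.5co", "bb_8Hz_0co", "bb_16Hz_0.25co")

#: stimuli most strongly linked to speech-in-noise performance
SPEECH_RELEVANT_STIMULI = ("bb_0Hz_0.25co", "bb_8Hz_0.5co", "nb_4Hz_2co_4000")


@dataclass(frozen=True)
class LATERParams:
    """Per-(participant x stimulus) LATER parameters on the promptness scale.

    ``mu_p`` is the median promptness (s^-1) and ``sigma_p`` its SD; the
    threshold distance and rise rate of the underlying accumulator are not
    separately identifiable from RTs alone, so the model is parameterized
    directly on promptness.
    """

    mu_p: float
    sigma_p: float
    lapse_rate: float = 0.0
    fp_rate_hz: float = 0.0

    def __post_init__(self) -> None:
        if self.mu_p <= 0 or self.sigma_p <= 0:
            raise ValueError("mu_p and sigma_p must be positive")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")
        if self.fp_rate_hz < 0:
            raise ValueError("fp_rate_hz must be >= 0")


@dataclass
class ParticipantProfile:
    id: str
    age_years: float
    trait: float
    later: dict[str, LATERParams]
    srt_true_db: float = np.nan
    implementation_delay_s: float = 0.0


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Defaults emulate the structure of the real experiment: 17 stimuli x
    10 trials x 2 blocks x 2 implementations per participant, a 470 ms
    App delay, median reaction times between roughly 0.4 and 0.9 s with
    reciprobit slopes around sigma_p/mu_p = 0.3, occasional lapses and
    slow Poisson false positives, and a latent trait that speeds responses
    to trait-loaded stimuli and lowers the speech-reception threshold.
    """

    n_participants: int = 20
    n_trials_per_stimulus: int = 10
    n_blocks: int = 2
    implementations: tuple[str, ...] = ("App", "Laptop")
    implementation_delay_s: float = 0.470
    #: median RT (s) per stimulus for a trait = 0 listener; unlisted stimuli
    #: fall back to `default_median_rt_s`
    median_rt_s: dict[str, float] = field(
        default_factory=lambda: {
            "bb_4Hz_0.5co": 0.42,
            "bb_8Hz_0co": 0.45,
            "bb_16Hz_0.25co": 0.48,
            "bb_4Hz_0co": 0.50,
            "bb_8Hz_0.5co": 0.50,
            "bb_0Hz_0.5co": 0.60,
            "bb_4Hz_1co": 0.55,
            "bb_8Hz_1co": 0.60,
            "bb_0Hz_0.25co": 0.65,
            "bb_0Hz_1co": 0.70,
            "bb_4Hz_2co": 0.70,
            "bb_0Hz_2co": 0.85,
            "nb_4Hz_2co_500": 0.90,
            "nb_4Hz_2co_1000": 0.80,
            "nb_4Hz_2co_2000": 0.75,
            "nb_4Hz_2co_4000": 0.70,
        }
    )
    default_median_rt_s: float = 0.6
    sigma_frac: float = 0.3  # sigma_p / mu_p
    lapse_rate: float = 0.03
    fp_rate_hz: float = 0.02
    #: trait loading on log promptness; unlisted non-catch stimuli use
    #: `default_trait_loading`
    trait_loading: dict[str, float] = field(
        default_factory=lambda: {
            **{s: 0.35 for s in SPEECH_RELEVANT_STIMULI},
            "bb_8Hz_0co": 0.0,  # configured trait-independent
        }
    )
    default_trait_loading: float = 0.2
    participant_jitter_sd: float = 0.15  # per-(participant, stimulus) log-mu_p noise
    age_mean: float = 55.0
    age_sd: float = 12.0
    #: speech-reception-threshold link: srt = b_trait*trait + b_age*z(age) + noise
    srt_b_trait: float = -1.5
    srt_b_age: float = 0.5
    srt_noise_sd: float = 0.8
    srt_intercept_db: float = 0.0


def simulate_later_rts(
    params: LATERParams, n: int, seed: int | np.random.Generator | None = None
) -> np.ndarray:
    """Draw ``n`` LATER reaction times (s); lapses are returned as NaN.

    Promptness is drawn from Normal(mu_p, sigma_p) truncated to positive
    values; RT = 1/promptness.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = rng.normal(params.mu_p, params.sigma_p, size=n)
    while True:  # truncate to p > 0 by redrawing
        bad = p <= 0
        if not bad.any():
            break
        p[bad] = rng.normal(params.mu_p, params.sigma_p, size=int(bad.sum()))
    rt = 1.0 / p
    lapse = rng.random(n) < params.lapse_rate
    rt[lapse] = np.nan
    return rt


def link_srt(
    trait: float,
    z_age: float,
    coeffs: tuple[float, float, float],
    rng: np.random.Generator | None = None,
    intercept: float = 0.0,
) -> float:
    """True 50% speech-reception threshold (dB SNR) from the latent trait.

    ``srt = intercept + b_trait*trait + b_age*z_age + Normal(0, noise_sd)``;
    a negative ``b_trait`` makes sensitive listeners (high trait) better
    (lower SRT).
    """
    b_trait, b_age, noise_sd = coeffs
    eps = 0.0 if noise_sd == 0 else float((rng or np.random.default_rng()).normal(0, noise_sd))
    return intercept + b_trait * trait + b_age * z_age + eps


def make_profiles(
    config: CohortConfig, seed: int | None = None, specs: list[RippleSpec] | None = None
) -> list[ParticipantProfile]:
    """Draw participant profiles (trait, age, per-stimulus LATER params, SRT)."""
    rng = np.random.default_rng(seed)
    specs = specs if specs is not None else build_stimulus_table()
    profiles = []
    ages = rng.normal(config.age_mean, config.age_sd, size=config.n_participants)
    z_age = (ages - np.mean(ages)) / (np.std(ages) if config.n_participants > 1 else 1.0)
    for i in range(config.n_participants):
        trait = float(rng.standard_normal())
        later: dict[str, LATERParams] = {}
        for spec in specs:
            sid = spec.stimulus_id
            if spec.band_kind == "catch":
                # catch trials have no ripple onset: the LATER unit never
                # fires; the params entry only feeds the FP/lapse machinery
                later[sid] = LATERParams(
                    mu_p=1.0,  # unused on catch trials
                    sigma_p=0.1,
                    lapse_rate=1.0,
                    fp_rate_hz=config.fp_rate_hz,
                )
                continue
            base_rt = config.median_rt_s.get(sid, config.default_median_rt_s)
            loading = config.trait_loading.get(sid, config.default_trait_loading)
            jitter = rng.normal(0.0, config.participant_jitter_sd)
            mu_p = (1.0 / base_rt) * np.exp(loading * trait + jitter)
            later[sid] = LATERParams(
                mu_p=float(mu_p),
                sigma_p=float(config.sigma_frac * mu_p),
                lapse_rate=config.lapse_rate,
                fp_rate_hz=config.fp_rate_hz,
            )
        srt = link_srt(
            trait,
            float(z_age[i]),
            (config.srt_b_trait, config.srt_b_age, config.srt_noise_sd),
            rng,
            intercept=config.srt_intercept_db,
        )
        profiles.append(
            ParticipantProfile(
                id=f"S{i + 1:02d}",
                age_years=float(ages[i]),
                trait=trait,
                later=later,
                srt_true_db=srt,
                implementation_delay_s=config.implementation_delay_s,
            )
        )
    return profiles


def _simulate_one_trial(
    params: LATERParams,
    is_catch: bool,
    onset_s: float,
    rng: np.random.Generator,
    max_reiterations: int = 100,
) -> tuple[float, bool, int]:
    """One trial: returns (rt_from_onset or NaN, responded, n_premature).

    A Poisson false-positive process runs from noise onset and races the
    LATER response; an FP before modulation onset makes the trial premature
    and it is reiterated.
    """
    n_premature = 0
    for _ in range(max_reiterations):
        # first false-positive arrival from noise onset
        fp_t = rng.exponential(1.0 / params.fp_rate_hz) if params.fp_rate_hz > 0 else np.inf
        if fp_t < onset_s:
            n_premature += 1
            continue
        if is_catch:
            later_t = np.inf
        else:
            rt = simulate_later_rts(params, 1, rng)[0]
            later_t = np.inf if np.isnan(rt) else onset_s + rt
        winner = min(later_t, fp_t)
        if winner - onset_s > RESPONSE_WINDOW_S or np.isinf(winner):
            return np.nan, False, n_premature
        return winner - onset_s, True, n_premature
    return np.nan, False, n_premature


def simulate_cohort(
    config: CohortConfig | None = None,
    seed: int | None = None,
    profiles: list[ParticipantProfile] | None = None,
) -> tuple[list[ParticipantProfile], pd.DataFrame]:
    """Simulate the full cohort trial table.

    For each participant x implementation x block, 10 trials of each of the
    17 stimuli are presented in pseudorandom order.  App reaction times have
    the configured technical delay added.  One root seed spawns independent
    per-participant streams.
    """
    config = config or CohortConfig()
    root = np.random.SeedSequence(seed)
    profile_seed, trial_seed = root.spawn(2)
    specs = build_stimulus_table()
    spec_by_id = {s.stimulus_id: s for s in specs}
    if profiles is None:
        profiles = make_profiles(config, profile_seed.generate_state(1)[0] % 2**31, specs)
    rows = []
    streams = trial_seed.spawn(len(profiles))
    for profile, stream in zip(profiles, streams):
        rng = np.random.default_rng(stream)
        for impl in config.implementations:
            for block in range(1, config.n_blocks + 1):
                order = np.repeat(list(spec_by_id), config.n_trials_per_stimulus)
                rng.shuffle(order)
                for sid in order:
                    spec = spec_by_id[sid]
                    onset = float(rng.choice(ONSET_GRID_S))
                    rt, responded, n_pre = _simulate_one_trial(
                        profile.later[sid], spec.band_kind == "catch", onset, rng
                    )
                    if responded and impl == "App":
                        rt = rt + profile.implementation_delay_s
                    rows.append(
                        (profile.id, impl, sid, block, onset, rt, responded, n_pre)
                    )
    records = pd.DataFrame(
        rows,
        columns=[
            "participant",
            "implementation",
            "stimulus_id",
            "block",
            "onset_s",
            "rt_raw_s",
            "responded",
            "n_premature",
        ],
    )
    return profiles, records


def profiles_to_frame(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Per-participant summary table (id, age, trait, true SRT, delay)."""
    return pd.DataFrame(
        {
            "participant": [p.id for p in profiles],
            "age_years": [p.age_years for p in profiles],
            "trait": [p.trait for p in profiles],
            "srt_true_db": [p.srt_true_db for p in profiles],
            "implementation_delay_s": [p.implementation_delay_s for p in profiles],
        }
    )
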