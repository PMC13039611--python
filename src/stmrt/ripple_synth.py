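"""Synthesis of calibrated spectrotemporal ripple-in-noise stimuli.

A ripple stimulus is a pink-noise carrier (0.1-8.7 kHz) whose spectrogram is
modulated sinusoidally along time (rate ``w`` in Hz) and log-frequency
(density ``omega`` in cycles/octave) inside a target band.  The target band is
additionally accentuated by a fixed spectral gain (default +15 dB) for the
full stimulus duration, and the out-of-band noise is calibrated to a fixed
sound-pressure level (60 dB SPL).  Modulation starts without ramp at a
randomized onset between 0.7 and 1.2 s and lasts at most 3 s.

The spectrotemporal gain is imposed multiplicatively in the short-time
Fourier domain (square-root Hann analysis windows, 75% overlap, ~46 ms at
44.1 kHz), which gives exact control of the target envelope
``g(f, t) = 1 + depth * sin(2*pi*(w*(t - onset) + omega*log2(f/f_lo)) + phase0)``
and perfect reconstruction at unity gain.  Band accentuation, being
time-invariant, is applied as a zero-phase spectral gain with raised-cosine
(Hanning) edges of 100 Hz width in linear frequency.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import ShortTimeFFT, butter, freqz, hilbert, lfilter, welch
from scipy.signal.windows import hann

__all__ = [
    "RippleSpec",
    "TrialAudio",
    "CalibrationModel",
    "make_pink_noise",
    "apply_stm",
    "apply_accentuation",
    "assemble_trial",
    "make_accentuated_carrier",
    "build_stimulus_table",
    "agc_standin",
    "measure_level_dbspl",
    "calibrate_carrier",
    "measure_accent_gain_db",
    "estimate_temporal_depth",
    "estimate_envelope_rate",
    "estimate_spectral_density",
    "write_trial_wav",
    "ONSET_GRID_S",
]

#: allowed modulation onsets (s), randomized in 100 ms steps
ONSET_GRID_S = (0.7, 0.8, 0.9, 1.0, 1.1, 1.2)

#: maximum duration of the modulated segment (s)
MAX_MODULATION_S = 3.0

#: pink-noise carrier band (Hz)
CARRIER_BAND_HZ = (100.0, 8700.0)

DEFAULT_SR = 44100
DEFAULT_DEPTH = 0.82
DEFAULT_ACCENT_DB = 15.0
STFT_NPERSEG = 2048  # ~46 ms at 44.1 kHz
NARROWBAND_CENTERS_HZ = (500.0, 1000.0, 2000.0, 4000.0)


class InvalidConfigurationError(ValueError):
    """Raised for stimulus parameters outside the supported design."""


@dataclass(frozen=True)
class RippleSpec:
    """One stimulus condition of the ripple test.

    Parameters
    ----------
    band_kind : {"broadband", "narrowband", "catch"}
        Catch stimuli are processed identically but carry zero modulation.
    f_lo, f_hi : float
        Edges of the modulated/accentuated band in Hz.  Broadband spans
        250-8000 Hz; narrowband spans one octave around a center frequency.
    omega : float
        Spectral modulation density in cycles/octave (>= 0).
    rate_hz : float
        Temporal modulation rate in Hz (>= 0).
    depth : float
        Modulation depth ``m`` in ``1 + m*sin`` on a linear amplitude scale.
    accent_db : float
        Spectral accentuation of the band relative to the surrounding noise.
    phase0 : float
        Starting phase of the ripple in radians (0 at ``f_lo``, onset time).
    omega_sign : {+1, -1}
        Drift direction convention; +1 means the ripple phase increases with
        ``log2(f/f_lo)`` (downward drift for positive rate and density).
    """

    band_kind: str
    f_lo: float
    f_hi: float
    omega: float
    rate_hz: float
    depth: float = DEFAULT_DEPTH
    accent_db: float = DEFAULT_ACCENT_DB
    phase0: float = 0.0
    omega_sign: int = 1

    def __post_init__(self) -> None:
        if self.band_kind not in ("broadband", "narrowband", "catch"):
            raise InvalidConfigurationError(f"unknown band_kind {self.band_kind!r}")
        if not 0.0 <= self.depth <= 1.0:
            raise InvalidConfigurationError(f"depth must be in [0, 1], got {self.depth}")
        if self.omega < 0 or self.rate_hz < 0:
            raise InvalidConfigurationError("omega and rate_hz must be >= 0")
        if self.f_lo <= 0 or self.f_hi <= self.f_lo:
            raise InvalidConfigurationError("need 0 < f_lo < f_hi")
        if self.band_kind == "narrowband":
            if abs(self.f_hi / self.f_lo - 2.0) > 1e-9 * 2.0:
                raise InvalidConfigurationError("narrowband span must be exactly one octave")
        if self.band_kind == "catch" and (self.omega != 0 or self.rate_hz != 0):
            raise InvalidConfigurationError("catch stimulus must have omega = rate = 0")
        if self.omega_sign not in (-1, 1):
            raise InvalidConfigurationError("omega_sign must be +1 or -1")

    @property
    def cf_hz(self) -> float:
        """Geometric center frequency of the modulated band."""
        return float(np.sqrt(self.f_lo * self.f_hi))

    @property
    def stimulus_id(self) -> str:
        """Stable key, e.g. ``bb_4Hz_0.5co`` or ``nb_4Hz_2co_1000``."""

        def num(x: float) -> str:
            return f"{x:g}"

        if self.band_kind == "catch":
            return "catch_0Hz_0co"
        if self.band_kind == "narrowband":
            return f"nb_{num(self.rate_hz)}Hz_{num(self.omega)}co_{num(round(self.cf_hz))}"
        return f"bb_{num(self.rate_hz)}Hz_{num(self.omega)}co"

    def to_dict(self) -> dict:
        return {
            "band_kind": self.band_kind,
            "f_lo": self.f_lo,
            "f_hi": self.f_hi,
            "omega": self.omega,
            "rate_hz": self.rate_hz,
            "depth": self.depth,
            "accent_db": self.accent_db,
            "phase0": self.phase0,
            "omega_sign": self.omega_sign,
        }


def broadband_spec(rate_hz: float, omega: float, **kw) -> RippleSpec:
    kind = "catch" if rate_hz == 0 and omega == 0 else "broadband"
    return RippleSpec(kind, 250.0, 8000.0, omega, rate_hz, **kw)


def narrowband_spec(cf_hz: float, rate_hz: float = 4.0, omega: float = 2.0, **kw) -> RippleSpec:
    half = np.sqrt(2.0)
    return RippleSpec("narrowband", cf_hz / half, cf_hz * half, omega, rate_hz, **kw)


@dataclass
class TrialAudio:
    """Audio buffer plus the metadata needed to reproduce it."""

    samples: np.ndarray
    sample_rate_hz: float
    onset_s: float | None = None
    total_duration_s: float = 0.0
    spec: RippleSpec | None = None
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.total_duration_s = len(self.samples) / self.sample_rate_hz

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate_hz

    def copy_with(self, samples: np.ndarray) -> "TrialAudio":
        return TrialAudio(
            samples=samples,
            sample_rate_hz=self.sample_rate_hz,
            onset_s=self.onset_s,
            spec=self.spec,
            noise_seed=self.noise_seed,
        )


@dataclass(frozen=True)
class CalibrationModel:
    """Maps digital RMS to sound pressure level.

    A full-scale sinusoid (peak 1, RMS 1/sqrt(2)) measures
    ``dbspl_at_fullscale`` dB SPL.
    """

    dbspl_at_fullscale: float = 94.0

    def rms_to_dbspl(self, rms: float) -> float:
        if rms <= 0:
            return -np.inf
        return self.dbspl_at_fullscale + 20.0 * np.log10(rms * np.sqrt(2.0))

    def dbspl_to_rms(self, dbspl: float) -> float:
        return 10.0 ** ((dbspl - self.dbspl_at_fullscale) / 20.0) / np.sqrt(2.0)


# ---------------------------------------------------------------------------
# carrier


def make_pink_noise(
    duration_s: float,
    sample_rate_hz: float = DEFAULT_SR,
    band: tuple[float, float] = CARRIER_BAND_HZ,
    seed: int | None = None,
) -> TrialAudio:
    """Pink-noise carrier, band-passed with a first-order Butterworth filter.

    Pink (1/f power) noise is produced by spectral shaping of seeded white
    Gaussian noise (amplitude proportional to ``1/sqrt(f)``), after which a
    causal first-order Butterworth bandpass with edges at ``band`` is applied
    once.  Deterministic for a fixed seed.
    """
    if duration_s <= 0:
        raise InvalidConfigurationError("duration_s must be positive")
    nyq = sample_rate_hz / 2.0
    if band[1] >= nyq or band[0] <= 0:
        raise InvalidConfigurationError(f"band {band} outside (0, Nyquist={nyq}) Hz")
    n = int(round(duration_s * sample_rate_hz))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / sample_rate_hz)
    shaping = np.zeros_like(f)
    shaping[1:] = 1.0 / np.sqrt(f[1:])  # power ~ 1/f; DC removed
    x = np.fft.irfft(spectrum * shaping, n=n)
    b, a = butter(1, band, btype="bandpass", fs=sample_rate_hz)
    x = lfilter(b, a, x)
    x = x / np.sqrt(np.mean(x**2))  # unit RMS; calibration rescales later
    return TrialAudio(samples=x, sample_rate_hz=sample_rate_hz, noise_seed=seed)


# ---------------------------------------------------------------------------
# spectrotemporal gain machinery


def _stft_transform(fs: float, nperseg: int = STFT_NPERSEG) -> ShortTimeFFT:
    win = np.sqrt(hann(nperseg, sym=False))
    return ShortTimeFFT(win, hop=nperseg // 4, fs=fs, fft_mode="onesided")

def _apply_tf_gain(x: np.ndarray, fs: float, gain_fn) -> np.ndarray:
    """Multiply the STFT of ``x`` by ``gain_fn(f, t) -> (n_f, n_t)`` and resynthesize."""
    sft = _stft_transform(fs)
    S = sft.stft(x)
    t_frames = sft.t(len(x))[: S.shape[1]]
    gain = gain_fn(sft.f, t_frames)
    y = sft.istft(S * gain, k1=len(x))
    return y[: len(x)]


def ripple_gain(
    spec: RippleSpec, f: np.ndarray, t: np.ndarray, onset_s: float
) -> np.ndarray:
    """Target spectrotemporal envelope ``g(f, t)`` on a linear amplitude scale.

    Unity before onset and outside the modulated band; inside,
    ``1 + depth*sin(2*pi*(w*(t-onset) + sign*omega*log2(f/f_lo)) + phase0)``
    with no onset ramp.
    """
    f = np.asarray(f, float)[:, None]
    t = np.asarray(t, float)[None, :]
    in_band = (f >= spec.f_lo) & (f <= spec.f_hi)
    after = t >= onset_s
    with np.errstate(divide="ignore"):
        logf = np.where(f > 0, np.log2(np.maximum(f, 1e-12) / spec.f_lo), 0.0)
    phase = (
        2.0 * np.pi * (spec.rate_hz * (t - onset_s) + spec.omega_sign * spec.omega * logf)
        + spec.phase0
    )
    g = 1.0 + spec.depth * np.sin(phase)
    return np.where(in_band & after, g, 1.0)


def apply_stm(carrier: TrialAudio, spec: RippleSpec, onset_s: float) -> TrialAudio:
    """Impose the sinusoidal spectrotemporal modulation from ``onset_s`` on.

    The modulation commences instantaneously (no ramp) with starting phase
    ``spec.phase0`` at the band's lower edge, applied on a linear amplitude
    scale in the short-time Fourier domain.
    """
    if spec.depth > 1.0:
        raise InvalidConfigurationError("depth > 1 would produce negative gain")
    if onset_s < 0 or onset_s > carrier.total_duration_s:
        raise InvalidConfigurationError("onset outside the carrier")
    y = _apply_tf_gain(
        carrier.samples,
        carrier.sample_rate_hz,
        lambda f, t: ripple_gain(spec, f, t, onset_s),
    )
    out = carrier.copy_with(y)
    out.onset_s = onset_s
    out.spec = spec
    return out


def _accent_gain_profile(
    f: np.ndarray, f_lo: float, f_hi: float, accent_db: float, edge_width_hz: float
) -> np.ndarray:
    """dB gain vs frequency: flat accent inside, Hanning (raised-cosine) edges.

    The ramp is centered on each band edge, so the gain at exactly ``f_lo``
    or ``f_hi`` is ``accent_db/2``.
    """
    half = edge_width_hz / 2.0
    gain_db = np.zeros_like(f, dtype=float)
    rising = np.clip((f - (f_lo - half)) / edge_width_hz, 0.0, 1.0)
    falling = np.clip(((f_hi + half) - f) / edge_width_hz, 0.0, 1.0)
    ramp_up = 0.5 - 0.5 * np.cos(np.pi * rising)
    ramp_down = 0.5 - 0.5 * np.cos(np.pi * falling)
    gain_db = accent_db * np.minimum(ramp_up, ramp_down)
    return gain_db


def apply_accentuation(
    buffer: TrialAudio,
    f_lo: float,
    f_hi: float,
    accent_db: float = DEFAULT_ACCENT_DB,
    edge_width_hz: float = 100.0,
) -> TrialAudio:
    """Boost the band ``[f_lo, f_hi]`` by ``accent_db`` for the full duration.

    Edges are smoothed with a raised-cosine (Hanning) profile of width
    ``edge_width_hz`` in linear frequency; the gain is applied as a
    zero-phase spectral multiplication.
    """
    if f_lo >= f_hi:
        raise InvalidConfigurationError("f_lo must be below f_hi")
    if edge_width_hz <= 0:
        raise InvalidConfigurationError("edge_width_hz must be positive")
    if f_hi - f_lo < edge_width_hz:
        raise InvalidConfigurationError("accentuation band narrower than the edge ramp")
    x = buffer.samples
    n = len(x)
    f = np.fft.rfftfreq(n, 1.0 / buffer.sample_rate_hz)
    gain = 10.0 ** (_accent_gain_profile(f, f_lo, f_hi, accent_db, edge_width_hz) / 20.0)
    y = np.fft.irfft(np.fft.rfft(x) * gain, n=n)
    return buffer.copy_with(y)


# ---------------------------------------------------------------------------
# levels and calibration


def measure_level_dbspl(
    buffer: TrialAudio,
    calibration: CalibrationModel,
    window: tuple[float, float] | None = None,
    band: tuple[float, float] | None = None,
) -> float:
    """RMS level in dB SPL over a time window, optionally band-limited."""
    fs = buffer.sample_rate_hz
    x = buffer.samples
    if window is not None:
        i0, i1 = (int(round(w * fs)) for w in window)
        if not 0 <= i0 < i1 <= len(x):
            raise ValueError(f"window {window} outside buffer")
        x = x[i0:i1]
    if len(x) == 0:
        raise ValueError("empty measurement window")
    if band is not None:
        n = len(x)
        f = np.fft.rfftfreq(n, 1.0 / fs)
        spec = np.fft.rfft(x)
        spec[(f < band[0]) | (f > band[1])] = 0.0
        x = np.fft.irfft(spec, n=n)
    return calibration.rms_to_dbspl(float(np.sqrt(np.mean(x**2))))


def calibrate_carrier(
    carrier: TrialAudio,
    calibration: CalibrationModel,
    target_dbspl: float = 60.0,
    band: tuple[float, float] = CARRIER_BAND_HZ,
) -> TrialAudio:
    """Scale the (unaccented) carrier so its in-band level is ``target_dbspl``.

    The reference is the carrier's power inside its nominal passband
    (0.1-8.7 kHz); the gentle first-order Butterworth skirts leave some power
    outside it, which is excluded from the calibration reference.  The noise
    outside the modulated band of the final stimulus then sits at this level,
    since accentuation leaves it untouched.
    """
    fs = carrier.sample_rate_hz
    n = len(carrier.samples)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec = np.fft.rfft(carrier.samples)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    band_rms = float(np.sqrt(np.mean(np.fft.irfft(spec, n=n) ** 2)))
    scale = calibration.dbspl_to_rms(target_dbspl) / band_rms
    return carrier.copy_with(carrier.samples * scale)


def draw_onset(seed: int | None) -> float:
    rng = np.random.default_rng(seed)
    return float(rng.choice(ONSET_GRID_S))


def make_accentuated_carrier(
    spec: RippleSpec,
    calibration: CalibrationModel,
    duration_s: float,
    seed: int | None = None,
    noise_level_dbspl: float = 60.0,
) -> TrialAudio:
    """Calibrated, accentuated carrier without modulation (any duration).

    This is the stimulus up to (and, for the catch condition, beyond) the
    modulation onset; used for level verification and as the substrate for
    :func:`apply_stm`.
    """
    carrier = make_pink_noise(duration_s, DEFAULT_SR, CARRIER_BAND_HZ, seed)
    carrier = calibrate_carrier(carrier, calibration, noise_level_dbspl)
    out = apply_accentuation(carrier, spec.f_lo, spec.f_hi, spec.accent_db)
    out.spec = spec
    return out


def assemble_trial(
    spec: RippleSpec,
    calibration: CalibrationModel | None = None,
    seed: int | None = None,
    onset_s: float | None = None,
    modulation_s: float = MAX_MODULATION_S,
) -> TrialAudio:
    """Full synthesis pipeline for one trial.

    Pink noise -> 60 dB SPL calibration -> band accentuation (full duration)
    -> spectrotemporal modulation from a randomized onset (0.7-1.2 s in
    100 ms steps) for at most 3 s.  Deterministic for fixed (spec, seed,
    calibration).
    """
    if calibration is None:
        calibration = CalibrationModel()
    if modulation_s > MAX_MODULATION_S:
        raise InvalidConfigurationError("modulated segment exceeds 3 s maximum")
    if onset_s is None:
        onset_s = draw_onset(seed)
    elif onset_s not in ONSET_GRID_S:
        raise InvalidConfigurationError(f"onset_s must be one of {ONSET_GRID_S}")
    duration = onset_s + modulation_s
    out = make_accentuated_carrier(spec, calibration, duration, seed)
    out = apply_stm(out, spec, onset_s)
    peak = float(np.max(np.abs(out.samples)))
    if peak > 1.0:
        raise InvalidConfigurationError(
            f"calibration leaves no headroom: peak {peak:.3f} exceeds full scale"
        )
    out.noise_seed = seed
    return out


def agc_standin(
    buffer: TrialAudio,
    gain_reduction_db: float,
    attack_delay_s: float = 0.4,
    ramp_s: float = 0.1,
) -> TrialAudio:
    """Generic automatic-gain-control stand-in.

    A single-band feed-forward gain trajectory: unity until
    ``attack_delay_s``, then a raised-cosine transition of ``ramp_s`` to a
    steady-state attenuation of ``gain_reduction_db``.  Fully engaged well
    before the earliest modulation onset (0.7 s), so the level is stable when
    the ripple starts.
    """
    if attack_delay_s < 0:
        raise InvalidConfigurationError("attack_delay_s must be >= 0")
    t = buffer.t
    s = np.clip((t - attack_delay_s) / max(ramp_s, 1e-9), 0.0, 1.0)
    engage = 0.5 - 0.5 * np.cos(np.pi * s)
    gain = 10.0 ** (-gain_reduction_db * engage / 20.0)
    return buffer.copy_with(buffer.samples * gain)


# ---------------------------------------------------------------------------
# the canonical stimulus set


def build_stimulus_table() -> list[RippleSpec]:
    """The 17 canonical stimulus conditions.

    Four 1-octave narrowband ripples at [4 Hz, 2 c/o] centered at 500, 1000,
    2000 and 4000 Hz; twelve broadband combinations
    ([0 Hz] x {2, 1, 0.5, 0.25 c/o}, [4 Hz] x {2, 1, 0.5, 0 c/o},
    [8 Hz] x {1, 0.5, 0 c/o}, [16 Hz] x {0.25 c/o}); and one broadband catch
    stimulus [0 Hz, 0 c/o].
    """
    specs = [narrowband_spec(cf) for cf in NARROWBAND_CENTERS_HZ]
    broadband_grid = {
        0.0: (2.0, 1.0, 0.5, 0.25),
        4.0: (2.0, 1.0, 0.5, 0.0),
        8.0: (1.0, 0.5, 0.0),
        16.0: (0.25,),
    }
    for rate, omegas in broadband_grid.items():
        for om in omegas:
            specs.append(broadband_spec(rate, om))
    specs.append(broadband_spec(0.0, 0.0))  # catch
    assert len(specs) == 17
    return specs


# ---------------------------------------------------------------------------
# acoustic verification oracles


def carrier_psd_model(
    f: np.ndarray,
    band: tuple[float, float] = CARRIER_BAND_HZ,
    sample_rate_hz: float = DEFAULT_SR,
) -> np.ndarray:
    """Unnormalized PSD of the ideal carrier: 1/f pink slope times the
    squared magnitude response of the first-order Butterworth bandpass."""
    f = np.asarray(f, float)
    b, a = butter(1, band, btype="bandpass", fs=sample_rate_hz)
    _, h = freqz(b, a, worN=np.maximum(f, 1e-6), fs=sample_rate_hz)
    return np.abs(h) ** 2 / np.maximum(f, 1e-6)


def measure_accent_gain_db(
    buffer: TrialAudio,
    in_band: tuple[float, float],
    ref_band: tuple[float, float],
    nperseg: int = 8192,
) -> float:
    """In-band vs reference-band accent gain from a slope-compensated PSD.

    The Welch PSD is divided by the carrier's spectral model (pink 1/f slope
    shaped by the first-order Butterworth bandpass), flattening the carrier;
    the dB difference of the compensated means inside ``in_band`` and
    ``ref_band`` then estimates the applied accentuation.
    """
    f, pxx = welch(buffer.samples, fs=buffer.sample_rate_hz, nperseg=nperseg)
    comp = np.zeros_like(pxx)
    pos = f > 0
    comp[pos] = pxx[pos] / carrier_psd_model(f[pos])
    sel_in = (f >= in_band[0]) & (f <= in_band[1])
    sel_ref = (f >= ref_band[0]) & (f <= ref_band[1])
    return 10.0 * float(np.log10(np.mean(comp[sel_in]) / np.mean(comp[sel_ref])))


def _band_envelope(buffer: TrialAudio, band: tuple[float, float]) -> np.ndarray:
    n = len(buffer.samples)
    f = np.fft.rfftfreq(n, 1.0 / buffer.sample_rate_hz)
    spec = np.fft.rfft(buffer.samples)
    spec[(f < band[0]) | (f > band[1])] = 0.0
    return np.abs(hilbert(np.fft.irfft(spec, n=n)))


def estimate_temporal_depth(
    buffer: TrialAudio,
    spec: RippleSpec,
    onset_s: float,
    n_phase_bins: int = 48,
    guard_s: float = 0.25,
) -> float:
    """Modulation depth from the period-averaged band-limited envelope.

    The Hilbert envelope of the band-filtered signal is folded at the
    modulation period; depth = (max - min) / (max + min) of the per-phase-bin
    mean envelope, in [0, 1].  Only valid for purely temporal ripples
    (``omega = 0``, ``rate_hz > 0``).
    """
    if spec.rate_hz <= 0:
        raise ValueError("temporal depth requires rate_hz > 0")
    env = _band_envelope(buffer, (spec.f_lo, spec.f_hi))
    t = buffer.t
    sel = t >= onset_s + guard_s
    period = 1.0 / spec.rate_hz
    phase = ((t[sel] - onset_s) % period) / period
    bins = np.minimum((phase * n_phase_bins).astype(int), n_phase_bins - 1)
    mean_env = np.bincount(bins, weights=env[sel], minlength=n_phase_bins)
    mean_env /= np.bincount(bins, minlength=n_phase_bins)
    return float((mean_env.max() - mean_env.min()) / (mean_env.max() + mean_env.min()))


def estimate_envelope_rate(
    buffer: TrialAudio, spec: RippleSpec, onset_s: float, guard_s: float = 0.25
) -> float:
    """Dominant temporal modulation frequency (Hz) of the in-band envelope."""
    env = _band_envelope(buffer, (spec.f_lo, spec.f_hi))
    sel = buffer.t >= onset_s + guard_s
    env = env[sel] - np.mean(env[sel])
    n = len(env)
    spec_mag = np.abs(np.fft.rfft(env * hann(n)))
    f = np.fft.rfftfreq(n, 1.0 / buffer.sample_rate_hz)
    keep = (f > 0.3) & (f < 64.0)
    return float(f[keep][np.argmax(spec_mag[keep])])


def estimate_spectral_density(
    buffer: TrialAudio,
    spec: RippleSpec,
    onset_s: float,
    n_logf: int = 512,
    nperseg: int = 8192,
) -> float:
    """Dominant spectral ripple density (cycles/octave) of the log-spectrum.

    The time-averaged Welch PSD after onset is sampled on a uniform
    ``log2(f/f_lo)`` grid inside the modulated band, detrended, and the peak
    of its spatial Fourier transform located.  Only meaningful for
    ``omega > 0``.
    """
    fs = buffer.sample_rate_hz
    i0 = int(round(onset_s * fs))
    f, pxx = welch(buffer.samples[i0:], fs=fs, nperseg=nperseg)
    sel = (f >= spec.f_lo) & (f <= spec.f_hi)
    logf = np.log2(f[sel] / spec.f_lo)
    prof = 10.0 * np.log10(pxx[sel])
    grid = np.linspace(logf.min(), logf.max(), n_logf)
    prof_i = np.interp(grid, logf, prof)
    prof_i -= np.polyval(np.polyfit(grid, prof_i, 1), grid)  # remove pink slope
    dx = grid[1] - grid[0]
    n_fft = n_logf * 16  # zero-pad: peak location finer than the 1/span grid
    mag = np.abs(np.fft.rfft(prof_i * hann(n_logf), n=n_fft))
    dens = np.fft.rfftfreq(n_fft, dx)
    keep = dens > 0.05
    return float(dens[keep][np.argmax(mag[keep])])


# ---------------------------------------------------------------------------
# file output


def write_trial_wav(trial: TrialAudio, path: str | Path, calibration: CalibrationModel | None = None) -> Path:
    """Write 16-bit PCM WAV plus a JSON sidecar with the trial metadata."""
    path = Path(path)
    x = np.clip(trial.samples, -1.0, 1.0)
    wavfile.write(path, int(trial.sample_rate_hz), (x * 32767).astype(np.int16))
    meta = {
        "spec": trial.spec.to_dict() if trial.spec else None,
        "stimulus_id": trial.spec.stimulus_id if trial.spec else None,
        "onset_s": trial.onset_s,
        "seed": trial.noise_seed,
        "sample_rate_hz": trial.sample_rate_hz,
        "calibration": (
            {"dbspl_at_fullscale": calibration.dbspl_at_fullscale} if calibration else None
        ),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path
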