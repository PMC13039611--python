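"""Acoustic properties of the synthesized ripple-in-noise stimuli."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.signal import welch

from stmrt import ripple_synth as rs


class TestPinkNoiseCarrier:
    def test_deterministic_for_fixed_seed(self):
        a = rs.make_pink_noise(1.0, seed=1)
        b = rs.make_pink_noise(1.0, seed=1)
        assert np.array_equal(a.samples, b.samples)
        c = rs.make_pink_noise(1.0, seed=2)
        assert not np.array_equal(a.samples, c.samples)

    def test_psd_slope_is_pink(self):
        """~-3 dB/octave within the passband (log-log linear fit, 0.3-6 kHz)."""
        noise = rs.make_pink_noise(60.0, seed=5)
        f, pxx = welch(noise.samples, fs=noise.sample_rate_hz, nperseg=16384)
        grid = np.logspace(np.log10(300), np.log10(6000), 60)
        slope = np.polyfit(np.log2(grid), 10 * np.log10(np.interp(grid, f, pxx)), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.3)

    def test_band_power_fraction_matches_analytic_oracle(self):
        """Measured 250-8000 vs 100-8700 Hz band power equals the integral of
        the 1/f x |H_butterworth|^2 spectral model."""
        num = quad(lambda fq: rs.carrier_psd_model(np.array([fq]))[0], 250, 8000, limit=200)[0]
        den = quad(lambda fq: rs.carrier_psd_model(np.array([fq]))[0], 100, 8700, limit=200)[0]
        noise = rs.make_pink_noise(60.0, seed=5)
        power = np.abs(np.fft.rfft(noise.samples)) ** 2
        f = np.fft.rfftfreq(len(noise.samples), 1.0 / noise.sample_rate_hz)
        measured = power[(f >= 250) & (f < 8000)].sum() / power[(f >= 100) & (f < 8700)].sum()
        assert measured == pytest.approx(num / den, abs=0.03)

    def test_band_edge_beyond_nyquist_rejected(self):
        with pytest.raises(rs.InvalidConfigurationError):
            rs.make_pink_noise(1.0, sample_rate_hz=16000, band=(100, 8700), seed=0)


class TestSpectrotemporalModulation:
    def test_zero_depth_is_identity(self, broadband_carrier_10s):
        """Analysis/synthesis at unity gain reconstructs below -40 dB residual."""
        _, carrier = broadband_carrier_10s
        spec = rs.RippleSpec("broadband", 250.0, 8000.0, 0.5, 4.0, depth=0.0)
        out = rs.apply_stm(carrier, spec, 0.5)
        resid_db = 10 * np.log10(
            np.mean((out.samples - carrier.samples) ** 2) / np.mean(carrier.samples**2)
        )
        assert resid_db < -40

    def test_temporal_rate_imposed(self, broadband_carrier_10s):
        """Purely temporal 4 Hz ripple: envelope periodicity at 4.00 +/- 0.05 Hz."""
        spec, carrier = broadband_carrier_10s
        out = rs.apply_stm(carrier, spec, 0.5)
        assert rs.estimate_envelope_rate(out, spec, 0.5) == pytest.approx(4.0, abs=0.05)

    @pytest.mark.parametrize("omega", [0.5, 2.0])
    def test_spectral_density_imposed(self, calibration, omega):
        """Purely spectral ripple: log-spectral profile periodic at omega c/o."""
        spec = rs.broadband_spec(0.0, omega)
        carrier = rs.make_accentuated_carrier(spec, calibration, 10.0, seed=3)
        out = rs.apply_stm(carrier, spec, 0.5)
        assert rs.estimate_spectral_density(out, spec, 0.5) == pytest.approx(omega, abs=0.06 * max(1.0, omega))

    def test_modulation_depth_recovered(self, broadband_carrier_10s):
        spec, carrier = broadband_carrier_10s
        out = rs.apply_stm(carrier, spec, 0.5)
        depth = rs.estimate_temporal_depth(out, spec, 0.5)
        assert depth == pytest.approx(0.82, abs=0.03)

    def test_depth_above_one_rejected(self):
        with pytest.raises(rs.InvalidConfigurationError):
            rs.RippleSpec("broadband", 250.0, 8000.0, 0.0, 4.0, depth=1.2)


class TestAccentuation:
    def test_zero_gain_is_identity(self, calibration):
        carrier = rs.calibrate_carrier(rs.make_pink_noise(2.0, seed=4), calibration)
        out = rs.apply_accentuation(carrier, 250.0, 8000.0, accent_db=0.0)
        assert np.allclose(out.samples, carrier.samples, atol=1e-12)

    def test_in_band_gain_15db(self, narrowband_carrier_10s):
        """Slope-compensated PSD ratio in-band vs out-of-band = 15 +/- 1 dB."""
        _, stim = narrowband_carrier_10s
        gain = rs.measure_accent_gain_db(stim, (800, 1200), (2000, 6000))
        assert gain == pytest.approx(15.0, abs=1.0)

    def test_half_gain_at_band_edge(self):
        f = np.array([250.0, 8000.0])
        g = rs._accent_gain_profile(f, 250.0, 8000.0, 15.0, 100.0)
        assert np.allclose(g, 7.5, atol=0.5)

    def test_band_narrower_than_edge_rejected(self, calibration):
        carrier = rs.make_pink_noise(0.5, seed=0)
        with pytest.raises(rs.InvalidConfigurationError):
            rs.apply_accentuation(carrier, 1000.0, 1050.0, 15.0, edge_width_hz=100.0)


class TestLevelsAndCalibration:
    def test_fullscale_sinusoid_measures_reference(self, calibration):
        t = np.arange(44100) / 44100.0
        tone = rs.TrialAudio(np.sin(2 * np.pi * 1000 * t), 44100.0)
        level = rs.measure_level_dbspl(tone, rs.CalibrationModel(dbspl_at_fullscale=100.0))
        assert level == pytest.approx(100.0, abs=0.01)

    def test_half_amplitude_drops_6db(self, calibration):
        t = np.arange(44100) / 44100.0
        tone = rs.TrialAudio(np.sin(2 * np.pi * 1000 * t), 44100.0)
        half = rs.TrialAudio(0.5 * tone.samples, 44100.0)
        d = rs.measure_level_dbspl(tone, calibration) - rs.measure_level_dbspl(half, calibration)
        assert d == pytest.approx(6.02, abs=0.01)

    def test_stationary_noise_levels_agree_across_windows(self, calibration):
        rng = np.random.default_rng(0)
        noise = rs.TrialAudio(0.1 * rng.standard_normal(44100 * 10), 44100.0)
        l1 = rs.measure_level_dbspl(noise, calibration, window=(0.0, 5.0))
        l2 = rs.measure_level_dbspl(noise, calibration, window=(5.0, 10.0))
        assert abs(l1 - l2) < 0.2

    def test_empty_window_rejected(self, calibration):
        noise = rs.TrialAudio(np.zeros(100), 44100.0)
        with pytest.raises(ValueError):
            rs.measure_level_dbspl(noise, calibration, window=(0.001, 0.001))

    def test_broadband_overall_level(self, calibration, broadband_carrier_10s):
        """60 dB SPL carrier + 15 dB accent over 250-8000 Hz -> 74 +/- 0.5 dB SPL."""
        _, stim = broadband_carrier_10s
        assert rs.measure_level_dbspl(stim, calibration) == pytest.approx(74.0, abs=0.5)

    def test_narrowband_overall_level(self, calibration, narrowband_carrier_10s):
        _, stim = narrowband_carrier_10s
        assert rs.measure_level_dbspl(stim, calibration) == pytest.approx(68.0, abs=0.5)

    @pytest.mark.parametrize("k_octaves,expected", [(5.0, 74.0), (1.0, 68.0)])
    def test_levels_match_octave_power_arithmetic(
        self, calibration, broadband_carrier_10s, narrowband_carrier_10s, k_octaves, expected
    ):
        """Boosting k of N pink octaves by G dB raises the total level by
        10*log10((N - k + k*10^(G/10))/N)."""
        n_oct = np.log2(8700 / 100)
        closed = 60.0 + 10 * np.log10((n_oct - k_octaves + k_octaves * 10**1.5) / n_oct)
        _, stim = broadband_carrier_10s if k_octaves == 5.0 else narrowband_carrier_10s
        assert rs.measure_level_dbspl(stim, calibration) == pytest.approx(closed, abs=0.5)
        assert closed == pytest.approx(expected, abs=0.5)


class TestTrialAssembly:
    def test_deterministic(self, calibration):
        spec = rs.broadband_spec(4.0, 0.5)
        a = rs.assemble_trial(spec, calibration, seed=9)
        b = rs.assemble_trial(spec, calibration, seed=9)
        assert np.array_equal(a.samples, b.samples)
        assert a.onset_s == b.onset_s

    def test_onset_grid_frequencies(self):
        """Seeded onsets are uniform over the 6-element 0.7-1.2 s grid."""
        draws = [rs.draw_onset(s) for s in range(1000)]
        for onset in rs.ONSET_GRID_S:
            assert np.mean(np.asarray(draws) == onset) == pytest.approx(1 / 6, abs=0.04)

    def test_no_clipping_and_duration(self, calibration):
        spec = rs.broadband_spec(16.0, 0.25)
        trial = rs.assemble_trial(spec, calibration, seed=1)
        assert np.max(np.abs(trial.samples)) < 1.0
        assert trial.onset_s in rs.ONSET_GRID_S
        assert trial.total_duration_s == pytest.approx(trial.onset_s + 3.0, abs=1e-6)

    def test_gain_order_commutes(self, calibration):
        """Accentuation and modulation commute in the spectrogram domain."""
        spec = rs.broadband_spec(4.0, 0.5)
        carrier = rs.calibrate_carrier(rs.make_pink_noise(4.0, seed=11), calibration)
        ab = rs.apply_stm(rs.apply_accentuation(carrier, spec.f_lo, spec.f_hi), spec, 1.0)
        ba = rs.apply_accentuation(rs.apply_stm(carrier, spec, 1.0), spec.f_lo, spec.f_hi)
        d = rs.measure_level_dbspl(ab, calibration) - rs.measure_level_dbspl(ba, calibration)
        assert abs(d) < 0.1

    def test_catch_stimulus_has_no_modulation_peak(self, calibration):
        """The catch trial's envelope spectrum is flat at every tested rate,
        while a genuinely modulated stimulus shows a dominant peak."""
        from scipy.signal.windows import hann

        def envelope_peak_ratio(trial, rate):
            env = rs._band_envelope(trial, (250.0, 8000.0))
            sel = trial.t >= trial.onset_s + 0.25
            e = env[sel] - env[sel].mean()
            mag = np.abs(np.fft.rfft(e * hann(len(e))))
            f = np.fft.rfftfreq(len(e), 1 / trial.sample_rate_hz)
            floor = np.median(mag[(f > 1) & (f < 30)])
            return mag[(f > rate - 0.5) & (f < rate + 0.5)].max() / floor

        catch = rs.assemble_trial(rs.broadband_spec(0.0, 0.0), calibration, seed=3, onset_s=0.7)
        for rate in (4.0, 8.0, 16.0):
            assert envelope_peak_ratio(catch, rate) < 8.0
        modulated = rs.assemble_trial(rs.broadband_spec(4.0, 0.0), calibration, seed=3, onset_s=0.7)
        assert envelope_peak_ratio(modulated, 4.0) > 20.0


class TestAgcStandin:
    def test_zero_reduction_is_identity(self, calibration):
        carrier = rs.calibrate_carrier(rs.make_pink_noise(2.0, seed=6), calibration)
        out = rs.agc_standin(carrier, gain_reduction_db=0.0)
        assert np.allclose(out.samples, carrier.samples)

    def test_steady_state_attenuation(self, calibration, broadband_carrier_10s):
        _, stim = broadband_carrier_10s
        out = rs.agc_standin(stim, gain_reduction_db=18.0)
        before = rs.measure_level_dbspl(stim, calibration, window=(0.6, 2.0))
        after = rs.measure_level_dbspl(out, calibration, window=(0.6, 2.0))
        assert before - after == pytest.approx(18.0, abs=0.5)

    def test_stable_before_modulation_onset(self, calibration):
        """For the catch stimulus the compressor alone changes the level by
        < 0.5 dB across the modulation-onset window (0.7-1.2 s)."""
        catch = rs.assemble_trial(rs.broadband_spec(0.0, 0.0), calibration, seed=3, onset_s=1.2)
        out = rs.agc_standin(catch, gain_reduction_db=18.0)
        l1 = rs.measure_level_dbspl(out, calibration, window=(0.7, 0.95))
        l2 = rs.measure_level_dbspl(out, calibration, window=(0.95, 1.2))
        assert abs(l1 - l2) < 0.5


class TestStimulusTable:
    def test_seventeen_conditions(self):
        specs = rs.build_stimulus_table()
        assert len(specs) == 17
        assert len({s.stimulus_id for s in specs}) == 17

    def test_exactly_one_catch(self):
        kinds = [s.band_kind for s in rs.build_stimulus_table()]
        assert kinds.count("catch") == 1

    def test_narrowband_all_4hz_2co(self):
        nb = [s for s in rs.build_stimulus_table() if s.band_kind == "narrowband"]
        assert len(nb) == 4
        assert all(s.omega == 2.0 and s.rate_hz == 4.0 for s in nb)
        assert sorted(round(s.cf_hz) for s in nb) == [500, 1000, 2000, 4000]
        for s in nb:
            assert s.f_hi / s.f_lo == pytest.approx(2.0, rel=1e-9)

    def test_broadband_grid_matches_design(self):
        bb = {
            (s.rate_hz, s.omega)
            for s in rs.build_stimulus_table()
            if s.band_kind == "broadband"
        }
        expected = {
            (0.0, 2.0), (0.0, 1.0), (0.0, 0.5), (0.0, 0.25),
            (4.0, 2.0), (4.0, 1.0), (4.0, 0.5), (4.0, 0.0),
            (8.0, 1.0), (8.0, 0.5), (8.0, 0.0),
            (16.0, 0.25),
        }
        assert bb == expected


class TestWavOutput:
    def test_wav_and_sidecar_roundtrip(self, tmp_path, calibration):
        from scipy.io import wavfile

        spec = rs.narrowband_spec(2000.0)
        trial = rs.assemble_trial(spec, calibration, seed=5)
        path = rs.write_trial_wav(trial, tmp_path / f"{spec.stimulus_id}.wav", calibration)
        sr, data = wavfile.read(path)
        assert sr == 44100
        assert data.dtype == np.int16
        assert len(data) == len(trial.samples)
        sidecar = path.with_suffix(".json")
        assert sidecar.exists()
        import json

        meta = json.loads(sidecar.read_text())
        assert meta["onset_s"] == trial.onset_s
        assert meta["spec"]["omega"] == 2.0
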