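"""Frame-level acoustics: framing arithmetic, f0/formant recovery against
synthesis ground truth, energies, entropy, fricatives, envelope, novelty."""

import numpy as np
import pytest
from dataclasses import replace

from crywatch.audio import AudioSegment
from crywatch.frontend import (
    CEPSTRAL,
    SPECTRAL,
    amplitude_envelope,
    analyze,
    estimate_f0_cepstral,
    estimate_formants,
    frame_energy,
    frame_signal,
    fricative_score,
    spectral_entropy,
    spectral_novelty,
)
from crywatch.synth import CrySynthesisParams, synthesize_recording, synthesize_utterance

SR = 22050


def pulse_train(f0: float, dur_s: float = 1.0, sr: int = SR) -> AudioSegment:
    x = np.zeros(int(dur_s * sr))
    x[:: int(round(sr / f0))] = 1.0
    return AudioSegment(x, sr)


class TestFraming:
    def test_frame_count_arithmetic(self):
        # 1 s at 22050 Hz, 12.5 ms frames, 6.25 ms hop
        audio = AudioSegment(np.random.default_rng(0).standard_normal(SR), SR)
        frames, times = frame_signal(audio, CEPSTRAL)
        frame_len = int(round(12.5 * SR / 1000))  # 276
        hop = int(round(6.25 * SR / 1000))  # 138
        assert frames.shape == ((SR - frame_len) // hop + 1, frame_len)
        assert frames.shape[0] == 158  # floor((22050 - 276) / 138) + 1
        assert times[1] - times[0] == pytest.approx(hop / SR)

    def test_single_frame_audio(self):
        n = int(round(12.5 * SR / 1000))
        audio = AudioSegment(np.ones(n), SR)
        frames, _ = frame_signal(audio, CEPSTRAL)
        assert frames.shape[0] == 1

    def test_frame_duration_fixed_in_ms_across_rates(self):
        for sr in (8000, 16000, 22050, 44100):
            audio = AudioSegment(np.ones(sr), sr)
            frames, _ = frame_signal(audio, CEPSTRAL)
            assert frames.shape[1] == int(round(12.5 * sr / 1000))

    def test_too_short_audio_empty(self):
        audio = AudioSegment(np.ones(10), SR)
        frames, times = frame_signal(audio, CEPSTRAL)
        assert frames.shape[0] == 0 and times.size == 0


class TestF0:
    def test_pulse_train_400hz(self):
        frames, _ = frame_signal(pulse_train(400.0), CEPSTRAL)
        f0, voiced = estimate_f0_cepstral(frames[50], SR)
        assert voiced
        # quantization: one quefrency bin around sr/400
        lag = SR / 400.0
        lo, hi = SR / (lag + 1), SR / (lag - 1)
        assert lo <= f0 <= hi

    def test_white_noise_unvoiced(self):
        rng = np.random.default_rng(1)
        audio = AudioSegment(rng.standard_normal(SR), SR)
        frames, _ = frame_signal(audio, CEPSTRAL)
        voiced = [estimate_f0_cepstral(f, SR)[1] for f in frames[:50]]
        assert np.mean(voiced) < 0.2

    def test_hyperphonation_flagged_above_1khz(self):
        frames, _ = frame_signal(pulse_train(1200.0), CEPSTRAL)
        f0, voiced = estimate_f0_cepstral(frames[50], SR)
        assert voiced and f0 == pytest.approx(1200.0, rel=0.05)
        assert f0 > CEPSTRAL.hyperphonation_threshold

    @pytest.mark.parametrize("profile", [CEPSTRAL, SPECTRAL], ids=lambda p: p.analyzer_id)
    def test_f0_recovery_grid_under_5pct(self, profile):
        # median |error| < 5% over synthesized cries at each grid pitch
        errors = []
        for true_f0 in (300.0, 500.0, 800.0, 1200.0):
            p = CrySynthesisParams(
                f0_base=min(true_f0, 1000.0),
                hyperphonation_f0=max(true_f0, 1001.0),
                f0_contour=((0.0, 1.0), (1.0, 1.0)),
                hyperphonation_prob=0.0,
                fricative_prob=0.0,
                noise_snr_db=40.0,
            )
            a = synthesize_utterance(p, 500, seed=17, hyperphonation=true_f0 > 1000)
            series = analyze(a, profile)
            f0 = series.table["f0"].dropna()
            errors.append(abs(np.median(f0) - true_f0) / true_f0)
        assert np.median(errors) < 0.05


class TestFormants:
    def test_recovery_on_synthetic_vowel(self, flat_params):
        # resonators at 1100 / 3300 Hz
        a = synthesize_utterance(flat_params, 800, seed=5)
        frames, _ = frame_signal(a, CEPSTRAL)
        est = np.array([estimate_formants(f, SR) for f in frames[10:110]])
        assert abs(np.nanmedian(est[:, 0]) - 1100.0) < 100.0
        assert abs(np.nanmedian(est[:, 1]) - 3300.0) < 150.0

    def test_ordering_invariant(self):
        p = CrySynthesisParams(
            formants=((900.0, 150.0), (2500.0, 300.0)),
            f0_contour=((0.0, 1.0), (1.0, 1.0)),
            hyperphonation_prob=0.0,
            fricative_prob=0.0,
            noise_snr_db=60.0,
        )
        a = synthesize_utterance(p, 500, seed=6)
        frames, _ = frame_signal(a, CEPSTRAL)
        for f in frames[5:60]:
            f1, f2 = estimate_formants(f, SR)
            if np.isfinite(f1) and np.isfinite(f2):
                assert f1 < f2

    def test_unvoiced_frame_gives_missing(self, flat_params):
        a = synthesize_utterance(flat_params, 400, seed=7)
        series = analyze(a, CEPSTRAL)
        t = series.table
        unvoiced = t[~t["voiced"]]
        assert unvoiced["F1"].isna().all() and unvoiced["F2"].isna().all()


class TestEnergy:
    def test_zero_frame_floored(self):
        t, lo, hi = frame_energy(np.zeros(276), SR)
        assert t == lo == hi == -120.0

    def test_low_sine_energy_in_low_band(self):
        n = 276
        w = np.hanning(n)
        x = np.sin(2 * np.pi * 500 * np.arange(n) / SR) * w
        t, lo, hi = frame_energy(x, SR)
        assert lo == pytest.approx(t, abs=0.1)
        assert hi < t - 30

    def test_doubling_amplitude_adds_6db(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(276)
        t1, lo1, hi1 = frame_energy(x, SR)
        t2, lo2, hi2 = frame_energy(2 * x, SR)
        for a, b in ((t1, t2), (lo1, lo2), (hi1, hi2)):
            assert b - a == pytest.approx(20 * np.log10(2), abs=1e-6)


class TestEntropy:
    def test_white_noise_near_one(self):
        rng = np.random.default_rng(3)
        vals = [spectral_entropy(rng.standard_normal(276)) for _ in range(200)]
        assert np.mean(vals) >= 0.95

    def test_pure_sine_near_zero(self):
        x = np.sin(2 * np.pi * 1000 * np.arange(276) / SR) * np.hanning(276)
        assert spectral_entropy(x) <= 0.3

    def test_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            v = spectral_entropy(rng.standard_normal(276) * rng.uniform(0.01, 10))
            assert 0.0 <= v <= 1.0

    def test_zero_frame_missing(self):
        assert np.isnan(spectral_entropy(np.zeros(276)))


class TestFricative:
    def test_high_band_noise_scores_high(self):
        from scipy import signal as sps

        rng = np.random.default_rng(5)
        sos = sps.butter(4, [4000, 9000], btype="bandpass", fs=SR, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(SR))
        assert fricative_score(x[5000:5276], SR) >= 0.8

    def test_low_frequency_voicing_scores_low(self):
        from scipy import signal as sps

        x = pulse_train(300.0).samples
        sos = sps.butter(4, 500, btype="lowpass", fs=SR, output="sos")
        y = sps.sosfilt(sos, x)
        assert fricative_score(y[5000:5276], SR) <= 0.2

    def test_monotone_in_high_band_ratio(self):
        # mixing more high-band noise into a low tone never lowers the score
        from scipy import signal as sps

        rng = np.random.default_rng(6)
        n = 276
        tone = np.sin(2 * np.pi * 400 * np.arange(n) / SR)
        sos = sps.butter(4, [5000, 9000], btype="bandpass", fs=SR, output="sos")
        noise = sps.sosfilt(sos, rng.standard_normal(4 * n))[-n:]
        scores = [
            fricative_score(tone + w * noise, SR) for w in (0.0, 0.5, 1.0, 2.0, 8.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(scores, scores[1:]))


class TestEnvelopeNovelty:
    def test_am_modulation_frequency_recovered(self):
        t = np.arange(2 * SR) / SR
        x = (1.0 + 0.9 * np.sin(2 * np.pi * 4.0 * t)) * np.sin(2 * np.pi * 800 * t)
        series = analyze(AudioSegment(x, SR), SPECTRAL)
        env, f_env = amplitude_envelope(series)
        assert np.all(env >= 0)
        assert f_env == pytest.approx(4.0, abs=0.5)

    def test_constant_amplitude_no_modulation(self):
        x = np.sin(2 * np.pi * 800 * np.arange(2 * SR) / SR)
        series = analyze(AudioSegment(x, SR), SPECTRAL)
        _, f_env = amplitude_envelope(series)
        assert np.isnan(f_env)

    def test_novelty_peaks_at_spectral_junction(self):
        sr = SR
        half = np.sin(2 * np.pi * 500 * np.arange(sr) / sr)
        half2 = np.sin(2 * np.pi * 3000 * np.arange(sr) / sr)
        series = analyze(AudioSegment(np.concatenate([half, half2]), sr), SPECTRAL)
        nov = series.table["novelty"].to_numpy()
        n = nov.size
        junction = n // 2
        assert abs(int(np.argmax(nov)) - junction) <= 8  # within kernel/2 frames
        assert np.all(nov >= 0)

    def test_stationary_noise_novelty_flat(self):
        rng = np.random.default_rng(7)
        series = analyze(AudioSegment(rng.standard_normal(SR), SR), SPECTRAL)
        nov = series.table["novelty"].to_numpy()
        inner = nov[10:-10]
        assert inner.max() / max(np.median(inner), 1e-12) < 3


class TestAnalyze:
    def test_profiles_differ_in_columns(self, flat_params):
        a = synthesize_utterance(flat_params, 400, seed=8)
        s1, s2 = analyze(a, CEPSTRAL), analyze(a, SPECTRAL)
        assert s1.analyzer_id != s2.analyzer_id
        assert set(s1.table.columns) != set(s2.table.columns)
        assert "energy_low" in s1.table and "spectral_entropy" in s2.table

    def test_synthesized_cry_mostly_voiced(self, flat_params):
        a = synthesize_utterance(flat_params, 600, seed=9)
        for prof in (CEPSTRAL, SPECTRAL):
            assert analyze(a, prof).table["voiced"].mean() > 0.5

    def test_silence_zero_voiced(self):
        a = AudioSegment(np.full(SR // 2, 1e-9), SR)
        assert analyze(a, CEPSTRAL).table["voiced"].sum() == 0

    def test_missing_f0_iff_unvoiced(self, flat_params):
        audio, _ = synthesize_recording(flat_params, 3, seed=10)
        t = analyze(audio, CEPSTRAL).table
        assert (t["f0"].isna() == ~t["voiced"]).all()

    def test_profile_independence(self, flat_params):
        a = synthesize_utterance(flat_params, 400, seed=11)
        base = analyze(a, SPECTRAL).table
        modified = replace(CEPSTRAL, feature_set=("f0", "energy_bands"))
        _ = analyze(a, modified)
        again = analyze(a, SPECTRAL).table
        assert base.equals(again)
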