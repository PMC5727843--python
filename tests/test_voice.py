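import math

import numpy as np
import pytest

from sasangdx.voice import (
    AudioFrame,
    PitchTrack,
    SentenceFeatures,
    SilentFrameError,
    cepstral_peak_prominence,
    harmonic_noise_ratio,
    mfcc12,
    pitch_summary,
    sentence_features,
    window_duration,
)

SR = 44100.0


def harmonic_frame(f0, n=2048, sr=SR, n_harm=5, rng=None, phase=0.0):
    t = np.arange(n) / sr
    x = sum(np.sin(2 * np.pi * (h + 1) * f0 * t + phase) / (h + 1)
            for h in range(n_harm))
    return AudioFrame(x, sr)


class TestWindowDuration:
    def test_reference_window_is_46_4_ms(self):
        assert round(window_duration(44100, 2 ** 11), 1) == 46.4

    def test_simple_case(self):
        assert window_duration(1000, 500) == pytest.approx(500)

    @pytest.mark.parametrize("sr,n", [(0, 2048), (44100, 0), (-1, 100)])
    def test_nonpositive_inputs_rejected(self, sr, n):
        with pytest.raises(ValueError):
            window_duration(sr, n)


def track(f0_values, voiced=None, hop=0.01):
    f0 = np.asarray(f0_values, dtype=float)
    t = np.arange(f0.size) * hop
    v = np.ones(f0.size, bool) if voiced is None else np.asarray(voiced, bool)
    return PitchTrack(times=t, f0=f0, voiced=v)


class TestPitchSummary:
    def test_constant_track(self):
        s = pitch_summary(track([120.0] * 10))
        assert s.sF0 == pytest.approx(120)
        assert s.sFCV == 0
        assert s.sF10 == s.sF50 == s.sF90 == 120
        assert math.isnan(s.sFHL)
        assert s.sDT == pytest.approx(0.09)

    def test_percentiles_match_order_statistics_oracle(self):
        """Linear interpolation between order statistics: percentile p of
        n sorted values sits at fractional rank p/100*(n-1)."""
        vals = [90, 95, 100, 105, 110, 120, 130, 145, 160, 180]
        s = pitch_summary(track(vals))

        def oracle(p):
            srt = sorted(vals)
            r = p / 100 * (len(srt) - 1)
            lo, frac = int(math.floor(r)), r - math.floor(r)
            hi = min(lo + 1, len(srt) - 1)
            return srt[lo] + frac * (srt[hi] - srt[lo])

        assert s.sF10 == pytest.approx(oracle(10))
        assert s.sF50 == pytest.approx(oracle(50))
        assert s.sF90 == pytest.approx(oracle(90))
        assert s.sFHL == pytest.approx((s.sF90 - s.sF50) / (s.sF50 - s.sF10))

    def test_percentile_ordering_property(self, rng):
        for _ in range(50):
            s = pitch_summary(track(rng.uniform(60, 300, rng.integers(2, 40))))
            assert s.sF10 <= s.sF50 <= s.sF90
            assert s.sFCV >= 0

    def test_unvoiced_frames_excluded(self):
        s = pitch_summary(track([100, 100, 500], voiced=[True, True, False]))
        assert s.sF0 == pytest.approx(100)

    def test_no_voiced_frames_is_an_error(self):
        with pytest.raises(ValueError):
            pitch_summary(track([100.0], voiced=[False]))


class TestHNR:
    def test_pure_sinusoid_hits_the_cap(self):
        # 2048 samples at 44.1 kHz with f0 chosen for an integer period
        f0 = SR / 210  # exact 210-sample period
        frame = AudioFrame(np.sin(2 * np.pi * f0 * np.arange(2048) / SR), SR)
        assert harmonic_noise_ratio(frame, f0) == 60.0

    def test_equal_harmonic_and_noise_power_is_near_zero_db(self, rng):
        f0 = 150.0
        vals = []
        for _ in range(30):
            h = harmonic_frame(f0, rng=rng).samples
            noise = rng.standard_normal(h.size)
            noise *= np.sqrt(np.mean(h ** 2) / np.mean(noise ** 2))
            vals.append(harmonic_noise_ratio(AudioFrame(h + noise, SR), f0))
        assert abs(np.median(vals)) < 1.5

    def test_programmed_20db_ratio_recovered(self, rng):
        f0 = 180.0
        est = []
        for _ in range(50):
            h = harmonic_frame(f0, rng=rng, phase=rng.uniform(0, 2 * np.pi)).samples
            p_h = np.mean(h ** 2)
            noise = rng.standard_normal(h.size) * np.sqrt(p_h / 10 ** 2.0)
            est.append(harmonic_noise_ratio(AudioFrame(h + noise, SR), f0))
        assert abs(np.median(est) - 20.0) < 2.0

    def test_monotone_in_noise_power(self, rng):
        f0 = 140.0
        h = harmonic_frame(f0).samples
        p_h = np.mean(h ** 2)
        noise = rng.standard_normal(h.size)
        noise /= np.sqrt(np.mean(noise ** 2))
        hnrs = []
        for snr_db in (40, 30, 20, 10, 0, -10):
            x = h + noise * np.sqrt(p_h / 10 ** (snr_db / 10))
            hnrs.append(harmonic_noise_ratio(AudioFrame(x, SR), f0))
        assert all(a >= b for a, b in zip(hnrs, hnrs[1:]))

    def test_all_zero_frame_is_an_error(self):
        with pytest.raises(SilentFrameError):
            harmonic_noise_ratio(AudioFrame(np.zeros(2048), SR), 100.0)


class TestCPP:
    def test_pulse_train_beats_white_noise(self, rng):
        wins = 0
        for _ in range(20):
            pulse = np.zeros(2048)
            pulse[:: 220] = 1.0
            pulse += rng.normal(0, 1e-4, 2048)  # break exact silence between pulses
            noise = rng.standard_normal(2048)
            noise *= np.sqrt(np.mean(pulse ** 2) / np.mean(noise ** 2))
            if cepstral_peak_prominence(AudioFrame(pulse, SR)) > \
                    cepstral_peak_prominence(AudioFrame(noise, SR)):
                wins += 1
        assert wins == 20

    def test_decreases_with_snr(self, rng):
        """A glottal-like pulse train (harmonics across the whole band)
        loses cepstral peak prominence as additive noise grows."""
        medians = []
        for snr_db in (30, 20, 10, 0):
            vals = []
            for _ in range(20):
                pulse = np.zeros(2048)
                pulse[int(rng.integers(0, 220)):: 220] = 1.0
                p = np.mean(pulse ** 2)
                n = rng.standard_normal(2048) * np.sqrt(p / 10 ** (snr_db / 10))
                vals.append(cepstral_peak_prominence(AudioFrame(pulse + n, SR)))
            medians.append(np.median(vals))
        assert all(a > b for a, b in zip(medians, medians[1:]))

    def test_silent_frame_is_an_error(self):
        with pytest.raises(SilentFrameError):
            cepstral_peak_prominence(AudioFrame(np.zeros(2048), SR))


class TestMFCC:
    def test_twelve_coefficients(self):
        assert mfcc12(harmonic_frame(150.0)).shape == (12,)

    def test_gain_invariance(self):
        frame = harmonic_frame(200.0)
        doubled = AudioFrame(2.0 * frame.samples, SR)
        np.testing.assert_allclose(mfcc12(doubled), mfcc12(frame), atol=1e-6)

    def test_deterministic(self):
        a = mfcc12(harmonic_frame(150.0))
        b = mfcc12(harmonic_frame(150.0))
        np.testing.assert_array_equal(a, b)

    def test_silent_frame_is_an_error(self):
        with pytest.raises(SilentFrameError):
            mfcc12(AudioFrame(np.zeros(2048), SR))


class TestSentenceFeatures:
    def _feat(self, sF0=100.0, sFHL=0.5):
        return SentenceFeatures(sF0, 0.1, 90, 100, 120, sFHL, 2.0, 15.0, 10.0,
                                mfcc=tuple(float(i) for i in range(12)))

    def test_vector_has_21_entries(self):
        assert len(SentenceFeatures.field_names()) == 21
        assert self._feat().to_array().shape == (21,)

    def test_two_identical_utterances(self):
        f = self._feat()
        out, flags = sentence_features(f, f)
        np.testing.assert_array_equal(out.to_array(), f.to_array())
        assert flags == []

    def test_arithmetic_mean(self):
        out, _ = sentence_features(self._feat(sF0=100), self._feat(sF0=120))
        assert out.sF0 == pytest.approx(110)

    def test_nan_field_uses_the_valid_utterance_and_flags(self):
        out, flags = sentence_features(self._feat(sFHL=float("nan")),
                                       self._feat(sFHL=0.7))
        assert out.sFHL == pytest.approx(0.7)
        assert flags == ["sFHL"]

    def test_both_nan_stays_nan_and_flags(self):
        out, flags = sentence_features(self._feat(sFHL=float("nan")),
                                       self._feat(sFHL=float("nan")))
        assert math.isnan(out.sFHL)
        assert "sFHL" in flags
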