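"""Vocal disguise, level normalization, speech-shaped noise, and SNR mixing."""

import numpy as np
import pytest
from scipy.signal import welch

from ownvoice import acoustic_features as af
from ownvoice import stimprep, synthdata

SR = synthdata.SAMPLE_RATE


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def _vowel(f1=600.0, f2=1100.0, dur=0.25, f0=200.0):
    return synthdata.synthesize_vowel([f1] * 20, [f2] * 20, dur, f0)


class TestRmsNormalize:
    def test_hits_the_praat_convention_target(self):
        """65 dB SPL re 2e-5 with full scale 1 Pa -> RMS 0.035566."""
        y = stimprep.rms_normalize(_vowel(), 65.0)
        assert _rms(y) == pytest.approx(0.0355656, abs=1e-6)

    def test_idempotent(self):
        y1 = stimprep.rms_normalize(_vowel(), 65.0)
        y2 = stimprep.rms_normalize(y1, 65.0)
        assert np.allclose(y1, y2)

    def test_rejects_silence(self):
        with pytest.raises(ValueError):
            stimprep.rms_normalize(np.zeros(1000), 65.0)


class TestMixAtSnr:
    def test_noise_gain_closed_form(self):
        """Equal-RMS inputs at +5 dB need noise gain 10^(-5/20) = 0.56234."""
        rng = np.random.default_rng(0)
        s = rng.standard_normal(8000)
        n = rng.standard_normal(9000)
        n *= _rms(s) / _rms(n[:8000])
        mixed = stimprep.mix_at_snr(s, n, 5.0)
        resid = mixed - s
        assert _rms(resid) / _rms(n[:8000]) == pytest.approx(0.5623413, abs=1e-4)

    @pytest.mark.parametrize("snr", [-5.0, 0.0, 5.0, 12.0])
    def test_measured_snr_matches_request(self, snr):
        rng = np.random.default_rng(1)
        s = _vowel()
        n = rng.standard_normal(len(s) + 100)
        mixed = stimprep.mix_at_snr(s, n, snr)
        measured = 20 * np.log10(_rms(s) / _rms(mixed - s))
        assert measured == pytest.approx(snr, abs=0.01)

    def test_zero_snr_equal_rms_gain_one(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal(5000)
        n = rng.standard_normal(5000)
        n *= _rms(s) / _rms(n)
        mixed = stimprep.mix_at_snr(s, n, 0.0)
        assert np.allclose(mixed, s + n, atol=1e-9)

    def test_rejects_short_or_silent_noise(self):
        s = _vowel()
        with pytest.raises(ValueError):
            stimprep.mix_at_snr(s, s[: len(s) // 2], 5.0)
        with pytest.raises(ValueError):
            stimprep.mix_at_snr(s, np.zeros(len(s)), 5.0)


def _band_ltas(x, nbands=40, flo=100.0, fhi=8000.0):
    f, p = welch(x, fs=SR, nperseg=2048)
    edges = np.linspace(flo, fhi, nbands + 1)
    return np.array(
        [10 * np.log10(np.mean(p[(f >= a) & (f < b)]) + 1e-30)
         for a, b in zip(edges[:-1], edges[1:])]
    )


class TestSpeechShapedNoise:
    def test_flat_corpus_gives_flat_noise(self):
        rng = np.random.default_rng(3)
        ssn = stimprep.speech_shaped_noise([rng.standard_normal(SR)], 2.0, seed=4)
        f, p = welch(ssn, fs=SR, nperseg=1024)
        band = (f >= 100) & (f <= 8000)
        flat = 10 * np.log10(p[band] / np.mean(p[band]))
        assert np.max(np.abs(flat)) < 3.0

    def test_ltas_matches_speech_corpus(self):
        """Self-consistency: banded LTAS of the noise tracks the corpus LTAS."""
        corpus = [_vowel(600 + 100 * i, 1100 + 200 * i, 0.4, 200.0 + 10 * i) for i in range(4)]
        ssn = stimprep.speech_shaped_noise(corpus, 2.0, seed=5)
        diff = _band_ltas(ssn) - _band_ltas(np.concatenate(corpus))
        assert np.max(np.abs(diff)) < 3.0

    def test_narrowband_corpus_peaks_at_the_sine(self):
        rng = np.random.default_rng(6)
        t = np.arange(2 * SR) / SR
        corpus = [np.sin(2 * np.pi * 1000 * t) + 1e-3 * rng.standard_normal(len(t))]
        ssn = stimprep.speech_shaped_noise(corpus, 1.0, seed=7)
        f, p = welch(ssn, fs=SR, nperseg=4096)
        assert abs(f[np.argmax(p)] - 1000.0) < 50.0

    def test_deterministic_under_seed_and_rejects_empty(self):
        rng = np.random.default_rng(8)
        corpus = [rng.standard_normal(SR)]
        a = stimprep.speech_shaped_noise(corpus, 1.0, seed=9)
        b = stimprep.speech_shaped_noise(corpus, 1.0, seed=9)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            stimprep.speech_shaped_noise([], 1.0, seed=0)
        with pytest.raises(ValueError):
            stimprep.speech_shaped_noise([np.zeros(100)], 1.0, seed=0)


@pytest.fixture(scope="module")
def audio_token():
    talkers, roster = synthdata.make_cohort(5, 13, seed=5)
    talkers[0].f0_base = 200.0
    rng = np.random.default_rng(0)
    return synthdata.synthesize_token(
        talkers[0], "kaat1", roster, jitter=0.0, with_audio=True, rng=rng
    )


class TestDisguise:
    def test_identity_factors_reproduce_the_input(self, audio_token):
        out = stimprep.disguise(
            audio_token, stimprep.DisguiseSpec(f0_factor=1.0, formant_factor=1.0)
        )
        assert np.allclose(out, audio_token.audio)

    def test_parametric_formant_scaling(self, audio_token):
        """Measured F1 of the disguised output sits at formant_factor x F1."""
        out = stimprep.disguise(audio_token, stimprep.DisguiseSpec())
        tr = af.measure_formants(out, SR, ceiling=5500.0)
        target = 0.81 * np.mean(audio_token.f1_track)
        assert np.mean(tr.f1) == pytest.approx(target, rel=0.05)

    def test_mean_factors_on_200hz_token(self):
        """Factors (0.62, 0.81) on a 200 Hz token: output f0 ~ 124 Hz."""
        audio = _vowel(f1=500.0, f2=1500.0, f0=200.0)
        out = stimprep._dsp_disguise(audio, SR, stimprep.DisguiseSpec())
        assert stimprep._estimate_f0(out, SR) == pytest.approx(124.0, rel=0.05)
        tr = af.measure_formants(out, SR, ceiling=5500.0)
        assert np.mean(tr.f1) == pytest.approx(405.0, rel=0.05)

    def test_dsp_path_preserves_duration(self, audio_token):
        out = stimprep._dsp_disguise(audio_token.audio, SR, stimprep.DisguiseSpec())
        assert len(out) == pytest.approx(len(audio_token.audio), rel=0.02)

    def test_paths_agree_on_measured_formants(self, audio_token):
        """Parametric and DSP disguise yield the same formants within 7%."""
        spec = stimprep.DisguiseSpec()
        a = stimprep.disguise(audio_token, spec)
        b = stimprep._dsp_disguise(audio_token.audio, SR, spec)
        ta = af.measure_formants(a, SR, ceiling=5500.0)
        tb = af.measure_formants(b, SR, ceiling=5500.0)
        assert np.mean(tb.f1) == pytest.approx(np.mean(ta.f1), rel=0.07)
        assert np.mean(tb.f2) == pytest.approx(np.mean(ta.f2), rel=0.07)

    def test_rejects_bad_factors_and_missing_parameters(self, audio_token):
        with pytest.raises(ValueError):
            stimprep.DisguiseSpec(f0_factor=0.0)
        bare = synthdata.VowelToken(
            talker_id="T01", word_id="w", pair_id="p", repetition=1,
            f1_track=None, f2_track=None, duration=0.2,
            audio=audio_token.audio,
        )
        with pytest.raises(ValueError):
            stimprep.disguise(bare, stimprep.DisguiseSpec())


def test_prepare_stimulus_full_chain(audio_token):
    """Disguise -> 65 dB RMS -> gated noise at +5 dB SNR, with padding."""
    corpus = [_vowel(600, 1100, 0.5, 210.0), _vowel(800, 1300, 0.6, 190.0)]
    noise = stimprep.speech_shaped_noise(corpus, 3.0, seed=11)
    out = stimprep.prepare_stimulus(audio_token, noise)
    pad = int(round(0.2 * SR))
    n_tok = len(stimprep.disguise(audio_token, stimprep.DisguiseSpec()))
    assert len(out) == n_tok + 2 * pad
    # the token segment carries signal + noise at +5 dB
    tok_part = stimprep.rms_normalize(
        stimprep.disguise(audio_token, stimprep.DisguiseSpec()), 65.0
    )
    resid = out[pad : pad + n_tok] - tok_part
    snr = 20 * np.log10(_rms(tok_part) / _rms(resid))
    assert snr == pytest.approx(5.0, abs=0.25)  # gate includes the padding noise


def test_wav_roundtrip(tmp_path, audio_token):
    path = tmp_path / "tok.wav"
    x = 0.5 * audio_token.audio / np.max(np.abs(audio_token.audio))
    stimprep.write_wav(path, x)
    sr, y = stimprep.read_wav(path)
    assert sr == SR
    assert np.max(np.abs(x - y)) < 1e-3  # 16-bit quantization
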