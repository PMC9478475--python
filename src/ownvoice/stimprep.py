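"""Perception-stimulus preparation: vocal disguise, level normalization,
speech-shaped noise, and SNR mixing.

The disguise lowers f0 and formant frequencies by multiplicative factors to
mask talker identity (the classic female-to-male "change gender"
manipulation). Two paths are provided:

* parametric — for generator tokens carrying their synthesis parameters the
  vowel is simply re-synthesized with scaled f0 and formants (exact);
* DSP — for raw audio, formants are scaled by playback-rate resampling,
  duration is restored and f0 corrected in a single pitch-synchronous
  overlap-add (PSOLA) pass.

Levels follow the Praat SPL convention: full scale = 1 Pa, reference
2e-5 Pa, so "65 dB" means an RMS of 2e-5 * 10**(65/20) ~= 0.035566.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile
from scipy.signal import fftconvolve, firwin2, resample_poly, welch

from .synthdata import SAMPLE_RATE, VowelToken, synthesize_vowel

__all__ = [
    "DisguiseSpec",
    "MixSpec",
    "disguise",
    "rms_normalize",
    "speech_shaped_noise",
    "mix_at_snr",
    "prepare_stimulus",
    "read_wav",
    "write_wav",
]

SPL_REFERENCE_PA = 2e-5


@dataclass
class DisguiseSpec:
    """Per-talker multiplicative disguise factors (defaults = study means)."""

    talker_id: str = ""
    f0_factor: float = 0.62
    formant_factor: float = 0.81

    def __post_init__(self) -> None:
        if self.f0_factor <= 0 or self.formant_factor <= 0:
            raise ValueError("disguise factors must be positive")


@dataclass
class MixSpec:
    """Presentation level and signal-to-noise ratio of the final stimulus."""

    target_rms_db: float = 65.0
    snr_db: float = 5.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def _rms(x: np.ndarray) -> float:
    return math.sqrt(float(np.mean(np.square(x))))


def disguise(x, spec: DisguiseSpec, sample_rate: int = SAMPLE_RATE) -> np.ndarray:
    """Lower f0 and formants of a token or waveform by the spec's factors.

    A :class:`~ownvoice.synthdata.VowelToken` with formant tracks takes the
    exact parametric path (re-synthesis with scaled parameters); a plain
    waveform takes the DSP path. Output duration is within 2% of the input.
    """
    if isinstance(x, VowelToken):
        if x.f1_track is None or x.f2_track is None or x.f0_track is None:
            raise ValueError("token lacks synthesis parameters for the parametric path")
        return synthesize_vowel(
            np.asarray(x.f1_track) * spec.formant_factor,
            np.asarray(x.f2_track) * spec.formant_factor,
            x.duration,
            float(np.mean(x.f0_track)) * spec.f0_factor,
            sample_rate=x.sample_rate,
            f3=3200.0 * spec.formant_factor,
        )
    return _dsp_disguise(np.asarray(x, dtype=float), sample_rate, spec)


def _estimate_f0(x: np.ndarray, sr: int, fmin: float = 70.0, fmax: float = 350.0) -> float:
    """Cepstral f0 estimate with parabolic refinement.

    A periodic signal shows near-equal cepstral rahmonics at every multiple
    of its period, so after locating the strongest rahmonic the shortest
    submultiple lag whose rahmonic is nearly as strong is taken as the
    fundamental period.
    """
    seg = np.asarray(x, dtype=float)
    if len(seg) < int(2 * sr / fmin):
        raise ValueError("signal too short for f0 estimation")
    seg = seg - np.mean(seg)
    logspec = np.log(np.abs(np.fft.rfft(seg * np.hanning(len(seg)))) + 1e-12)

    # variance-reduced multitaper spectrum for the harmonic-comb check (a
    # single-frame log spectrum has wildly noisy inter-harmonic floors, and
    # Welch averaging would trade away the frequency resolution needed to
    # separate harmonics from half-harmonic offsets at low f0)
    from scipy.signal.windows import dpss

    tapers = dpss(len(seg), NW=2.5, Kmax=4)
    mt = np.mean(np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2, axis=0)
    logw = np.log(mt + 1e-300)
    dfw = sr / len(seg)

    def comb_contrast(f0: float) -> tuple[float, float]:
        # per-harmonic prominence: spectrum level at h*f0 minus the mean level
        # at the surrounding half-harmonic offsets. Returns (mean, min over
        # the first harmonics). A half-f0 candidate has ~zero prominence at
        # its odd harmonics, so the min exposes subharmonic errors.
        hmax = max(2, int(2000.0 / f0))
        h = np.arange(1, hmax + 1)

        def level(f):
            # max over the multitaper mainlobe width (+-3 bins): harmonic
            # peaks may straddle bin boundaries
            i = np.clip(np.round(f / dfw).astype(int), 3, len(logw) - 4)
            return np.maximum.reduce([logw[i + d] for d in range(-3, 4)])

        # compare against the *higher* neighbor so overall spectral slope
        # (e.g. the radiation high-pass) cannot fake a harmonic peak
        prom = level(h * f0) - np.maximum(level((h - 0.5) * f0), level((h + 0.5) * f0))
        return float(np.mean(prom)), float(np.min(prom[: min(4, hmax)])), prom

    # coarse stage: densely score candidate f0s by comb contrast. The true
    # f0 and its odd multiples tie near the maximum (their harmonics all sit
    # on the comb) while submultiples reach only about half of it, so the
    # lowest candidate within 80% of the maximum is the fundamental.
    grid = np.arange(fmin, fmax, 0.5)
    scores = np.array([comb_contrast(f)[0] for f in grid])
    smax = scores.max()
    thr = smax - max(0.2 * abs(smax), 0.25 * (smax - float(np.median(scores))))
    qualified = grid[scores >= thr]
    f_rough = float(qualified[0])
    # an odd supermultiple (3*f0) also scores high on its own comb; if a
    # submultiple of the candidate still explains the spectrum well, take it
    for m in (3, 2):
        fm = f_rough / m
        if fm >= fmin and comb_contrast(fm)[0] >= 0.55 * comb_contrast(f_rough)[0]:
            f_rough = fm
            break
    # a subharmonic (f0/2) candidate shows strong even but weak odd
    # harmonics; the true f0 shows no such imbalance
    for _ in range(2):
        prom = comb_contrast(f_rough)[2]
        if len(prom) >= 4 and 2 * f_rough < fmax:
            odd, even = np.mean(prom[0::2]), np.mean(prom[1::2])
            if odd < 0.35 * even:
                f_rough *= 2.0
                continue
        break

    # fine stage: parabolic refinement on a 4x oversampled cepstrum (the
    # zero-padded log-spectrum keeps off-grid periods from splitting their
    # rahmonic peak across lag bins)
    pad = 4
    c = np.fft.irfft(logspec, n=pad * 2 * (len(logspec) - 1))
    lo = max(2, int(pad * sr / (f_rough * 1.08)))
    hi = min(len(c) // 2 - 2, int(pad * sr / (f_rough / 1.08)))
    if hi <= lo:
        raise ValueError("f0 search range empty at this signal length")
    k = lo + int(np.argmax(c[lo:hi]))
    y0, y1, y2 = c[k - 1], c[k], c[k + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return pad * sr / (k + shift)


def _psola(x: np.ndarray, sr: int, time_factor: float, pitch_factor: float) -> np.ndarray:
    """Pitch-synchronous overlap-add: scale duration by ``time_factor`` and
    f0 by ``pitch_factor`` while preserving the spectral envelope.

    Assumes quasi-constant f0 (true of the level-tone vowel stimuli); pitch
    marks are placed at uniform period intervals.
    """
    f0 = _estimate_f0(x, sr)
    period = sr / f0
    out_len = int(round(len(x) * time_factor))
    out = np.zeros(out_len)
    norm = np.zeros(out_len)
    # 2.5-period grains: long enough to limit spectral-envelope smearing,
    # short enough to localize the time-scale modification
    grain_half = int(round(1.25 * period))
    win = np.hanning(2 * grain_half)

    syn_step = period / pitch_factor
    m = 0
    while m * syn_step < out_len:
        s = m * syn_step
        src = s / time_factor
        k = int(round(src / period))  # nearest analysis mark
        a = int(round(k * period))
        g0, g1 = a - grain_half, a + grain_half
        if g0 >= 0 and g1 <= len(x):
            grain = x[g0:g1] * win
            o0 = int(round(s)) - grain_half
            lo = max(0, -o0)
            hi = min(len(grain), out_len - o0)
            if hi > lo:
                out[o0 + lo : o0 + hi] += grain[lo:hi]
                norm[o0 + lo : o0 + hi] += win[lo:hi]
        m += 1
    norm[norm < 1e-3] = 1.0
    return out / norm


def _dsp_disguise(x: np.ndarray, sr: int, spec: DisguiseSpec) -> np.ndarray:
    ff = spec.formant_factor
    # spectrum compression by ff: interpolate to len/ff samples played at sr
    up, down = 10_000, int(round(10_000 * ff))
    y = resample_poly(x, up, down)
    # restore duration (factor ff) and move f0 from f0*ff to f0*f0_factor
    return _psola(y, sr, time_factor=ff, pitch_factor=spec.f0_factor / ff)


def rms_normalize(audio, target_rms_db: float = 65.0) -> np.ndarray:
    """Scale audio to the target RMS level (dB SPL re 2e-5, full scale 1 Pa)."""
    x = np.asarray(audio, dtype=float)
    r = _rms(x)
    if r < 1e-12:
        raise ValueError("cannot normalize silent audio")
    target = SPL_REFERENCE_PA * 10.0 ** (target_rms_db / 20.0)
    return x * (target / r)


def speech_shaped_noise(
    corpus,
    duration: float,
    seed: int = 0,
    sample_rate: int = SAMPLE_RATE,
    n_taps: int = 1025,
    nperseg: int = 2048,
) -> np.ndarray:
    """Gaussian noise spectrally shaped to the corpus' long-term average spectrum.

    The concatenated corpus' LTAS is Welch-estimated and converted into a
    linear-phase FIR filter (frequency-sampling design) applied to white
    noise. Output RMS matches the corpus RMS; deterministic under ``seed``.
    """
    parts = [np.asarray(c, dtype=float) for c in corpus]
    if not parts:
        raise ValueError("empty corpus")
    cat = np.concatenate(parts)
    if len(cat) < sample_rate:
        raise ValueError("corpus must total at least 1 s of audio")
    freqs, psd = welch(cat, fs=sample_rate, nperseg=nperseg)
    gains = np.sqrt(psd)
    gains /= gains.max()
    taps = firwin2(n_taps, freqs / (sample_rate / 2), gains)

    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    white = rng.standard_normal(n + n_taps)
    shaped = fftconvolve(white, taps, mode="full")[n_taps : n_taps + n]
    return shaped * (_rms(cat) / _rms(shaped))


def mix_at_snr(signal, noise, snr_db: float) -> np.ndarray:
    """Scale a noise segment to sit ``snr_db`` below the signal RMS and add it.

    The noise must be at least as long as the signal; a leading segment is
    used. Warns if the mixture clips full scale.
    """
    s = np.asarray(signal, dtype=float)
    n = np.asarray(noise, dtype=float)
    if len(n) < len(s):
        raise ValueError("noise must be at least as long as the signal")
    n = n[: len(s)]
    rs, rn = _rms(s), _rms(n)
    if rs < 1e-12 or rn < 1e-12:
        raise ValueError("silent signal or noise")
    gain = rs / (rn * 10.0 ** (snr_db / 20.0))
    mixed = s + gain * n
    if np.max(np.abs(mixed)) > 1.0:
        warnings.warn("mixture clips full scale", stacklevel=2)
    return mixed


def prepare_stimulus(
    token_or_audio,
    noise: np.ndarray,
    disguise_spec: DisguiseSpec | None = None,
    mix: MixSpec | None = None,
    noise_offset: int = 0,
    pad_s: float = 0.2,
    sample_rate: int = SAMPLE_RATE,
) -> np.ndarray:
    """Full preparation chain: disguise, normalize, pad, and embed in noise.

    The token is gated into a noise stretch of token length plus ``pad_s``
    seconds of leading and trailing noise, at the mix's SNR, with the noise
    segment taken from ``noise`` starting at ``noise_offset`` samples.
    """
    if disguise_spec is None:
        disguise_spec = DisguiseSpec()
    if mix is None:
        mix = MixSpec()
    y = disguise(token_or_audio, disguise_spec, sample_rate=sample_rate)
    y = rms_normalize(y, mix.target_rms_db)
    pad = int(round(pad_s * sample_rate))
    padded = np.concatenate([np.zeros(pad), y, np.zeros(pad)])
    seg = noise[noise_offset : noise_offset + len(padded)]
    if len(seg) < len(padded):
        raise ValueError("noise too short for the requested gate")
    rs = _rms(y)  # SNR defined on the token, not the padding
    gain = rs / (_rms(seg) * 10.0 ** (mix.snr_db / 20.0))
    return padded + gain * seg


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a mono PCM WAV into float64 in [-1, 1]."""
    sr, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("expected mono audio")
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return sr, np.asarray(data, dtype=float)


def write_wav(path, audio, sample_rate: int = SAMPLE_RATE) -> None:
    """Write float audio as 16-bit PCM, clipping to full scale."""
    x = np.clip(np.asarray(audio, dtype=float), -1.0, 1.0)
    wavfile.write(path, sample_rate, (x * 32767).astype(np.int16))
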