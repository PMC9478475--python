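"""Seven-dimensional acoustic parameterization of vowel tokens.

A vowel production is summarized by the first three discrete-cosine-transform
coefficients of its Bark-scaled F1 and F2 trajectories — interpretable as the
trajectory's mean, slope, and curvature — plus the vowel duration as a seventh
dimension. Formant trajectories may come directly from the synthetic generator
or be measured from audio with an autocorrelation-LPC tracker.

Conventions fixed here (any consistent linear scaling of the DCT is equivalent
after downstream z-scoring):

* Bark conversion uses Traunmüller's rational form
  ``z = 26.81 f / (1960 + f) - 0.53``.
* Trajectories are linearly resampled to a fixed number of points (default 20)
  before the DCT, so coefficients are comparable across durations; duration
  information is carried solely by the seventh dimension.
* DCT-II coefficients are scaled such that ``c0`` equals the arithmetic mean
  of the resampled track.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.fft import dct as _scipy_dct
from scipy.linalg import solve_toeplitz
from scipy.signal import resample_poly

__all__ = [
    "FormantTrack",
    "FeatureVector",
    "hz_to_bark",
    "bark_to_hz",
    "dct_coefficients",
    "measure_formants",
    "featurize",
    "featurize_word",
    "feature_table",
]

_BARK_A = 26.81
_BARK_B = 1960.0
_BARK_C = 0.53

FEATURE_COLUMNS = ["f1_c0", "f1_c1", "f1_c2", "f2_c0", "f2_c1", "f2_c2", "duration"]


@dataclass
class FormantTrack:
    """Measured F1/F2 trajectory in Hz with uniform frame times."""

    times: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    ceiling: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.f1 = np.asarray(self.f1, dtype=float)
        self.f2 = np.asarray(self.f2, dtype=float)
        if not (len(self.times) == len(self.f1) == len(self.f2)):
            raise ValueError("times, f1 and f2 must have equal lengths")
        if np.any(self.f1 <= 0) or np.any(self.f2 <= self.f1):
            raise ValueError("require 0 < f1 < f2 elementwise")
        if np.any(self.f2 >= self.ceiling):
            raise ValueError("formants must lie below the analysis ceiling")


@dataclass
class FeatureVector:
    """The 7-D (Bark-DCT + duration) representation of one word for one talker."""

    talker_id: str
    word_id: str
    pair_id: str
    f1_c0: float
    f1_c1: float
    f1_c2: float
    f2_c0: float
    f2_c1: float
    f2_c2: float
    duration: float

    def values(self) -> np.ndarray:
        v = np.array(
            [self.f1_c0, self.f1_c1, self.f1_c2, self.f2_c0, self.f2_c1, self.f2_c2, self.duration]
        )
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite feature value")
        return v


def hz_to_bark(f):
    """Convert frequency in Hz to the Bark critical-band scale.

    Uses Traunmüller's rational approximation; vectorized over arrays.
    Raises for negative frequencies.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("negative frequency")
    out = _BARK_A * f / (_BARK_B + f) - _BARK_C
    return float(out) if out.ndim == 0 else out


def bark_to_hz(z):
    """Inverse of :func:`hz_to_bark` (valid for z > -0.53)."""
    z = np.asarray(z, dtype=float)
    out = _BARK_B * (z + _BARK_C) / (_BARK_A - (z + _BARK_C))
    return float(out) if out.ndim == 0 else out


def dct_coefficients(track, n_coef: int = 3, n_resample: int = 20) -> tuple[float, ...]:
    """First ``n_coef`` DCT-II coefficients of a trajectory.

    The track is linearly resampled to ``n_resample`` uniform points first.
    Scaling is chosen so that ``c0`` is the arithmetic mean of the resampled
    track; ``c1`` and ``c2`` are the k=1,2 cosine loadings under the same
    scaling (positive ``c1`` = falling trajectory).
    """
    x = np.asarray(track, dtype=float)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("track must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in track")
    if len(x) != n_resample:
        t_old = np.linspace(0.0, 1.0, len(x))
        t_new = np.linspace(0.0, 1.0, n_resample)
        x = np.interp(t_new, t_old, x)
    # scipy DCT-II (norm=None): y_k = 2 * sum_n x_n cos(pi k (2n+1) / (2N))
    y = _scipy_dct(x, type=2, norm=None)
    coefs = y[:n_coef] / (2.0 * n_resample)
    return tuple(float(c) for c in coefs)


def _lpc(frame: np.ndarray, order: int) -> np.ndarray | None:
    """Autocorrelation-method LPC coefficients a_1..a_p (prediction filter
    A(z) = 1 - sum a_k z^-k), or None for a degenerate frame."""
    r = np.correlate(frame, frame, mode="full")[len(frame) - 1 : len(frame) + order]
    if r[0] <= 0:
        return None
    r = r / r[0]
    r[0] += 1e-9  # ridge for numerical stability
    try:
        a = solve_toeplitz((r[:order], r[:order]), r[1 : order + 1])
    except np.linalg.LinAlgError:
        return None
    return a


def _formants_from_lpc(a: np.ndarray, sr: float, max_bandwidth: float, ceiling: float) -> np.ndarray:
    poly = np.concatenate(([1.0], -a))
    roots = np.roots(poly)
    roots = roots[np.imag(roots) > 0]
    freqs = np.angle(roots) * sr / (2.0 * math.pi)
    with np.errstate(divide="ignore"):
        bws = -np.log(np.abs(roots)) * sr / math.pi
    keep = (freqs > 90.0) & (freqs < ceiling - 50.0) & (bws < max_bandwidth) & (bws > 0)
    return np.sort(freqs[keep])


def measure_formants(
    audio,
    sample_rate: int,
    ceiling: float = 5500.0,
    frame_step: float = 0.002,
    frame_length: float = 0.045,
    n_formants: int = 4,
    pre_emphasis: float = 0.97,
    max_bandwidth: float = 400.0,
) -> FormantTrack:
    """Track F1/F2 with frame-wise autocorrelation LPC.

    The audio is resampled to twice the formant ceiling, pre-emphasized, cut
    into Hamming-windowed frames every ``frame_step`` seconds, and each
    frame's LPC polynomial (order ``2 + 2 * n_formants``) is root-solved.
    Roots with bandwidth below ``max_bandwidth`` count as formants; frames
    with fewer than two valid formants are interpolated from neighbors.
    """
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("audio must be non-empty and mono")
    if not 4000.0 <= ceiling <= 8000.0:
        raise ValueError("ceiling must lie in [4000, 8000] Hz")
    if np.sqrt(np.mean(x**2)) < 1e-8:
        raise ValueError("audio is silent")

    sr2 = int(round(2 * ceiling))
    g = math.gcd(sr2, int(sample_rate))
    x = resample_poly(x, sr2 // g, int(sample_rate) // g)
    x = np.append(x[0], x[1:] - pre_emphasis * x[:-1])

    win = int(round(frame_length * sr2))
    hop = max(1, int(round(frame_step * sr2)))
    order = 2 + 2 * n_formants
    if len(x) < win:
        x = np.pad(x, (0, win - len(x)))
    window = np.hamming(win)

    starts = np.arange(0, len(x) - win + 1, hop)
    times = (starts + win / 2) / sr2
    f1 = np.full(len(starts), np.nan)
    f2 = np.full(len(starts), np.nan)
    peak = np.max(np.abs(x))
    for i, s in enumerate(starts):
        frame = x[s : s + win] * window
        if np.max(np.abs(frame)) < 1e-6 * peak:
            continue
        a = _lpc(frame, order)
        if a is None:
            continue
        ff = _formants_from_lpc(a, sr2, max_bandwidth, ceiling)
        if len(ff) >= 2:
            f1[i], f2[i] = ff[0], ff[1]

    valid = np.isfinite(f1) & np.isfinite(f2)
    if not np.any(valid):
        raise ValueError("no analyzable voiced frames found")
    f1 = np.interp(times, times[valid], f1[valid])
    f2 = np.interp(times, times[valid], f2[valid])
    f2 = np.maximum(f2, f1 + 1.0)  # guard the ordering invariant at interpolation seams
    return FormantTrack(times=times, f1=f1, f2=f2, ceiling=ceiling)


def _track_features(f1_hz, f2_hz, n_resample: int) -> tuple[float, ...]:
    b1 = hz_to_bark(np.asarray(f1_hz, dtype=float))
    b2 = hz_to_bark(np.asarray(f2_hz, dtype=float))
    return dct_coefficients(b1, 3, n_resample) + dct_coefficients(b2, 3, n_resample)


def featurize(token, n_resample: int = 20, **measure_kwargs) -> FeatureVector:
    """Reduce a vowel token to its 7-D feature vector.

    Uses the token's formant trajectories when present; otherwise measures
    them from the token's audio via :func:`measure_formants`.
    """
    f1, f2 = token.f1_track, token.f2_track
    if f1 is None or f2 is None:
        if token.audio is None:
            raise ValueError("token has neither formant tracks nor audio")
        tr = measure_formants(token.audio, token.sample_rate, **measure_kwargs)
        f1, f2 = tr.f1, tr.f2
    c = _track_features(f1, f2, n_resample)
    return FeatureVector(
        talker_id=token.talker_id,
        word_id=token.word_id,
        pair_id=token.pair_id,
        f1_c0=c[0],
        f1_c1=c[1],
        f1_c2=c[2],
        f2_c0=c[3],
        f2_c1=c[4],
        f2_c2=c[5],
        duration=float(token.duration),
    )


def featurize_word(tokens, n_resample: int = 20) -> FeatureVector:
    """Per-word feature vector: the coefficient-wise mean across repetitions."""
    tokens = list(tokens)
    if not tokens:
        raise ValueError("no tokens given")
    vecs = [featurize(t, n_resample=n_resample) for t in tokens]
    ids = {(v.talker_id, v.word_id, v.pair_id) for v in vecs}
    if len(ids) != 1:
        raise ValueError("repetitions must come from one talker/word/pair")
    mean = np.mean([v.values() for v in vecs], axis=0)
    t0 = vecs[0]
    return FeatureVector(t0.talker_id, t0.word_id, t0.pair_id, *map(float, mean))


def feature_table(tokens, n_resample: int = 20) -> pd.DataFrame:
    """Featurize a token collection into one row per talker x word.

    Repetitions of the same word are averaged in coefficient space.
    """
    groups: dict[tuple, list] = {}
    for t in tokens:
        groups.setdefault((t.talker_id, t.word_id, t.pair_id), []).append(t)
    rows = []
    for key in sorted(groups):
        v = featurize_word(groups[key], n_resample=n_resample)
        rows.append(
            {
                "talker_id": v.talker_id,
                "word_id": v.word_id,
                "pair_id": v.pair_id,
                **{c: getattr(v, c) for c in FEATURE_COLUMNS},
            }
        )
    return pd.DataFrame(rows)
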