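"""Synthetic talkers, vowel productions, and simulated 2AFC responses.

The generator emulates the data-generating conditions of an own-voice
word-recognition study: a cohort of adult female talkers each producing both
members of a set of Cantonese-style vowel minimal pairs twice, and simulated
listeners responding in a personalized two-alternative forced-choice task.

Each talker carries a per-pair *contrast separation* parameter ``delta``: the
expected trajectories of a pair's two words differ by ``delta`` times the
canonical contrast between the pair's two vowel nuclei (quality and/or
duration). ``delta = 0`` collapses the pair; ``delta = 1`` reproduces the
canonical contrast. Deltas are drawn log-normally across talkers so that
ranked contrastiveness groups A-E are all populated with overlapping,
decreasing distance distributions.

Audio, when requested, is source-filter synthesis: a periodic glottal pulse
source at the talker's f0 through cascaded second-order resonators at the
trajectory's formant values (F3 held constant), so that LPC formant
measurement can recover the generating trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit
from scipy.stats import lognorm

from .stimuli import perception_stimuli

__all__ = [
    "TalkerSpec",
    "VowelToken",
    "ResponseGenParams",
    "make_cohort",
    "synthesize_token",
    "generate_productions",
    "synthesize_vowel",
    "simulate_trials",
]

SAMPLE_RATE = 44_100
N_TRACK_POINTS = 20  # uniform time samples per vowel trajectory

# Canonical nucleus targets for an adult female voice:
# (F1 start, F1 end, F2 start, F2 end, duration s)
VOWEL_SPACE: dict[str, tuple[float, float, float, float, float]] = {
    "a": (850.0, 880.0, 1500.0, 1470.0, 0.14),
    "aa": (1000.0, 930.0, 1420.0, 1340.0, 0.28),
    "ai": (850.0, 450.0, 1500.0, 2300.0, 0.19),
    "aai": (1000.0, 500.0, 1400.0, 2200.0, 0.30),
    "ei": (550.0, 400.0, 2200.0, 2600.0, 0.22),
    "o": (650.0, 670.0, 1050.0, 1015.0, 0.20),
    "ou": (550.0, 420.0, 1050.0, 850.0, 0.24),
    "au": (850.0, 500.0, 1400.0, 1000.0, 0.19),
    "aau": (1000.0, 550.0, 1350.0, 950.0, 0.30),
}


@dataclass
class TalkerSpec:
    """One synthetic talker: voice parameters plus per-pair contrast separation."""

    talker_id: str
    f0_base: float
    formant_shift: np.ndarray  # multiplicative idiosyncrasy, one factor per formant
    contrast_sep: dict[str, float]  # pair_id -> delta >= 0

    def __post_init__(self) -> None:
        self.formant_shift = np.asarray(self.formant_shift, dtype=float)
        if self.f0_base <= 0:
            raise ValueError("f0_base must be positive")
        if np.any(self.formant_shift <= 0):
            raise ValueError("formant_shift factors must be positive")
        if any(d < 0 for d in self.contrast_sep.values()):
            raise ValueError("contrast separation delta must be >= 0")


@dataclass
class VowelToken:
    """One production of one word by one talker."""

    talker_id: str
    word_id: str
    pair_id: str
    repetition: int
    f1_track: np.ndarray | None
    f2_track: np.ndarray | None
    duration: float
    audio: np.ndarray | None = None
    sample_rate: int = SAMPLE_RATE
    f0_track: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for tr in (self.f1_track, self.f2_track):
            if tr is not None:
                tr = np.asarray(tr, dtype=float)
                if len(tr) == 0 or np.any(tr <= 0):
                    raise ValueError("formant tracks must be non-empty and positive")


# Reference effect set for response generation (log-odds): a high baseline
# accuracy, a small own-voice benefit, a slow improvement across trials,
# generally decreasing accuracy from more to less contrastive groups, and
# small interactions. Used as the generator's defaults.
REFERENCE_EFFECTS = {
    "intercept": 1.66,
    "own": 0.23,
    "trial": 0.07,
    "group": (-0.21, 0.27, 0.21, 0.26),
    "own_group": (0.31, -0.41, 0.31, -0.04),
    "trial_group": (0.08, -0.04, -0.03, -0.04),
    "own_trial": 0.03,
}


def _identity3() -> np.ndarray:
    return np.eye(3)


@dataclass
class ResponseGenParams:
    """Generating parameters of the hierarchical 2AFC response model.

    Fixed effects are on the log-odds scale and follow the analysis model's
    coding: voice match treatment-coded (other voice = reference), group
    forward-difference coded (adjacent-level differences), trial centered and
    scaled. Random effects are correlated by-participant intercepts and
    slopes for voice match and trial. Reaction times are log-normal (ms) with
    a contamination fraction falling outside the [200, 5000] ms window.
    """

    b_intercept: float = REFERENCE_EFFECTS["intercept"]
    b_own: float = REFERENCE_EFFECTS["own"]
    b_trial: float = REFERENCE_EFFECTS["trial"]
    b_group: tuple = REFERENCE_EFFECTS["group"]
    b_own_group: tuple = REFERENCE_EFFECTS["own_group"]
    b_trial_group: tuple = REFERENCE_EFFECTS["trial_group"]
    b_own_trial: float = REFERENCE_EFFECTS["own_trial"]
    re_sd: tuple = (0.5, 0.3, 0.1)  # intercept, own-slope, trial-slope
    re_corr: np.ndarray = field(default_factory=_identity3)
    rt_meanlog: float = math.log(900.0)  # median RT 900 ms
    rt_sdlog: float = 0.35
    rt_contamination: float = 0.02

    def __post_init__(self) -> None:
        self.re_corr = np.asarray(self.re_corr, dtype=float)
        if any(s < 0 for s in self.re_sd):
            raise ValueError("random-effect SDs must be non-negative")
        if self.re_corr.shape != (3, 3) or not np.allclose(self.re_corr, self.re_corr.T):
            raise ValueError("re_corr must be a symmetric 3x3 matrix")
        if not np.allclose(np.diag(self.re_corr), 1.0):
            raise ValueError("re_corr must have unit diagonal")
        if np.any(np.linalg.eigvalsh(self.re_corr) <= 0):
            raise ValueError("re_corr must be positive definite")
        if not 0.0 <= self.rt_contamination < 1.0:
            raise ValueError("rt_contamination must be in [0, 1)")

    def coefficient_vector(self) -> np.ndarray:
        """Fixed effects in the analysis design-matrix column order."""
        return np.concatenate(
            [
                [self.b_intercept, self.b_own, self.b_trial],
                self.b_group,
                self.b_own_group,
                self.b_trial_group,
                [self.b_own_trial],
            ]
        )


def make_cohort(
    n_talkers: int,
    n_pairs: int,
    seed: int,
    delta_median: float = 1.0,
    delta_log_sd: float = 0.5,
    formant_shift_sd: float = 0.05,
) -> tuple[list[TalkerSpec], pd.DataFrame]:
    """Draw a talker cohort and the word roster they produce.

    Deltas (per talker, per pair) are log-normal with the given median and
    log-SD. The first 13 pairs are the perception-stimulus roster; additional
    pairs recycle its vowel contrasts under generic pair ids.
    """
    if n_talkers < 5:
        raise ValueError("need at least 5 talkers")
    if n_pairs < 1:
        raise ValueError("need at least 1 pair")
    rng = np.random.default_rng(seed)

    base = perception_stimuli()
    rows = []
    for j in range(n_pairs):
        src = base.iloc[j % len(base)]
        if j < len(base):
            rows.append(src[["pair_id", "word_1", "word_2", "nucleus_1", "nucleus_2"]].to_dict())
        else:
            rows.append(
                {
                    "pair_id": f"xpair{j + 1:02d}",
                    "word_1": f"xw{j + 1:02d}a",
                    "word_2": f"xw{j + 1:02d}b",
                    "nucleus_1": src["nucleus_1"],
                    "nucleus_2": src["nucleus_2"],
                }
            )
    roster = pd.DataFrame(rows)

    talkers = []
    for i in range(n_talkers):
        deltas = lognorm.ppf(
            rng.random(n_pairs), s=delta_log_sd, scale=delta_median
        )
        talkers.append(
            TalkerSpec(
                talker_id=f"T{i + 1:02d}",
                f0_base=float(rng.uniform(180.0, 240.0)),
                formant_shift=np.exp(rng.normal(0.0, formant_shift_sd, size=2)),
                contrast_sep={p: float(d) for p, d in zip(roster["pair_id"], deltas)},
            )
        )
    return talkers, roster


def _word_targets(roster_row, member: int, delta: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Expected (f1_track, f2_track, duration) for one pair member.

    Word 1 sits at its canonical nucleus target; word 2 is displaced from it
    toward the second nucleus by ``delta`` (durations interpolate in log
    space). The trajectory eases between onset and offset targets with a
    raised-cosine ramp, giving naturalistic curvature.
    """
    a = np.array(VOWEL_SPACE[roster_row["nucleus_1"]])
    b = np.array(VOWEL_SPACE[roster_row["nucleus_2"]])
    if member == 1:
        tgt = a
    else:
        tgt = a + delta * (b - a)
        tgt[4] = a[4] * math.exp(delta * (math.log(b[4]) - math.log(a[4])))
    t = np.linspace(0.0, 1.0, N_TRACK_POINTS)
    ease = 0.5 * (1.0 - np.cos(math.pi * t))
    # clamp extrapolated targets (large delta draws) to a physiological range
    f1 = np.clip(tgt[0] + (tgt[1] - tgt[0]) * ease, 200.0, 1300.0)
    f2 = np.clip(tgt[2] + (tgt[3] - tgt[2]) * ease, 600.0, 3000.0)
    return f1, f2, float(np.clip(tgt[4], 0.05, 0.6))


def synthesize_token(
    talker: TalkerSpec,
    word_id: str,
    roster: pd.DataFrame,
    repetition: int = 1,
    jitter: float = 0.04,
    with_audio: bool = False,
    rng: np.random.Generator | None = None,
) -> VowelToken:
    """Generate one production of ``word_id`` by ``talker``.

    The word's expected trajectory is warped by the talker's multiplicative
    formant idiosyncrasy and delta-scaled contrast separation, then perturbed
    by multiplicative repetition noise of log-magnitude ``jitter``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    hit = roster[(roster["word_1"] == word_id) | (roster["word_2"] == word_id)]
    if hit.empty:
        raise KeyError(f"unknown word {word_id!r}")
    row = hit.iloc[0]
    member = 1 if row["word_1"] == word_id else 2
    delta = talker.contrast_sep[row["pair_id"]]

    f1, f2, dur = _word_targets(row, member, delta)
    f1 = f1 * talker.formant_shift[0]
    f2 = f2 * talker.formant_shift[1]
    if jitter > 0:
        f1 = f1 * math.exp(rng.normal(0.0, jitter)) * np.exp(rng.normal(0.0, jitter / 4, f1.shape))
        f2 = f2 * math.exp(rng.normal(0.0, jitter)) * np.exp(rng.normal(0.0, jitter / 4, f2.shape))
        dur = dur * math.exp(rng.normal(0.0, jitter))
    f2 = np.maximum(f2, f1 * 1.15)  # keep formants ordered after noise

    audio = None
    f0_track = None
    if with_audio:
        f0_track = np.full(N_TRACK_POINTS, talker.f0_base)
        audio = synthesize_vowel(f1, f2, dur, talker.f0_base)
    return VowelToken(
        talker_id=talker.talker_id,
        word_id=word_id,
        pair_id=row["pair_id"],
        repetition=repetition,
        f1_track=f1,
        f2_track=f2,
        duration=dur,
        audio=audio,
        f0_track=f0_track,
    )


def generate_productions(
    talkers: list[TalkerSpec],
    roster: pd.DataFrame,
    jitter: float = 0.04,
    with_audio: bool = False,
    seed: int = 0,
    repetitions: int = 2,
) -> list[VowelToken]:
    """All productions for a cohort: each talker, each word, ``repetitions`` times."""
    rng = np.random.default_rng(seed)
    words = []
    for _, row in roster.iterrows():
        for w in (row["word_1"], row["word_2"]):
            if w not in words:
                words.append(w)
    tokens = []
    for talker in talkers:
        for w in words:
            for rep in range(1, repetitions + 1):
                tokens.append(
                    synthesize_token(
                        talker, w, roster, repetition=rep, jitter=jitter,
                        with_audio=with_audio, rng=rng,
                    )
                )
    return tokens


def synthesize_vowel(
    f1_track,
    f2_track,
    duration: float,
    f0: float,
    sample_rate: int = SAMPLE_RATE,
    f3: float = 3200.0,
    bandwidths: tuple[float, float, float] = (90.0, 110.0, 170.0),
    aspiration_db: float = -22.0,
) -> np.ndarray:
    """Source-filter synthesis of a vowel with time-varying F1/F2.

    A periodic impulse source at ``f0`` — mixed with low-level aspiration
    noise so the spectral envelope is defined between harmonics — is low-pass
    shaped (glottal roll-off) and passed through cascaded second-order
    resonators at F1(t), F2(t) and a constant F3. The aspiration noise uses a
    fixed internal seed so synthesis is a pure function of its arguments.
    Output is RMS-normalized to 0.1 full scale.
    """
    n = int(round(duration * sample_rate))
    if n < 8:
        raise ValueError("duration too short to synthesize")
    f1 = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(f1_track)), f1_track)
    f2 = np.interp(np.linspace(0, 1, n), np.linspace(0, 1, len(f2_track)), f2_track)

    # impulse train at f0 with band-limited (windowed-sinc) pulses at exact
    # fractional positions; grid quantization would otherwise introduce
    # spurious subharmonic modulation
    half = 16
    src = np.zeros(n + 2 * half)
    period = sample_rate / f0
    offsets = np.arange(-half, half + 1)
    for t in np.arange(0.0, n - 1, period):
        center = int(round(t))
        frac = t - center
        # window centered on the *fractional* pulse position so every pulse
        # has identical shape (an off-center window would modulate pulse
        # energy with the fractional phase and inject subharmonics)
        arg = offsets - frac
        win = 0.5 * (1.0 + np.cos(np.pi * arg / (half + 1)))
        src[center + half - half : center + half + half + 1] += win * np.sinc(arg)
    src = src[half:-half]
    src = src + 10.0 ** (aspiration_db / 20.0) * np.random.default_rng(0).standard_normal(n)
    # -12 dB/oct glottal roll-off
    src = lfilter([1.0], [1.0, -0.985], src)
    src = lfilter([1.0], [1.0, -0.985], src)

    y = _cascade_time_varying(src, f1, bandwidths[0], sample_rate)
    y = _cascade_time_varying(y, f2, bandwidths[1], sample_rate)
    r3 = math.exp(-math.pi * bandwidths[2] / sample_rate)
    b3 = 2.0 * r3 * math.cos(2.0 * math.pi * f3 / sample_rate)
    c3 = -r3 * r3
    y = lfilter([1.0 - b3 - c3], [1.0, -b3, -c3], y)
    # lip-radiation characteristic (+6 dB/oct); also removes the DC rumble
    # the glottal roll-off would otherwise leave in the aspiration noise
    y = np.diff(y, prepend=0.0)

    rms = math.sqrt(float(np.mean(y**2)))
    return 0.1 * y / rms


def _cascade_time_varying(x: np.ndarray, freq: np.ndarray, bw: float, sr: int) -> np.ndarray:
    r = math.exp(-math.pi * bw / sr)
    b = 2.0 * r * np.cos(2.0 * math.pi * freq / sr)
    c = -r * r
    a = 1.0 - b - c
    y = np.empty_like(x)
    y1 = y2 = 0.0
    for i in range(len(x)):
        yi = a[i] * x[i] + b[i] * y1 + c * y2
        y2 = y1
        y1 = yi
        y[i] = yi
    return y


def simulate_trials(
    design: pd.DataFrame,
    params: ResponseGenParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate 2AFC responses for an experiment trial table.

    ``design`` needs columns ``participant_id, voice_id, own_voice, pair_id,
    word_id, trial_index, group``. The linear predictor is assembled exactly
    as the analysis design matrix prescribes (treatment-coded voice match,
    forward-difference-coded group, centered+scaled trial, the stated
    interactions, and correlated by-participant random intercepts/slopes),
    correctness is Bernoulli(logistic(eta)), and RTs are log-normal with the
    configured contamination outside [200, 5000] ms.
    """
    from . import inference  # local import to keep module load order simple

    if params is None:
        params = ResponseGenParams()
    rng = np.random.default_rng(seed)
    df = design.copy().reset_index(drop=True)

    n_group_levels = df["group"].nunique()
    if n_group_levels > len(params.b_group) + 1:
        raise ValueError(
            f"design has {n_group_levels} group levels but params encode "
            f"{len(params.b_group) + 1}"
        )

    X, _ = inference.fixed_effect_matrix(df)
    beta = params.coefficient_vector()
    participants = np.unique(df["participant_id"])
    pidx = pd.Categorical(df["participant_id"], categories=participants).codes
    sd = np.asarray(params.re_sd, dtype=float)
    L = np.linalg.cholesky(params.re_corr)
    z = rng.standard_normal((len(participants), 3))
    U = (z @ L.T) * sd
    eta = X @ beta + np.sum(X[:, :3] * U[pidx], axis=1)
    p = expit(eta)
    correct = rng.random(len(df)) < p

    words_by_pair: dict[str, set] = {}
    for pair, w in zip(df["pair_id"], df["word_id"]):
        words_by_pair.setdefault(pair, set()).add(w)
    other = np.array(
        [
            next(iter(words_by_pair[pair] - {w}), w)
            for pair, w in zip(df["pair_id"], df["word_id"])
        ]
    )

    # truncated log-normal RTs via inverse CDF, plus out-of-range contaminants
    lo, hi = 200.0, 5000.0
    dist = lognorm(s=params.rt_sdlog, scale=math.exp(params.rt_meanlog))
    u = rng.uniform(dist.cdf(lo), dist.cdf(hi), size=len(df))
    rt = dist.ppf(u)
    contam = rng.random(len(df)) < params.rt_contamination
    fast = rng.random(len(df)) < 0.5
    rt = np.where(contam & fast, rng.uniform(50.0, 199.0, len(df)), rt)
    rt = np.where(contam & ~fast, rng.uniform(5001.0, 8000.0, len(df)), rt)

    out = df.copy()
    out["correct"] = correct
    out["chosen_word_id"] = np.where(correct, df["word_id"], other)
    out["rt_ms"] = rt
    return out
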