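"""Personalized 2AFC experiment construction and response bookkeeping.

Every participant's roster contains, for each minimal pair where she produced
both words, both words as spoken by every member of her contrastiveness group
for that pair (including herself), four times each. Trials are fully
randomized and split across four blocks. Responses are scored against the
intended word, and reaction times outside [200, 5000] ms are removed before
analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .stimuli import perception_stimuli, unique_words

__all__ = [
    "perception_stimuli",
    "unique_words",
    "build_roster",
    "build_all_trials",
    "randomize_blocks",
    "practice_trials",
    "analysis_trials",
    "filter_rt",
    "score_responses",
    "stimulus_filename",
]


def _pair_words(roster: pd.DataFrame) -> dict[str, tuple[str, str]]:
    return {r["pair_id"]: (r["word_1"], r["word_2"]) for _, r in roster.iterrows()}


def build_roster(
    participant_id: str,
    assignments: pd.DataFrame,
    word_roster: pd.DataFrame | None = None,
    availability: set[tuple[str, str]] | None = None,
    reps: int = 4,
) -> pd.DataFrame:
    """Build one participant's trial roster (unordered).

    ``assignments`` holds columns ``pair_id, talker_id, group`` (one row per
    talker and pair). ``availability``, when given, is the set of
    ``(talker_id, word_id)`` productions that exist; a voice missing either
    word of a pair is dropped for both words of that pair (the removal of one
    item entails the removal of two), and a pair missing the participant's
    own production is dropped entirely.

    Returns one row per (pair, word, voice, repetition) with the
    participant's group label for the pair.
    """
    if word_roster is None:
        word_roster = perception_stimuli()
    mine = assignments[assignments["talker_id"] == participant_id]
    if mine.empty:
        raise ValueError(f"participant {participant_id!r} absent from assignments")
    words = _pair_words(word_roster)

    def available(voice: str, pair: str) -> bool:
        if availability is None:
            return True
        w1, w2 = words[pair]
        return (voice, w1) in availability and (voice, w2) in availability

    rows = []
    for _, row in mine.iterrows():
        pair, group = row["pair_id"], row["group"]
        if pair not in words or not available(participant_id, pair):
            continue
        members = assignments[
            (assignments["pair_id"] == pair) & (assignments["group"] == group)
        ]["talker_id"]
        for voice in members:
            if not available(voice, pair):
                continue
            for word in words[pair]:
                for rep in range(1, reps + 1):
                    rows.append(
                        {
                            "participant_id": participant_id,
                            "voice_id": voice,
                            "own_voice": voice == participant_id,
                            "pair_id": pair,
                            "word_id": word,
                            "repetition": rep,
                            "group": group,
                        }
                    )
    return pd.DataFrame(rows)


def randomize_blocks(roster: pd.DataFrame, n_blocks: int = 4, seed: int = 0) -> pd.DataFrame:
    """Uniformly permute a roster and split it into near-equal blocks.

    Adds ``trial_index`` (1-based, in presentation order) and ``block``
    (1..n_blocks, contiguous, sizes differing by at most 1).
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    if roster.empty:
        raise ValueError("empty roster")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(roster))
    out = roster.iloc[order].reset_index(drop=True)
    out["trial_index"] = np.arange(1, len(out) + 1)
    sizes = np.full(n_blocks, len(out) // n_blocks)
    sizes[: len(out) % n_blocks] += 1
    out["block"] = np.repeat(np.arange(1, n_blocks + 1), sizes)
    return out


def build_all_trials(
    assignments: pd.DataFrame,
    word_roster: pd.DataFrame | None = None,
    availability: set[tuple[str, str]] | None = None,
    reps: int = 4,
    n_blocks: int = 4,
    seed: int = 0,
) -> pd.DataFrame:
    """Rosters for every participant in ``assignments``, randomized per participant."""
    rng = np.random.default_rng(seed)
    parts = []
    for pid in sorted(assignments["talker_id"].unique()):
        roster = build_roster(pid, assignments, word_roster, availability, reps)
        if roster.empty:
            continue
        parts.append(
            randomize_blocks(roster, n_blocks=n_blocks, seed=int(rng.integers(2**31)))
        )
    return pd.concat(parts, ignore_index=True)


def practice_trials(roster: pd.DataFrame, n: int = 3, seed: int = 0) -> pd.DataFrame:
    """Sample ``n`` practice trials from a participant's roster.

    Practice rows are flagged ``is_practice = True`` (block 0, negative trial
    indices) so downstream analysis can exclude them.
    """
    if n < 1 or roster.empty:
        return roster.iloc[0:0].assign(is_practice=True, block=0, trial_index=[])
    rng = np.random.default_rng(seed)
    pick = roster.iloc[rng.choice(len(roster), size=min(n, len(roster)), replace=False)]
    out = pick.reset_index(drop=True).copy()
    out["is_practice"] = True
    out["block"] = 0
    out["trial_index"] = -np.arange(len(out), 0, -1)
    return out


def analysis_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop practice trials (rows flagged ``is_practice``) before analysis."""
    if "is_practice" in trials.columns:
        return trials[~trials["is_practice"].astype(bool)].reset_index(drop=True)
    return trials


def filter_rt(
    trials: pd.DataFrame, low: float = 200.0, high: float = 5000.0
) -> tuple[pd.DataFrame, dict]:
    """Remove trials with reaction times under ``low`` or over ``high`` ms.

    Bounds are inclusive on the kept side (rt == 200 ms is kept). Returns the
    kept trials and a removal report.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    if np.any(rt < 0):
        raise ValueError("negative reaction time")
    keep = (rt >= low) & (rt <= high)
    report = {
        "n_total": int(len(trials)),
        "n_removed": int((~keep).sum()),
        "fraction_removed": float((~keep).mean()) if len(trials) else 0.0,
    }
    return trials[keep].reset_index(drop=True), report


def score_responses(trials: pd.DataFrame) -> pd.DataFrame:
    """Score chosen words against intended words (adds/overwrites ``correct``)."""
    out = trials.copy()
    out["correct"] = out["chosen_word_id"] == out["word_id"]
    return out


def stimulus_filename(voice_id: str, word_id: str, disguised: bool = True) -> str:
    """Canonical stimulus file name ``<voice>_<word>_<disguised|plain>.wav``."""
    tag = "disguised" if disguised else "plain"
    return f"{voice_id}_{word_id}_{tag}.wav"
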