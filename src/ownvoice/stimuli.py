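"""Perception-task stimulus roster: 13 Cantonese minimal pairs, level tone (T1).

Each pair differs in exactly one vowel contrast (quality and/or phonemic
length). ``chicken`` (gai1) serves as a member of two different pairs, so the
roster contains 26 pair slots but only 25 unique words.
"""

from __future__ import annotations

import pandas as pd

# (word_1 jyutping, gloss_1, word_2 jyutping, gloss_2)
_PAIRS: list[tuple[str, str, str, str]] = [
    ("gai1", "chicken", "gei1", "machine"),
    ("gai1", "chicken", "gaai1", "street"),
    ("fai1", "to wave", "fei1", "to fly"),
    ("do1", "many", "dou1", "knife"),
    ("go1", "song", "gou1", "tall"),
    ("so1", "comb", "sou1", "beard, moustache"),
    ("bo1", "ball", "bou1", "pot"),
    ("mau1", "to squat", "maau1", "cat"),
    ("cau1", "autumn", "caau1", "to copy"),
    ("kat1", "cough", "kaat1", "card"),
    ("sam1", "heart", "saam1", "shirt"),
    ("sai1", "west", "saai1", "to waste"),
    ("gwai1", "turtle", "gwaai1", "well-behaved"),
]

_INITIALS = ("gw", "b", "c", "d", "f", "g", "k", "m", "s")
_CODAS = ("i", "u", "t", "m")  # off-glides and consonantal codas


def vowel_nucleus(jyutping: str) -> str:
    """Extract the vocalic nucleus (plus off-glide) from a T1 jyutping form.

    ``gaai1 -> aai``, ``sam1 -> a``, ``kaat1 -> aa``, ``dou1 -> ou``.
    """
    w = jyutping.rstrip("123456")
    for ini in _INITIALS:
        if w.startswith(ini):
            w = w[len(ini):]
            break
    # strip a consonantal coda, but keep vocalic off-glides of diphthongs
    if w.endswith(("t", "m", "n", "p", "k")) and len(w) > 1:
        w = w[:-1]
    return w


def perception_stimuli() -> pd.DataFrame:
    """Return the 13-minimal-pair perception roster as a tidy DataFrame.

    Columns: ``pair_id, word_1, gloss_1, word_2, gloss_2, nucleus_1,
    nucleus_2``.  ``pair_id`` is ``<word_1>-<word_2>``.
    """
    rows = []
    for w1, g1, w2, g2 in _PAIRS:
        rows.append(
            {
                "pair_id": f"{w1}-{w2}",
                "word_1": w1,
                "gloss_1": g1,
                "word_2": w2,
                "gloss_2": g2,
                "nucleus_1": vowel_nucleus(w1),
                "nucleus_2": vowel_nucleus(w2),
            }
        )
    return pd.DataFrame(rows)


def unique_words(roster: pd.DataFrame | None = None) -> list[str]:
    """Unique word forms in the roster (25 for the default roster)."""
    if roster is None:
        roster = perception_stimuli()
    return sorted(set(roster["word_1"]).union(roster["word_2"]))
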