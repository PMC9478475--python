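"""Per-talker, per-minimal-pair contrastiveness scoring and group assignment.

For each minimal pair, every contributing talker's two word vectors (the 7-D
Bark-DCT + duration features) are standardized *within the pair across all
talkers*: each dimension is centered to mean 0 and scaled to SD 1 over all
word vectors of that pair. The talker's contrastiveness for the pair is the
Euclidean distance between her two standardized word vectors; a greater
distance indicates a more distinctive production. Talkers are then ranked by
distance within each pair and cut into ordered groups A (most contrastive)
through E (least contrastive) with sizes as equal as possible.
"""

from __future__ import annotations

import string
import warnings

import numpy as np
import pandas as pd

from .acoustic_features import FEATURE_COLUMNS

__all__ = [
    "zscore_features",
    "pair_distance",
    "contrast_scores",
    "assign_groups",
    "compute_contrastiveness",
    "group_sizes",
]


def zscore_features(vectors: pd.DataFrame, columns=FEATURE_COLUMNS) -> pd.DataFrame:
    """Standardize each feature dimension over all word vectors of one pair.

    Expects one row per talker x word (both pair members, all contributing
    talkers). Uses the sample SD (ddof=1); zero-variance dimensions map to 0.
    """
    if vectors["talker_id"].nunique() < 2:
        raise ValueError("need at least 2 talkers contributing to the pair")
    out = vectors.copy()
    for c in columns:
        x = vectors[c].to_numpy(dtype=float)
        mu = x.mean()
        sd = x.std(ddof=1)
        out[c] = 0.0 if sd == 0 else (x - mu) / sd
    return out


def pair_distance(vec_a, vec_b) -> float:
    """Euclidean distance between two standardized 7-D feature vectors."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("dimension mismatch")
    return float(np.sqrt(np.sum((a - b) ** 2)))


def contrast_scores(features: pd.DataFrame) -> pd.DataFrame:
    """Distance and rank per talker and pair.

    ``features`` holds one row per talker x word with the 7 feature columns
    (see :func:`ownvoice.acoustic_features.feature_table`). Talkers missing
    either word of a pair are excluded from that pair. Rank 1 is the most
    contrastive talker; ties break by talker_id.
    """
    rows = []
    for pair_id, grp in features.groupby("pair_id", sort=True):
        counts = grp.groupby("talker_id")["word_id"].nunique()
        complete = counts[counts == 2].index
        sub = grp[grp["talker_id"].isin(complete)]
        if sub["talker_id"].nunique() < 2:
            continue
        z = zscore_features(sub)
        for talker_id, tg in z.groupby("talker_id"):
            vecs = tg[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
            rows.append(
                {
                    "pair_id": pair_id,
                    "talker_id": talker_id,
                    "distance": pair_distance(vecs[0], vecs[1]),
                }
            )
    scores = pd.DataFrame(rows)
    ranked = []
    for pair_id, grp in scores.groupby("pair_id"):
        srt = grp.sort_values(["distance", "talker_id"], ascending=[False, True])
        r = pd.Series(np.arange(1, len(srt) + 1), index=srt.index)
        ranked.append(r)
    scores["rank"] = pd.concat(ranked)
    return scores.sort_values(["pair_id", "rank"]).reset_index(drop=True)


def group_sizes(n: int, n_groups: int) -> list[int]:
    """Largest-remainder split of n talkers into n_groups ordered groups.

    Remainders go to the earliest (most contrastive) groups, e.g.
    33 -> (7, 7, 7, 6, 6).
    """
    base, rem = divmod(n, n_groups)
    return [base + 1 if i < rem else base for i in range(n_groups)]


def assign_groups(
    scores: pd.DataFrame,
    n_groups: int = 5,
    size_bounds: tuple[int, int] = (5, 7),
    override: dict | None = None,
) -> pd.DataFrame:
    """Cut one pair's ranked talkers into contiguous ordered groups A, B, ...

    Talkers are sorted by descending distance (ties by talker_id) and split
    into ``n_groups`` contiguous blocks with largest-remainder balancing. If
    the resulting sizes fall outside ``size_bounds``, the bounds are relaxed
    with a warning. ``override`` maps talker_id -> group label and reproduces
    any manual regrouping; overridden labels are applied after the automatic
    assignment.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 groups")
    if scores["pair_id"].nunique() != 1:
        raise ValueError("assign_groups operates on one pair at a time")
    labels = list(string.ascii_uppercase[:n_groups])
    srt = scores.sort_values(["distance", "talker_id"], ascending=[False, True])
    sizes = group_sizes(len(srt), n_groups)
    lo, hi = size_bounds
    if any(s < lo or s > hi for s in sizes):
        warnings.warn(
            f"group sizes {sizes} fall outside bounds {size_bounds}; bounds relaxed",
            stacklevel=2,
        )
    assigned = np.repeat(labels, sizes)
    out = srt.copy()
    out["group"] = assigned
    if override:
        out["group"] = [
            override.get(t, g) for t, g in zip(out["talker_id"], out["group"])
        ]
    return out.reset_index(drop=True)


def compute_contrastiveness(
    features: pd.DataFrame,
    n_groups: int = 5,
    size_bounds: tuple[int, int] = (5, 7),
    overrides: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scores and group assignments for every pair in a feature table.

    ``overrides`` maps pair_id -> {talker_id: group label}. Returns
    ``(scores, assignments)``; assignments have columns
    ``pair_id, talker_id, distance, rank, group``.
    """
    scores = contrast_scores(features)
    parts = []
    for pair_id, grp in scores.groupby("pair_id", sort=True):
        ov = (overrides or {}).get(pair_id)
        parts.append(assign_groups(grp, n_groups=n_groups, size_bounds=size_bounds, override=ov))
    assignments = pd.concat(parts, ignore_index=True)
    return scores, assignments
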