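import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ownvoice import acoustic_features as af
from ownvoice import contrastiveness as ct
from ownvoice import synthdata

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """8 talkers x 4 pairs, trajectory-only productions at default jitter."""
    talkers, roster = synthdata.make_cohort(8, 4, seed=11)
    tokens = synthdata.generate_productions(talkers, roster, jitter=0.04, seed=12)
    return talkers, roster, tokens


@pytest.fixture(scope="session")
def full_cohort_features():
    """33 talkers x 13 pairs featurized, plus the generating deltas."""
    talkers, roster = synthdata.make_cohort(33, 13, seed=1)
    tokens = synthdata.generate_productions(talkers, roster, jitter=0.04, seed=2)
    features = af.feature_table(tokens)
    deltas = pd.DataFrame(
        [(t.talker_id, p, d) for t in talkers for p, d in t.contrast_sep.items()],
        columns=["talker_id", "pair_id", "delta"],
    )
    return features, deltas


@pytest.fixture(scope="session")
def full_assignments(full_cohort_features):
    features, _ = full_cohort_features
    scores, assignments = ct.compute_contrastiveness(features)
    return scores, assignments


def make_trial_frame(n_participants=8, n_trials=60, own_fraction=0.2, seed=0):
    """Minimal trial design frame for response simulation tests."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_participants):
        pid = f"P{i + 1:02d}"
        own = rng.random(n_trials) < own_fraction
        for t in range(n_trials):
            rows.append(
                {
                    "participant_id": pid,
                    "voice_id": pid if own[t] else "other",
                    "own_voice": bool(own[t]),
                    "pair_id": "p1",
                    "word_id": "w1" if t % 2 else "w2",
                    "trial_index": t + 1,
                    "group": "ABCDE"[i % 5],
                }
            )
    return pd.DataFrame(rows)
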