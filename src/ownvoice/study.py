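"""End-to-end simulation and parameter-recovery pipeline.

``simulate_study`` chains every stage at its default study conditions: a
33-talker cohort producing the 13-pair roster twice each, Bark-DCT
featurization, within-pair contrastiveness scoring and A-E grouping,
personalized 2AFC rosters (4 repetitions, 4 blocks), hierarchical response
simulation, and the RT filter. ``run_recovery`` then fits the analysis model
to the simulated responses and reports how well the generating coefficients
are recovered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import contrastiveness, experiment, inference, synthdata
from .acoustic_features import feature_table

__all__ = ["StudyData", "RecoveryResult", "simulate_study", "run_recovery"]


@dataclass
class StudyData:
    talkers: list
    word_roster: pd.DataFrame
    features: pd.DataFrame
    scores: pd.DataFrame
    assignments: pd.DataFrame
    trials: pd.DataFrame  # simulated responses, pre RT filter
    analyzed: pd.DataFrame  # RT-filtered
    rt_report: dict


@dataclass
class RecoveryResult:
    study: StudyData
    fit: inference.FitResult
    summary: pd.DataFrame
    generating: dict  # parameter name -> generating value


def simulate_study(
    n_talkers: int = 33,
    n_pairs: int = 13,
    reps: int = 4,
    jitter: float = 0.04,
    params: synthdata.ResponseGenParams | None = None,
    seed: int = 0,
) -> StudyData:
    """Simulate the full study at the given scale."""
    ss = np.random.SeedSequence(seed)
    s_cohort, s_prod, s_blocks, s_resp = (
        int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)
    )
    if params is None:
        params = synthdata.ResponseGenParams()

    talkers, roster = synthdata.make_cohort(n_talkers, n_pairs, seed=s_cohort)
    tokens = synthdata.generate_productions(talkers, roster, jitter=jitter, seed=s_prod)
    features = feature_table(tokens)
    scores, assignments = contrastiveness.compute_contrastiveness(features)
    trial_design = experiment.build_all_trials(
        assignments, word_roster=roster, reps=reps, seed=s_blocks
    )
    trials = synthdata.simulate_trials(trial_design, params=params, seed=s_resp)
    analyzed, rt_report = experiment.filter_rt(trials)
    return StudyData(
        talkers=talkers,
        word_roster=roster,
        features=features,
        scores=scores,
        assignments=assignments,
        trials=trials,
        analyzed=analyzed,
        rt_report=rt_report,
    )


def generating_values(params: synthdata.ResponseGenParams, names: list[str]) -> dict:
    """Map design-matrix parameter names to their generating coefficients."""
    return dict(zip(names, params.coefficient_vector()))


def run_recovery(
    seed: int = 0,
    n_talkers: int = 33,
    params: synthdata.ResponseGenParams | None = None,
    sampler: inference.SamplerConfig | None = None,
) -> RecoveryResult:
    """Simulate at full scale, fit the analysis model, summarize recovery."""
    if params is None:
        params = synthdata.ResponseGenParams()
    ss = np.random.SeedSequence(seed)
    s_study, s_fit = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    study = simulate_study(n_talkers=n_talkers, params=params, seed=s_study)
    design = inference.build_design(study.analyzed)
    if sampler is None:
        sampler = inference.SamplerConfig(seed=s_fit)
    else:
        sampler.seed = s_fit
    result = inference.fit(design, config=sampler)
    summary = result.summary()
    return RecoveryResult(
        study=study,
        fit=result,
        summary=summary,
        generating=generating_values(params, design.names),
    )
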