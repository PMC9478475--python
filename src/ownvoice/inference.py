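"""Bayesian multilevel logistic regression of 2AFC word-identification accuracy.

The model regresses per-trial correctness (Bernoulli, logit link) on:

* Voice Match, treatment-coded with Other Voice as the reference level;
* Trial number, centered and scaled;
* Contrastiveness Group (A-E), forward-difference coded so each coefficient
  is the difference between adjacent ordered levels (mu_j - mu_{j+1});
* the Voice Match x Group, Trial x Group and Voice Match x Trial interactions;
* correlated by-participant random intercepts and slopes for Voice Match and
  Trial.

Priors: Normal(0, 5) on the intercept, Normal(0, 2.5) on the remaining
population-level effects, half-Normal(2.5) on random-effect SDs, LKJ(2) on
the random-effect correlation Cholesky factor. Sampling is Hamiltonian Monte
Carlo (4 chains x 4000 iterations, 1000 warm-up by default) with a
non-centered parameterization of the random effects; convergence is judged
by split-R-hat < 1.01 and bulk ESS.

Posterior summaries report the median, the equal-tailed 95% credible
interval, the posterior mean, and the probability of direction (pd). An
effect is flagged *compelling* when the CrI excludes 0 and *weak evidence*
when the CrI includes 0 but pd >= 0.95.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._hmc import BernoulliMultilevelPosterior, SamplerConfig, run_hmc

__all__ = [
    "forward_difference_matrix",
    "fixed_effect_matrix",
    "build_design",
    "Design",
    "Priors",
    "SamplerConfig",
    "FitDiagnostics",
    "FitResult",
    "fit",
    "summarize",
]


def forward_difference_matrix(k: int) -> np.ndarray:
    """Forward-difference contrast matrix (k levels x k-1 columns).

    With this coding, fitted coefficient j estimates mu_j - mu_{j+1} (level
    means of adjacent ordered levels) and every column sums to zero, so the
    intercept is the grand mean of level means under a balanced design.
    Column j has value (k-j)/k for rows 1..j and -j/k for rows j+1..k
    (1-based).
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    C = np.zeros((k, k - 1))
    for j in range(1, k):
        C[:j, j - 1] = (k - j) / k
        C[j:, j - 1] = -j / k
    return C


def group_labels(n_groups: int) -> list[str]:
    return list(string.ascii_uppercase[:n_groups])


def _contrast_names(n_groups: int) -> list[str]:
    labels = group_labels(n_groups)
    return [f"Group {a} vs. {b}" for a, b in zip(labels[:-1], labels[1:])]


def fixed_effect_matrix(
    trials: pd.DataFrame, n_groups: int = 5
) -> tuple[np.ndarray, list[str]]:
    """Assemble the fixed-effect design matrix (16 columns for 5 groups).

    Columns, in order: intercept; Voice Match (0/1); Trial (standardized to
    mean 0, SD 1 within the dataset); n_groups-1 forward-difference group
    columns; Voice Match x Group; Trial x Group; Voice Match x Trial.
    The first three columns double as the random-effect design.
    """
    labels = group_labels(n_groups)
    unknown = set(trials["group"]) - set(labels)
    if unknown:
        raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    own = trials["own_voice"].to_numpy(dtype=float)
    t = trials["trial_index"].to_numpy(dtype=float)
    sd = t.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("trial index has no variation; cannot scale")
    tz = (t - t.mean()) / sd

    C = forward_difference_matrix(n_groups)
    gidx = np.array([labels.index(g) for g in trials["group"]])
    G = C[gidx]  # (n, k-1)

    cols = [np.ones(len(trials)), own, tz]
    names = ["Intercept", "Voice Match (Own Voice)", "Trial"]
    cnames = _contrast_names(n_groups)
    for j, nm in enumerate(cnames):
        cols.append(G[:, j])
        names.append(nm)
    for j, nm in enumerate(cnames):
        cols.append(own * G[:, j])
        names.append(f"Voice Match × {nm}")
    for j, nm in enumerate(cnames):
        cols.append(tz * G[:, j])
        names.append(f"Trial × {nm}")
    cols.append(own * tz)
    names.append("Voice Match × Trial")
    return np.column_stack(cols), names


@dataclass
class Design:
    """Design matrices plus index maps for the multilevel fit."""

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    participant_idx: np.ndarray | None = None
    participants: np.ndarray | None = None


def build_design(trials: pd.DataFrame, n_groups: int = 5) -> Design:
    """Design matrices from an RT-filtered, scored trial table."""
    X, names = fixed_effect_matrix(trials, n_groups=n_groups)
    y = trials["correct"].to_numpy(dtype=float)
    participants = np.unique(trials["participant_id"])
    pidx = pd.Categorical(
        trials["participant_id"], categories=participants
    ).codes.astype(int)
    counts = np.bincount(pidx, minlength=len(participants))
    if np.any(counts == 0):
        raise ValueError("every participant must contribute at least one trial")
    return Design(X=X, y=y, names=names, participant_idx=pidx, participants=participants)


@dataclass
class Priors:
    intercept_sd: float = 5.0
    slope_sd: float = 2.5
    re_sd_scale: float = 2.5
    lkj_eta: float = 2.0


@dataclass
class FitDiagnostics:
    rhat: dict
    ess_bulk: dict
    n_chains: int
    n_iter: int
    n_warmup: int
    divergences: int
    accept_rate: float

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def min_ess_bulk(self) -> float:
        return min(self.ess_bulk.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < 1.01

    def to_dict(self) -> dict:
        return {
            "rhat": self.rhat,
            "ess_bulk": self.ess_bulk,
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_warmup": self.n_warmup,
            "divergences": self.divergences,
            "accept_rate": self.accept_rate,
            "max_rhat": self.max_rhat,
            "min_ess_bulk": self.min_ess_bulk,
            "converged": self.converged,
        }


_RE_SD_NAMES = ["SD (Intercept)", "SD (Voice Match)", "SD (Trial)"]
_RE_CORR_NAMES = [
    "Corr (Intercept, Voice Match)",
    "Corr (Intercept, Trial)",
    "Corr (Voice Match, Trial)",
]


@dataclass
class FitResult:
    """Posterior draws (per parameter: chains x kept iterations) + diagnostics."""

    draws: dict
    diagnostics: FitDiagnostics
    names: list[str]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def summary(self, parameters: list[str] | None = None) -> pd.DataFrame:
        return summarize(self.draws if parameters is None else {p: self.draws[p] for p in parameters})


def fit(
    design: Design,
    priors: Priors | None = None,
    config: SamplerConfig | None = None,
    random_effects: bool = True,
) -> FitResult:
    """Fit the accuracy model by HMC and return draws plus diagnostics.

    ``random_effects=False`` drops the by-participant terms (used for small
    fixed-effects-only fits, e.g. calibration studies and prior-only runs).
    A non-converged fit is reported through the diagnostics, never silently
    accepted: check ``result.diagnostics.converged``.
    """
    if priors is None:
        priors = Priors()
    if config is None:
        config = SamplerConfig()
    use_re = random_effects and design.participant_idx is not None
    posterior = BernoulliMultilevelPosterior(
        design.X,
        design.y,
        participant_idx=design.participant_idx if use_re else None,
        intercept_prior_sd=priors.intercept_sd,
        slope_prior_sd=priors.slope_sd,
        re_sd_prior_scale=priors.re_sd_scale,
        lkj_eta=priors.lkj_eta,
    )
    res = run_hmc(posterior, config)
    raw = res["draws"]  # (chains, kept, dim)
    p = len(design.names)

    draws: dict[str, np.ndarray] = {}
    for j, nm in enumerate(design.names):
        draws[nm] = raw[:, :, j]
    if use_re:
        for j, nm in enumerate(_RE_SD_NAMES):
            draws[nm] = np.exp(raw[:, :, p + j])
        z1 = np.tanh(raw[:, :, p + 3])
        z2 = np.tanh(raw[:, :, p + 4])
        z3 = np.tanh(raw[:, :, p + 5])
        draws[_RE_CORR_NAMES[0]] = z1
        draws[_RE_CORR_NAMES[1]] = z2
        draws[_RE_CORR_NAMES[2]] = z1 * z2 + np.sqrt((1 - z1**2) * (1 - z2**2)) * z3

    diag = _diagnose(draws, res, config)
    return FitResult(draws=draws, diagnostics=diag, names=list(design.names))


def _diagnose(draws: dict, res: dict, config: SamplerConfig) -> FitDiagnostics:
    import arviz as az

    idata = az.from_dict(posterior={k: v for k, v in draws.items()})
    rhat_ds = az.rhat(idata)
    ess_ds = az.ess(idata, method="bulk")
    rhat = {k: float(rhat_ds[k].values) for k in draws}
    ess = {k: float(ess_ds[k].values) for k in draws}
    return FitDiagnostics(
        rhat=rhat,
        ess_bulk=ess,
        n_chains=config.chains,
        n_iter=config.iterations,
        n_warmup=config.warmup,
        divergences=int(np.sum(res["divergences"])),
        accept_rate=float(np.mean(res["accept_rate"])),
    )


def summarize(draws: dict) -> pd.DataFrame:
    """Posterior summary table: median, mean, 95% CrI, pd, evidence flags.

    ``pd`` (probability of direction) is the larger of the posterior shares
    on either side of zero. ``compelling`` means the equal-tailed 95% CrI
    excludes 0; ``weak_evidence`` means the CrI includes 0 but pd >= 0.95.
    """
    rows = []
    for name, d in draws.items():
        d = np.asarray(d, dtype=float).reshape(-1)
        if d.size == 0:
            raise ValueError(f"no draws for parameter {name!r}")
        lo, hi = np.quantile(d, [0.025, 0.975])
        pd_val = max(float(np.mean(d >= 0)), float(np.mean(d <= 0)))
        compelling = bool(lo > 0 or hi < 0)
        rows.append(
            {
                "parameter": name,
                "median": float(np.median(d)),
                "mean": float(np.mean(d)),
                "cri_low": float(lo),
                "cri_high": float(hi),
                "pd": pd_val,
                "compelling": compelling,
                "weak_evidence": bool(not compelling and pd_val >= 0.95),
            }
        )
    return pd.DataFrame(rows)
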