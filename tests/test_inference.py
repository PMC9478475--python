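"""Design coding, the HMC sampler, posterior summaries, and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import approx_fprime, minimize
from scipy.special import expit
from scipy.stats import norm

from ownvoice import inference, synthdata
from ownvoice._hmc import BernoulliMultilevelPosterior, SamplerConfig, run_hmc
from tests.conftest import make_trial_frame


class TestForwardDifference:
    def test_two_levels(self):
        C = inference.forward_difference_matrix(2)
        assert np.allclose(C, [[0.5], [-0.5]])

    def test_coefficients_are_adjacent_differences(self):
        """Least-squares oracle: fitting level means (5,4,3,2,1) gives (1,1,1,1)."""
        C = inference.forward_difference_matrix(5)
        X = np.column_stack([np.ones(5), C])
        y = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert beta[0] == pytest.approx(3.0)  # intercept = grand mean
        assert np.allclose(beta[1:], 1.0)

    def test_columns_sum_to_zero(self):
        for k in (2, 3, 5, 8):
            C = inference.forward_difference_matrix(k)
            assert np.allclose(C.sum(axis=0), 0.0)

    def test_rejects_single_level(self):
        with pytest.raises(ValueError):
            inference.forward_difference_matrix(1)


class TestBuildDesign:
    def test_sixteen_columns_and_standardized_trial(self):
        df = make_trial_frame(n_participants=10, n_trials=50, seed=0)
        df["correct"] = True
        design = inference.build_design(df)
        assert design.X.shape[1] == 16
        assert len(design.names) == 16
        trial_col = design.X[:, 2]
        assert trial_col.mean() == pytest.approx(0.0, abs=1e-9)
        assert trial_col.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_all_other_voice_gives_zero_voicematch_column(self):
        df = make_trial_frame(n_participants=10, n_trials=50, own_fraction=0.0, seed=1)
        df["correct"] = True
        design = inference.build_design(df)
        assert np.all(design.X[:, 1] == 0.0)

    def test_unknown_group_rejected(self):
        df = make_trial_frame(seed=2).assign(group="Z", correct=True)
        with pytest.raises(ValueError):
            inference.build_design(df)

    def test_constant_trial_rejected(self):
        df = make_trial_frame(seed=3).assign(trial_index=7, correct=True)
        with pytest.raises(ValueError):
            inference.build_design(df)


class TestGradients:
    """Analytic log-posterior gradients agree with finite differences."""

    def _design(self, seed, n=150, J=6):
        rng = np.random.default_rng(seed)
        X = np.column_stack(
            [np.ones(n), rng.integers(0, 2, n), rng.normal(size=n), rng.normal(size=(n, 2))]
        )
        y = rng.integers(0, 2, n).astype(float)
        return X, y, rng.integers(0, J, n)

    @pytest.mark.parametrize("with_re", [True, False])
    def test_gradient_matches_finite_differences(self, with_re):
        X, y, pidx = self._design(7)
        post = BernoulliMultilevelPosterior(X, y, pidx if with_re else None)
        rng = np.random.default_rng(8)
        for _ in range(3):
            q = rng.normal(0, 0.6, post.dim)
            _, g = post.logp_grad(q)
            g_num = approx_fprime(q, lambda v: post.logp_grad(v)[0], 1e-6)
            assert np.max(np.abs(g - g_num)) < 1e-3


class TestSamplerAgainstQuadrature:
    def test_intercept_only_posterior_matches_numeric_integration(self):
        """Independent oracle: 1-D quadrature of the exact posterior density."""
        y = np.concatenate([np.ones(65), np.zeros(35)])
        post = BernoulliMultilevelPosterior(np.ones((100, 1)), y, None)
        res = run_hmc(post, SamplerConfig(chains=2, iterations=2500, warmup=500, seed=3))
        d = res["draws"][:, :, 0].ravel()

        grid = np.linspace(-5, 5, 20001)
        logpost = (
            65 * np.log(expit(grid)) + 35 * np.log(expit(-grid)) - 0.5 * (grid / 5) ** 2
        )
        w = np.exp(logpost - logpost.max())
        cdf = np.cumsum(w) / w.sum()
        q_med, q_lo, q_hi = (grid[np.searchsorted(cdf, p)] for p in (0.5, 0.025, 0.975))
        assert np.median(d) == pytest.approx(q_med, abs=0.04)
        assert np.quantile(d, 0.025) == pytest.approx(q_lo, abs=0.08)
        assert np.quantile(d, 0.975) == pytest.approx(q_hi, abs=0.08)

    def test_prior_only_intercept_spans_wide_interval(self):
        """With no data the intercept CrI must span at least [-8, 8]."""
        post = BernoulliMultilevelPosterior(np.ones((0, 1)), np.zeros(0), None)
        res = run_hmc(post, SamplerConfig(chains=2, iterations=3000, warmup=500, seed=4))
        d = res["draws"][:, :, 0].ravel()
        lo, hi = np.quantile(d, [0.025, 0.975])
        assert lo < -8.0 and hi > 8.0


def test_coding_equivalence_at_mle():
    """Forward-difference and treatment coding give identical fitted cell
    probabilities (likelihood invariance to reparameterization)."""
    rng = np.random.default_rng(5)
    n = 4000
    g = rng.integers(0, 5, n)
    own = rng.integers(0, 2, n).astype(float)
    mu = np.array([0.9, 1.3, 0.6, 0.4, 0.1])
    eta = mu[g] + 0.3 * own
    y = (rng.random(n) < expit(eta)).astype(float)

    C = inference.forward_difference_matrix(5)
    X_fd = np.column_stack([np.ones(n), own, C[g]])
    D = np.eye(5)[g]
    X_tr = np.column_stack([np.ones(n), own, D[:, 1:]])

    def nll(beta, X):
        e = X @ beta
        return -np.sum(y * e - np.logaddexp(0, e))

    fits = []
    for X in (X_fd, X_tr):
        r = minimize(nll, np.zeros(X.shape[1]), args=(X,), method="BFGS")
        fits.append(expit(X @ r.x))
    assert np.max(np.abs(fits[0] - fits[1])) < 1e-5


class TestSummarize:
    def test_constant_draws(self):
        s = inference.summarize({"x": np.full((2, 100), 0.7)}).iloc[0]
        assert (s["median"], s["cri_low"], s["cri_high"], s["pd"]) == (0.7, 0.7, 0.7, 1.0)

    def test_symmetric_draws_are_no_evidence(self):
        rng = np.random.default_rng(6)
        d = rng.normal(0.0, 1.0, (4, 3000))
        s = inference.summarize({"x": d}).iloc[0]
        assert s["pd"] == pytest.approx(0.5, abs=0.02)
        assert not s["compelling"] and not s["weak_evidence"]

    def test_pd_matches_gaussian_tail(self):
        """Draws ~ N(0.23, 0.09): pd equals Phi(0.23/0.09) ~ 0.9947."""
        rng = np.random.default_rng(7)
        d = rng.normal(0.23, 0.09, (4, 3000))
        s = inference.summarize({"x": d}).iloc[0]
        assert s["pd"] == pytest.approx(norm.cdf(0.23 / 0.09), abs=0.005)
        assert s["compelling"]  # CrI ~ [0.05, 0.41] excludes 0

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            inference.summarize({"x": np.empty((2, 0))})


def test_null_pd_calibration():
    """Under the null (no own-voice effect), pd is uniform: ~5% of replicates
    exceed 0.975."""
    rng = np.random.default_rng(20)
    exceed = 0
    n_rep = 100
    for rep in range(n_rep):
        n = 250
        own = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        post = BernoulliMultilevelPosterior(np.column_stack([np.ones(n), own]), y, None)
        res = run_hmc(
            post, SamplerConfig(chains=1, iterations=900, warmup=300, seed=1000 + rep)
        )
        d = res["draws"][:, :, 1].ravel()
        pd_val = max(np.mean(d > 0), np.mean(d < 0))
        exceed += pd_val > 0.975
    assert 0.005 <= exceed / n_rep <= 0.12


def test_small_scale_fit_recovers_strong_effect():
    """End-to-end fit on a small simulated design recovers a large own-voice
    benefit inside its credible interval and converges."""
    params = synthdata.ResponseGenParams(
        b_intercept=0.8, b_own=1.0, b_trial=0.0,
        b_group=(0, 0, 0, 0), b_own_group=(0, 0, 0, 0),
        b_trial_group=(0, 0, 0, 0), b_own_trial=0.0,
        re_sd=(0.3, 0.2, 0.1),
    )
    trials = make_trial_frame(n_participants=20, n_trials=150, own_fraction=0.4, seed=9)
    out = synthdata.simulate_trials(trials, params, seed=10)
    design = inference.build_design(out.assign(correct=out["correct"]))
    cfg = inference.SamplerConfig(chains=2, iterations=1500, warmup=500, seed=11)
    result = inference.fit(design, config=cfg)
    s = result.summary().set_index("parameter")
    row = s.loc["Voice Match (Own Voice)"]
    assert row["cri_low"] <= 1.0 <= row["cri_high"]
    assert abs(row["median"] - 1.0) < 0.5
    assert result.diagnostics.max_rhat < 1.05
    assert result.diagnostics.divergences == 0
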