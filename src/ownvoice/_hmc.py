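"""Hamiltonian Monte Carlo for the hierarchical Bernoulli-logit model.

The posterior is expressed in fully unconstrained coordinates:

* fixed effects ``beta`` (Normal priors);
* ``s = log(sd)`` for the three by-participant random-effect SDs
  (half-Normal prior on sd, log-Jacobian included);
* three unconstrained canonical partial correlations ``y`` for the 3x3
  random-effect correlation matrix. ``z = tanh(y)`` are the C-vine partial
  correlations, which under an LKJ(eta) prior are independent with
  ``(z+1)/2 ~ Beta(a, a)`` where ``a = eta + (K-1-k)/2`` for tree level k;
  combined with the tanh Jacobian the log prior is simply
  ``sum a_i * log(1 - z_i^2)``;
* non-centered standard-normal participant effects ``z_u`` with
  ``u_j = sd * (L z_u_j)``.

All gradients are analytic (and finite-difference tested). Sampling is plain
HMC with dual-averaging step-size adaptation and windowed diagonal mass
matrix estimation in the warmup phase, in the style of Stan's adaptation
schedule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import expit as _expit
from scipy.special import log_expit as _log_expit

__all__ = ["BernoulliMultilevelPosterior", "SamplerConfig", "run_hmc"]


class BernoulliMultilevelPosterior:
    """Log density and gradient of the 2AFC accuracy model.

    Parameters
    ----------
    X : (n, p) fixed-effect design matrix (first column must be the intercept
        when random effects are used; the first three columns double as the
        random-effect design: intercept, voice-match, trial).
    y : (n,) binary outcomes.
    participant_idx : (n,) integer codes 0..J-1, or None for a fixed-effects
        only model.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        participant_idx: np.ndarray | None = None,
        intercept_prior_sd: float = 5.0,
        slope_prior_sd: float = 2.5,
        re_sd_prior_scale: float = 2.5,
        lkj_eta: float = 2.0,
    ) -> None:
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.n, self.p = self.X.shape
        self.prior_sd = np.full(self.p, slope_prior_sd)
        if self.p:
            self.prior_sd[0] = intercept_prior_sd
        self.re_sd_prior_scale = re_sd_prior_scale
        # C-vine Beta shapes for K=3: tree 1 (two marginal correlations) and
        # tree 2 (one partial correlation)
        self.lkj_alpha = np.array([lkj_eta + 0.5, lkj_eta + 0.5, lkj_eta])

        self.re = participant_idx is not None
        if self.re:
            pidx = np.asarray(participant_idx, dtype=int)
            self.J = int(pidx.max()) + 1 if len(pidx) else 0
            # sort rows by participant once so segment sums need no reindexing
            order = np.argsort(pidx, kind="stable")
            self.X = np.ascontiguousarray(self.X[order])
            self.y = self.y[order]
            pidx = pidx[order]
            self._pidx = pidx
            self._counts = np.bincount(pidx, minlength=self.J)
            self._seg_starts = np.searchsorted(pidx, np.arange(self.J))
            self._W = np.ascontiguousarray(self.X[:, :3])
        else:
            self.J = 0

    @property
    def dim(self) -> int:
        return self.p + (6 + 3 * self.J if self.re else 0)

    def unpack(self, q: np.ndarray) -> dict:
        beta = q[: self.p]
        out = {"beta": beta}
        if self.re:
            out["s"] = q[self.p : self.p + 3]
            out["ycorr"] = q[self.p + 3 : self.p + 6]
            out["zu"] = q[self.p + 6 :].reshape(self.J, 3)
        return out

    @staticmethod
    def corr_cholesky(zc: np.ndarray) -> np.ndarray:
        """Lower Cholesky factor of the 3x3 correlation from partial corrs."""
        z1, z2, z3 = zc
        L = np.zeros((3, 3))
        L[0, 0] = 1.0
        L[1, 0] = z1
        L[1, 1] = math.sqrt(1.0 - z1 * z1)
        L[2, 0] = z2
        L[2, 1] = z3 * math.sqrt(1.0 - z2 * z2)
        L[2, 2] = math.sqrt((1.0 - z2 * z2) * (1.0 - z3 * z3))
        return L

    def _segment_sum(self, G: np.ndarray) -> np.ndarray:
        return np.add.reduceat(G, self._seg_starts, axis=0)

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        # early warmup steps can wander to extreme coordinates; overflow
        # yields -inf log density and a rejected proposal, which is correct
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            return self._logp_grad(q)

    def _logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        P = self.unpack(q)
        beta = P["beta"]
        grad = np.empty_like(q)

        if self.re:
            s = P["s"]
            sd = np.exp(s)
            zc = np.clip(np.tanh(P["ycorr"]), -1.0 + 1e-12, 1.0 - 1e-12)
            zu = P["zu"]
            L = self.corr_cholesky(zc)
            U = (zu @ L.T) * sd  # (J, 3) actual random effects
            eta = self.X @ beta + np.einsum(
                "ij,ij->i", self._W, np.repeat(U, self._counts, axis=0)
            )
        else:
            eta = self.X @ beta

        # sum[(y-1)*eta + log_expit(eta)] == sum[y*eta - log1pexp(eta)]
        logp = float(np.dot(self.y - 1.0, eta) + np.sum(_log_expit(eta)))
        r = self.y - _expit(eta)
        gbeta = self.X.T @ r

        # fixed-effect priors
        logp += float(-0.5 * np.sum((beta / self.prior_sd) ** 2))
        gbeta -= beta / self.prior_sd**2
        grad[: self.p] = gbeta

        if not self.re:
            return logp, grad

        Gu = self._segment_sum(r[:, None] * self._W)  # (J, 3) dloglik/du
        Lz = zu @ L.T

        # sd (half-Normal prior, log-Jacobian of exp)
        tau2 = self.re_sd_prior_scale**2
        logp += float(np.sum(-0.5 * sd**2 / tau2 + s))
        g_s = np.sum(Gu * Lz, axis=0) * sd - sd**2 / tau2 + 1.0
        grad[self.p : self.p + 3] = g_s

        # correlation part
        z1, z2, z3 = zc
        GL = (Gu * sd).T @ zu  # (3, 3), dloglik/dL
        l22 = L[2, 2]
        dz1 = GL[1, 0] + GL[1, 1] * (-z1 / max(L[1, 1], 1e-12))
        dz2 = (
            GL[2, 0]
            + GL[2, 1] * z3 * (-z2 / max(math.sqrt(1 - z2 * z2), 1e-12))
            + GL[2, 2] * (-z2 * (1 - z3 * z3)) / max(l22, 1e-12)
        )
        dz3 = (
            GL[2, 1] * math.sqrt(1 - z2 * z2)
            + GL[2, 2] * (-z3 * (1 - z2 * z2)) / max(l22, 1e-12)
        )
        logp += float(np.sum(self.lkj_alpha * np.log1p(-zc**2)))
        grad[self.p + 3 : self.p + 6] = (
            np.array([dz1, dz2, dz3]) * (1.0 - zc**2) - 2.0 * self.lkj_alpha * zc
        )

        # non-centered participant effects
        logp += float(-0.5 * np.sum(zu**2))
        gz = ((Gu * sd) @ L) - zu
        grad[self.p + 6 :] = gz.ravel()
        return logp, grad


@dataclass
class SamplerConfig:
    """HMC run configuration (iterations are per chain, including warmup)."""

    chains: int = 4
    iterations: int = 4000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.85
    trajectory_length: float = 1.5
    max_leapfrog: int = 48
    init_jitter: float = 0.1


def _find_initial_step(posterior, q, inv_mass, rng) -> float:
    eps = 0.1
    lp, g = posterior.logp_grad(q)
    p = rng.standard_normal(len(q)) / np.sqrt(inv_mass)
    h0 = lp - 0.5 * float(np.sum(p * p * inv_mass))
    q1, p1, lp1, _ = _leapfrog(posterior, q, p, g, eps, 1, inv_mass)
    h1 = lp1 - 0.5 * float(np.sum(p1 * p1 * inv_mass))
    direction = 1.0 if (h1 - h0) > math.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q1, p1, lp1, _ = _leapfrog(posterior, q, p, g, eps, 1, inv_mass)
        h1 = lp1 - 0.5 * float(np.sum(p1 * p1 * inv_mass))
        if direction * (h1 - h0) < direction * math.log(0.5):
            break
    return eps


def _leapfrog(posterior, q, p, grad, eps, n_steps, inv_mass):
    q = q.copy()
    p = p + 0.5 * eps * grad
    for i in range(n_steps):
        q = q + eps * inv_mass * p
        lp, grad = posterior.logp_grad(q)
        if not np.isfinite(lp):
            return q, p, -np.inf, grad
        p = p + (eps if i < n_steps - 1 else 0.5 * eps) * grad
    return q, p, lp, grad


def _warmup_windows(warmup: int) -> list[tuple[int, int]]:
    """Stan-style expanding mass-estimation windows inside the warmup phase."""
    init_buf, term_buf, base = 75, 50, 25
    if warmup < init_buf + term_buf + base:
        return [(warmup // 3, max(warmup // 3 + 1, warmup - warmup // 4))]
    windows = []
    start, size = init_buf, base
    while start + size < warmup - term_buf:
        end = start + size
        if start + 3 * size >= warmup - term_buf:
            end = warmup - term_buf
        windows.append((start, end))
        start, size = end, size * 2
    return windows


def run_hmc(posterior, config: SamplerConfig, q0: np.ndarray | None = None) -> dict:
    """Sample the posterior; returns draws of shape (chains, kept, dim)."""
    dim = posterior.dim
    root = np.random.SeedSequence(config.seed)
    kept = config.iterations - config.warmup
    if kept <= 0:
        raise ValueError("iterations must exceed warmup")
    draws = np.empty((config.chains, kept, dim))
    divergences = np.zeros(config.chains, dtype=int)
    accept = np.zeros(config.chains)
    windows = _warmup_windows(config.warmup)

    for c, child in enumerate(root.spawn(config.chains)):
        rng = np.random.default_rng(child)
        q = (
            q0.copy()
            if q0 is not None
            else rng.normal(0.0, config.init_jitter, size=dim)
        )
        inv_mass = np.ones(dim)
        lp, grad = posterior.logp_grad(q)
        eps = _find_initial_step(posterior, q, inv_mass, rng)
        # dual averaging state
        mu = math.log(10.0 * eps)
        log_eps_bar, h_bar, t0, gamma, kappa = 0.0, 0.0, 10.0, 0.05, 0.75
        da_count = 0
        win_i = 0
        wsum = np.zeros(dim)
        wsum2 = np.zeros(dim)
        wn = 0
        acc_sum = 0.0

        for it in range(config.iterations):
            warming = it < config.warmup
            p = rng.standard_normal(dim) / np.sqrt(inv_mass)
            h0 = lp - 0.5 * float(np.sum(p * p * inv_mass))
            n_steps = int(
                np.clip(
                    round(config.trajectory_length / eps * rng.uniform(0.5, 1.5)),
                    1,
                    config.max_leapfrog,
                )
            )
            q_new, p_new, lp_new, grad_new = _leapfrog(
                posterior, q, p, grad, eps, n_steps, inv_mass
            )
            if np.isfinite(lp_new):
                h1 = lp_new - 0.5 * float(np.sum(p_new * p_new * inv_mass))
                dh = h1 - h0
            else:
                dh = -np.inf
            alpha = min(1.0, math.exp(min(dh, 0.0)))
            diverged = dh < -1000.0
            if not diverged and rng.random() < alpha:
                q, lp, grad = q_new, lp_new, grad_new

            if warming:
                da_count += 1
                h_bar = (1 - 1 / (da_count + t0)) * h_bar + (
                    config.target_accept - alpha
                ) / (da_count + t0)
                log_eps = mu - math.sqrt(da_count) / gamma * h_bar
                w = da_count**-kappa
                log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
                eps = math.exp(log_eps)
                if win_i < len(windows):
                    lo, hi = windows[win_i]
                    if lo <= it < hi:
                        wsum += q
                        wsum2 += q * q
                        wn += 1
                    if it == hi - 1 and wn > 1:
                        var = (wsum2 - wsum**2 / wn) / (wn - 1)
                        inv_mass = wn / (wn + 5.0) * var + 1e-3 * (5.0 / (wn + 5.0))
                        inv_mass = np.maximum(inv_mass, 1e-8)
                        win_i += 1
                        wsum[:] = 0.0
                        wsum2[:] = 0.0
                        wn = 0
                        eps = _find_initial_step(posterior, q, inv_mass, rng)
                        mu = math.log(10.0 * eps)
                        h_bar, log_eps_bar, da_count = 0.0, 0.0, 0
                if it == config.warmup - 1:
                    eps = math.exp(log_eps_bar) if da_count else eps
            else:
                if diverged:
                    divergences[c] += 1
                acc_sum += alpha
                draws[c, it - config.warmup] = q
        accept[c] = acc_sum / kept

    return {
        "draws": draws,
        "divergences": divergences,
        "accept_rate": accept,
    }
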