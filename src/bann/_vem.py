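"""Coordinate-ascent variational EM for normal-mixture spike-and-slab regression.

Model:  b = A beta + e,  e ~ N(0, tau2 I), with the mixture-of-normals
spike-and-slab prior on each coefficient

    beta_j ~ pi * sum_k eta_k N(0, sigma2_k) + (1 - pi) * delta_0.

The variational family is fully factorized over coefficients; each factor is
a (K+1)-outcome mixture with component inclusion probabilities alpha_{jk}
(spike mass 1 - sum_k alpha_{jk}) and per-component Gaussians N(mu_{jk},
s2_{jk}).  One sweep of :func:`coordinate_sweep` refreshes every factor at
its mean-field fixed point, maintaining the residual r = b - A m
incrementally, so a full sweep costs O(N J K).

The same machinery serves the input layer (K = 3, design = genotypes or LD
matrix) and the hidden layer (K = 1, design = SNP-set activations).
"""

from __future__ import annotations

import numpy as np
from numba import njit

from scipy.special import xlogy

ALPHA_FLOOR = 1e-10
TAU2_FLOOR = 1e-8

__all__ = [
    "coordinate_sweep",
    "compute_elbo",
    "m_step",
    "init_state",
    "VEMState",
]


@njit(cache=False)
def _sweep_kernel(A, atA, r, alpha, mu, s2, m, tau2, sigma2, eta, log_pi, log_1mpi):
    """One full coordinate-ascent sweep; updates alpha/mu/s2/m/r in place."""
    N, J = A.shape
    K = sigma2.shape[0]
    logw = np.empty(K + 1)
    for j in range(J):
        mj_old = m[j]
        xr = 0.0
        for i in range(N):
            xr += A[i, j] * r[i]
        xr += atA[j] * mj_old  # j-th column's own contribution restored
        logw[0] = log_1mpi
        for k in range(K):
            s2_jk = 1.0 / (atA[j] / tau2 + 1.0 / sigma2[k])
            mu_jk = s2_jk * xr / tau2
            s2[j, k] = s2_jk
            mu[j, k] = mu_jk
            logw[k + 1] = (
                log_pi
                + np.log(eta[k])
                + 0.5 * np.log(s2_jk / sigma2[k])
                + 0.5 * mu_jk * mu_jk / s2_jk
            )
        wmax = logw[0]
        for k in range(K + 1):
            if logw[k] > wmax:
                wmax = logw[k]
        norm = 0.0
        for k in range(K + 1):
            norm += np.exp(logw[k] - wmax)
        mj_new = 0.0
        for k in range(K):
            a_jk = np.exp(logw[k + 1] - wmax) / norm
            alpha[j, k] = a_jk
            mj_new += a_jk * mu[j, k]
        m[j] = mj_new
        if mj_new != mj_old:
            delta = mj_old - mj_new
            for i in range(N):
                r[i] += A[i, j] * delta
        if not np.isfinite(mj_new):
            return j
    return -1


class VEMState:
    """Mutable variational state for one layer at one hyper-prior grid point."""

    __slots__ = ("alpha", "mu", "s2", "m", "r", "tau2", "sigma2", "eta", "pi",
                 "sigma2_floor", "elbo_trace", "converged", "n_sweeps")

    def __init__(self, alpha, mu, s2, m, r, tau2, sigma2, eta, pi, sigma2_floor=1e-12):
        self.alpha = alpha
        self.mu = mu
        self.s2 = s2
        self.m = m
        self.r = r
        self.tau2 = tau2
        self.sigma2 = sigma2
        self.eta = eta
        self.pi = pi
        self.sigma2_floor = sigma2_floor
        self.elbo_trace: list[float] = []
        self.converged = False
        self.n_sweeps = 0

    @property
    def pip(self) -> np.ndarray:
        """Per-coefficient inclusion probability sum_k alpha_jk."""
        return np.minimum(self.alpha.sum(axis=1), 1.0)

    def posterior_variance(self) -> np.ndarray:
        second = (self.alpha * (self.mu**2 + self.s2)).sum(axis=1)
        return second - self.m**2


def init_state(A, b, sigma2, eta, pi, rng=None, tau2=None) -> VEMState:
    """Initialize a layer's variational factors from prior draws.

    mu_{jk} is drawn from the k-th prior slab component, alpha at the prior
    masses pi * eta_k, and s2 at the slab variances; the residual r = b - A m
    is formed from the implied posterior means.

    A fixed lower bound on the slab variances is recorded at the per-
    coefficient detection scale var(b) / mean(a_j'a_j): M-step updates may
    never collapse a slab component below the effect size that a single
    predictor could distinguish from noise, which would turn the slab into a
    second point mass at zero and leave the inclusion probability
    unidentified.
    """
    J = A.shape[1]
    K = len(sigma2)
    sigma2 = np.asarray(sigma2, dtype=np.float64)
    eta = np.asarray(eta, dtype=np.float64)
    if rng is None:
        mu = np.zeros((J, K))
    else:
        mu = rng.standard_normal((J, K)) * np.sqrt(sigma2)[None, :]
    alpha = pi * np.broadcast_to(eta, (J, K)).copy()
    s2 = np.tile(sigma2, (J, 1))
    m = (alpha * mu).sum(axis=1)
    r = b - A @ m
    if tau2 is None:
        tau2 = max(float(np.var(b)), TAU2_FLOOR)
    mean_atA = float(np.mean(np.einsum("ij,ij->j", A, A)))
    floor = max(float(np.var(b)) / max(mean_atA, 1e-12), 1e-12)
    floor = min(floor, float(sigma2.min()))  # never above the chosen prior scales
    return VEMState(alpha, mu, s2, m, r, float(tau2), sigma2.copy(), eta.copy(),
                    float(pi), sigma2_floor=floor)


def coordinate_sweep(state: VEMState, A: np.ndarray, atA: np.ndarray) -> None:
    """Run one full coordinate-ascent sweep over all coefficients."""
    pi = min(max(state.pi, ALPHA_FLOOR), 1 - ALPHA_FLOOR)
    bad = _sweep_kernel(
        A,
        atA,
        state.r,
        state.alpha,
        state.mu,
        state.s2,
        state.m,
        state.tau2,
        state.sigma2,
        state.eta,
        np.log(pi),
        np.log1p(-pi),
    )
    state.n_sweeps += 1
    if bad >= 0:
        raise FloatingPointError(
            f"non-finite variational update at coefficient {bad} (tau2={state.tau2:.3e})"
        )


def expected_rss(state: VEMState, atA: np.ndarray) -> float:
    """E_q ||b - A beta||^2 = ||r||^2 + sum_j a_j'a_j Var_q(beta_j)."""
    return float(state.r @ state.r + atA @ state.posterior_variance())


def compute_elbo(state: VEMState, atA: np.ndarray, n_obs: int) -> float:
    """Variational lower bound on the marginal log-likelihood.

    Expected Gaussian log-likelihood under q minus the KL divergence of the
    factorized (K+1)-outcome spike-slab mixture from its prior.
    """
    tau2 = state.tau2
    ell = -0.5 * n_obs * np.log(2 * np.pi * tau2) - expected_rss(state, atA) / (2 * tau2)

    alpha = np.clip(state.alpha, 0.0, 1.0)
    spike = np.clip(1.0 - alpha.sum(axis=1), 0.0, 1.0)
    pi = min(max(state.pi, ALPHA_FLOOR), 1 - ALPHA_FLOOR)
    # categorical part of the KL
    kl = (
        xlogy(alpha, alpha).sum()
        - (alpha * np.log(pi * state.eta)[None, :]).sum()
        + xlogy(spike, spike).sum()
        - spike.sum() * np.log1p(-pi)
    )
    # Gaussian part, weighted by component responsibilities
    g = 0.5 * (
        np.log(state.sigma2)[None, :]
        - np.log(state.s2)
        + (state.s2 + state.mu**2) / state.sigma2[None, :]
        - 1.0
    )
    kl += (alpha * g).sum()
    return float(ell - kl)


def m_step(state: VEMState, atA: np.ndarray, n_obs: int, update_sigma2: bool = True) -> None:
    """Closed-form M-step maximizers of the lower bound.

    tau2 <- E_q||b - A beta||^2 / N (floored at 1e-8); each slab variance
    sigma2_k <- sum_j alpha_jk (mu_jk^2 + s2_jk) / sum_j alpha_jk when the
    k-th responsibility mass is positive.  The decreasing-variance ordering
    is restored by jointly permuting the mixture columns (a pure relabeling,
    leaving the bound unchanged for exchangeable eta).
    """
    state.tau2 = max(expected_rss(state, atA) / n_obs, TAU2_FLOOR)
    if not np.isfinite(state.tau2) or state.tau2 <= 0:
        raise FloatingPointError(f"invalid tau2 update: {state.tau2}")
    if update_sigma2:
        mass = state.alpha.sum(axis=0)
        moment = (state.alpha * (state.mu**2 + state.s2)).sum(axis=0)
        new = state.sigma2.copy()
        ok = mass > 1e-12
        new[ok] = moment[ok] / mass[ok]
        new = np.maximum(new, state.sigma2_floor)
        order = np.argsort(-new, kind="stable")
        state.sigma2 = new[order]
        state.eta = state.eta[order]
        state.alpha = np.ascontiguousarray(state.alpha[:, order])
        state.mu = np.ascontiguousarray(state.mu[:, order])
        state.s2 = np.ascontiguousarray(state.s2[:, order])


def update_pi_em(state: VEMState, pi_min: float) -> None:
    """EM update of the inclusion probability: pi at the mean inclusion mass."""
    p = state.pip
    odds = p.sum() / max((1.0 - p).sum(), ALPHA_FLOOR)
    state.pi = float(np.clip(odds / (1.0 + odds), pi_min, 1 - ALPHA_FLOOR))
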