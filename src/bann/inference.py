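"""Two-stage variational EM inference for the annotated network model.

The model is the partially connected Bayesian network regression

    y = sum_g h(X_g theta_g + 1 b_g) w_g + 1 b,

with a K-component normal-mixture spike-and-slab prior on the SNP weights
theta and a single-slab spike-and-slab prior on the SNP-set weights w; h is a
leaky ReLU (identity under the linear-activation ablation).  Fitting proceeds
in two stages: the "inner" problem regresses y on the genotypes under the
mixture prior, iterated to convergence at every value of a log-spaced grid of
inclusion probabilities pi_theta in [1/J, 1]; per-grid fits are combined by
importance weights proportional to their exponentiated lower bounds (Bayesian
model averaging).  The averaged posterior-mean SNP weights define the hidden
activations H, and the "outer" problem regresses y on H over a pi_w grid in
[1/G, 1] with the same machinery.  Posterior inclusion probabilities

    PIP(j) = Pr[theta_j != 0 | y, X],   PIP(g) = Pr[w_g != 0 | y, X, theta_g]

summarize evidence at SNP and SNP-set scale, and the phenotypic variance
explained (PVE) is estimated at both scales from the fitted mean weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _vem
from ._vem import VEMState, coordinate_sweep, compute_elbo, m_step, init_state, update_pi_em
from .annotation import AnnotationMask

__all__ = [
    "InputLayerPrior",
    "HiddenLayerPrior",
    "FitResult",
    "BANN",
    "standardize",
    "leaky_relu",
    "fit_inner",
    "fit_outer",
    "compute_hidden_activations",
    "average_over_grid",
    "compute_pips",
    "estimate_pve",
    "fit",
]

DEFAULT_TOL = 1e-4
DEFAULT_MAX_SWEEPS = 10_000
# Tolerated ELBO regression per iteration before declaring an update bug.
_ELBO_BACKSLIDE = 10 * np.finfo(np.float64).eps


@dataclass(frozen=True)
class InputLayerPrior:
    """Mixture spike-and-slab prior for SNP-level weights.

    K slab components with strictly decreasing variances emulate large,
    moderate and small nonzero effects; ``pi_grid`` is the log-spaced grid of
    total inclusion probabilities in [1/J, 1] that the fit averages over.
    """

    sigma2: tuple = (1.0, 0.1, 0.01)
    eta: tuple | None = None
    pi_grid: np.ndarray = None

    def __post_init__(self) -> None:
        s = np.asarray(self.sigma2, dtype=np.float64)
        if (s <= 0).any() or (np.diff(s) >= 0).any():
            raise ValueError("sigma2 must be positive and strictly decreasing")
        if self.eta is not None:
            e = np.asarray(self.eta, dtype=np.float64)
            if len(e) != len(s) or not np.isclose(e.sum(), 1.0) or (e <= 0).any():
                raise ValueError("eta must be a positive K-simplex")
        if self.pi_grid is not None:
            g = np.asarray(self.pi_grid, dtype=np.float64)
            if (np.diff(g) <= 0).any():
                raise ValueError("pi_grid must be strictly increasing")

    @property
    def K(self) -> int:
        return len(self.sigma2)

    def eta_array(self) -> np.ndarray:
        if self.eta is None:
            return np.full(self.K, 1.0 / self.K)
        return np.asarray(self.eta, dtype=np.float64)


@dataclass(frozen=True)
class HiddenLayerPrior:
    """Single-slab spike-and-slab prior for SNP-set weights."""

    sigma2_w: float = 1.0
    pi_w_grid: np.ndarray = None

    def __post_init__(self) -> None:
        if self.sigma2_w <= 0:
            raise ValueError("sigma2_w must be positive")


def log_spaced_grid(lower: float, n: int) -> np.ndarray:
    """n log-spaced values in [lower, 1]."""
    return np.exp(np.linspace(np.log(lower), 0.0, n))


@dataclass
class FitResult:
    """Grid-averaged posterior summaries of a fitted network."""

    pip_snp: np.ndarray
    pip_set: np.ndarray
    m_theta: np.ndarray
    m_w: np.ndarray
    bias_hidden: np.ndarray
    bias_output: float
    pve_snp: float
    pve_set: float
    grid_elbos_inner: np.ndarray
    grid_elbos_outer: np.ndarray
    grid_weights_inner: np.ndarray
    grid_weights_outer: np.ndarray
    elbo_trace_inner: list = field(default_factory=list, repr=False)
    elbo_trace_outer: list = field(default_factory=list, repr=False)
    converged: bool = False
    n_sweeps: int = 0
    dropped_sets: np.ndarray = None


def standardize(X, y=None, covariates=None, snp_ids=None):
    """Mean-center and unit-scale genotype columns and phenotype.

    If covariates are given, y is first replaced by the residuals of its
    least-squares projection on [1, covariates].  Returns (Xs, ys, info) where
    info records the centers/scales so the transform can be replayed at
    prediction time.  Raises on monomorphic (zero-variance) columns, listing
    the offending SNPs.
    """
    X = np.asarray(X, dtype=np.float64)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    bad = np.flatnonzero(scale <= 0)
    if bad.size:
        labels = [str(snp_ids[b]) for b in bad] if snp_ids is not None else bad.tolist()
        raise ValueError(f"zero-variance (monomorphic) genotype columns: {labels[:20]}")
    Xs = (X - center) / scale
    info = {"x_center": center, "x_scale": scale}
    if y is None:
        return Xs, None, info
    y = np.asarray(y, dtype=np.float64).ravel()
    if covariates is not None:
        Q = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=np.float64)])
        beta, *_ = np.linalg.lstsq(Q, y, rcond=None)
        y = y - Q @ beta
        info["covariate_coef"] = beta
    y_center = y.mean()
    y_scale = y.std()
    if y_scale <= 1e-12:
        raise ValueError("phenotype has (near) zero variance after covariate adjustment")
    ys = (y - y_center) / y_scale
    info.update(y_center=y_center, y_scale=y_scale)
    return Xs, ys, info


def leaky_relu(x, slope: float = 0.01):
    """Hidden-layer activation: identity on the positive branch, slope 0.01
    on the non-positive branch."""
    x = np.asarray(x, dtype=np.float64)
    return np.where(x > 0, x, slope * x)


def update_input_layer(state: VEMState, A: np.ndarray, atA: np.ndarray) -> VEMState:
    """One full coordinate-ascent sweep over all coefficients (in place)."""
    coordinate_sweep(state, A, atA)
    return state


def update_hyperparameters_inner(state: VEMState, atA: np.ndarray, n_obs: int) -> VEMState:
    """M-step refresh of tau2 and the slab variances (in place)."""
    m_step(state, atA, n_obs)
    return state


def _fit_layer(
    A,
    b,
    sigma2,
    eta,
    pi,
    tol=DEFAULT_TOL,
    max_sweeps=DEFAULT_MAX_SWEEPS,
    rng=None,
    update_hyper=True,
    update_pi=False,
    pi_min=None,
) -> VEMState:
    """Iterate sweeps and M-steps until the lower bound stabilizes."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    A = np.asfortranarray(A, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64).ravel()
    atA = np.einsum("ij,ij->j", A, A)
    state = init_state(A, b, sigma2, eta, pi, rng=rng)
    n_obs = A.shape[0]
    prev = -np.inf
    for _ in range(max_sweeps):
        coordinate_sweep(state, A, atA)
        if update_hyper:
            m_step(state, atA, n_obs)
        if update_pi:
            update_pi_em(state, pi_min if pi_min is not None else 1.0 / A.shape[1])
        elbo = compute_elbo(state, atA, n_obs)
        state.elbo_trace.append(elbo)
        if np.isinf(tol):  # degenerate tolerance: stop after the first sweep
            state.converged = True
            break
        if np.isfinite(prev):
            drop = prev - elbo
            if not update_pi and drop > _ELBO_BACKSLIDE * max(1.0, abs(prev)):
                raise FloatingPointError(
                    f"lower bound decreased by {drop:.3e} at sweep {state.n_sweeps}"
                )
            if abs(elbo - prev) < tol:
                state.converged = True
                break
        prev = elbo
    return state


def fit_inner(X, y, prior: InputLayerPrior, pi_theta, tol=DEFAULT_TOL,
              max_sweeps=DEFAULT_MAX_SWEEPS, rng=None, update_hyper=True) -> VEMState:
    """Converge the input-layer (SNP-level) variational problem at one
    grid value of pi_theta."""
    return _fit_layer(X, y, prior.sigma2, prior.eta_array(), pi_theta,
                      tol=tol, max_sweeps=max_sweeps, rng=rng, update_hyper=update_hyper)


def fit_outer(H, y, prior: HiddenLayerPrior, pi_w, tol=DEFAULT_TOL,
              max_sweeps=DEFAULT_MAX_SWEEPS, rng=None, update_hyper=True) -> VEMState:
    """Converge the hidden-layer (SNP-set-level) spike-slab problem (K = 1)."""
    return _fit_layer(H, y, (prior.sigma2_w,), (1.0,), pi_w,
                      tol=tol, max_sweeps=max_sweeps, rng=rng, update_hyper=update_hyper)


def compute_hidden_activations(X, mask, m_theta, linear: bool = False, pip_snp=None):
    """Form the standardized hidden-unit design H and hidden biases.

    Column g is h(X_g m_theta_g + b_g) where the sum runs over the members of
    SNP-set g and b_g centers the pre-activation (identically zero for
    column-centered X, but recorded).  Activated columns are mean-centered
    and scaled to unit variance.

    A column is flagged (excluded from the outer regression, set PIP 0) when
    it carries no signal from the input layer: either its variance is exactly
    zero, or — when the inner inclusion probabilities are supplied — the
    posterior probability that the set contains at least one nonzero-effect
    SNP, 1 - prod_{j in S_g} (1 - PIP(j)), falls below 1/2.  Enrichment of a
    SNP-set is defined as containing at least one associated SNP and the
    set-level posterior is conditioned on the SNP-level weights, so a unit
    whose members carry essentially no posterior mass is a zero neuron whose
    weight the phenotype cannot identify; rescaling such a column to unit
    variance would manufacture a spurious predictor out of shrinkage noise.

    Returns (H, b1, flags) with flags True for degenerate columns.
    """
    membership = mask.membership if isinstance(mask, AnnotationMask) else mask
    W = np.asarray(membership.todense() if hasattr(membership, "todense") else membership,
                   dtype=np.float64)
    Z = X @ (W * np.asarray(m_theta, dtype=np.float64)[:, None])
    b1 = -Z.mean(axis=0)
    Z = Z + b1[None, :]
    H = Z if linear else leaky_relu(Z)
    sd = H.std(axis=0)
    flags = sd <= 1e-12
    if pip_snp is not None:
        with np.errstate(divide="ignore"):
            log_none = W.T @ np.log1p(-np.minimum(np.asarray(pip_snp), 1 - 1e-12))
        p_any = -np.expm1(log_none)
        flags = flags | (p_any < 0.5)
    out = np.zeros_like(H)
    ok = ~flags
    out[:, ok] = (H[:, ok] - H[:, ok].mean(axis=0)) / sd[ok]
    return out, b1, flags


def average_over_grid(states: list[VEMState], elbos=None):
    """Importance-weight per-grid variational fits by their lower bounds.

    Weights are softmax(ELBO) computed through log-sum-exp; returns
    (weights, averaged alpha, averaged posterior mean vector).
    """
    if not states:
        raise ValueError("no grid results to average")
    if elbos is None:
        elbos = [s.elbo_trace[-1] for s in states]
    elbos = np.asarray(elbos, dtype=np.float64)
    if not np.isfinite(elbos).any():
        raise ValueError("all grid lower bounds are -inf")
    w = np.exp(elbos - logsumexp(elbos))
    w = w / w.sum()
    alpha = sum(wi * s.alpha for wi, s in zip(w, states))
    m = sum(wi * s.m for wi, s in zip(w, states))
    return w, alpha, m


def compute_pips(alpha_inner: np.ndarray, alpha_outer: np.ndarray):
    """PIP(j) = sum_k alpha_jk; PIP(g) = alpha_w_g (both grid-averaged)."""
    pip_snp = np.clip(np.asarray(alpha_inner).sum(axis=1), 0.0, 1.0)
    pip_set = np.clip(np.asarray(alpha_outer).ravel(), 0.0, 1.0)
    return pip_snp, pip_set


def estimate_pve(Xs, ys, m_theta, H, m_w, var_theta=None, var_w=None):
    """Phenotypic variance explained at SNP and SNP-set scale.

    The ratio of the empirical variance of the fitted genetic predictor
    (X theta, respectively H w) to the empirical phenotype variance, taken
    in expectation under the variational posterior:
    E_q Var_N(X theta) = Var_N(X m) + sum_j (x_j'x_j/N) Var_q(theta_j).
    Using the full posterior rather than the point posterior mean avoids
    the downward bias that squaring partially-shrunk weights would
    introduce for coefficients with intermediate inclusion probability.
    Omitting ``var_theta``/``var_w`` falls back to the point version.
    Both estimates are clipped to [0, 1].
    """
    n = Xs.shape[0]
    vy = float(np.var(ys))
    pve_snp = float(np.var(Xs @ m_theta))
    if var_theta is not None:
        pve_snp += float(np.einsum("ij,ij->j", Xs, Xs) @ np.asarray(var_theta)) / n
    pve_set = float(np.var(H @ m_w))
    if var_w is not None:
        pve_set += float(np.einsum("ij,ij->j", H, H) @ np.asarray(var_w)) / n
    return float(np.clip(pve_snp / vy, 0, 1)), float(np.clip(pve_set / vy, 0, 1))


def _layer_pve(A, ys, states, weights) -> float:
    """Grid-averaged E_q Var_N(A beta) / Var_N(y), clipped to [0, 1]."""
    n = A.shape[0]
    atA = np.einsum("ij,ij->j", A, A)
    total = 0.0
    for w, s in zip(weights, states):
        total += w * (float(np.var(A @ s.m)) + float(atA @ s.posterior_variance()) / n)
    return float(np.clip(total / float(np.var(ys)), 0.0, 1.0))


def _two_stage_fit(
    Xs,
    ys,
    mask,
    input_prior: InputLayerPrior,
    hidden_prior: HiddenLayerPrior,
    grid_size: int,
    tol: float,
    max_sweeps: int,
    seed: int,
    linear_activation: bool,
    model_averaging: bool,
) -> FitResult:
    J = Xs.shape[1]
    membership = mask.membership if isinstance(mask, AnnotationMask) else mask
    G = membership.shape[1]
    ss = np.random.SeedSequence(seed)
    inner_seeds, outer_seeds = ss.spawn(2)

    pi_grid = input_prior.pi_grid
    if pi_grid is None:
        pi_grid = log_spaced_grid(1.0 / J, grid_size)
    pi_grid = np.asarray(pi_grid, dtype=np.float64)

    if model_averaging:
        inner_states = []
        children = inner_seeds.spawn(len(pi_grid))
        for i, pi in enumerate(pi_grid):
            rng = np.random.default_rng(children[i])
            inner_states.append(
                fit_inner(Xs, ys, input_prior, pi, tol=tol, max_sweeps=max_sweeps, rng=rng)
            )
        elbos_in = np.array([s.elbo_trace[-1] for s in inner_states])
        w_in, alpha_in, m_theta = average_over_grid(inner_states, elbos_in)
    else:
        rng = np.random.default_rng(inner_seeds)
        state = _fit_layer(
            Xs, ys, input_prior.sigma2, input_prior.eta_array(),
            pi=float(np.exp(0.5 * np.log(1.0 / J))), tol=tol, max_sweeps=max_sweeps,
            rng=rng, update_pi=True, pi_min=1.0 / J,
        )
        inner_states = [state]
        elbos_in = np.array([state.elbo_trace[-1]])
        w_in = np.array([1.0])
        alpha_in, m_theta = state.alpha, state.m

    pip_in = np.clip(np.asarray(alpha_in).sum(axis=1), 0.0, 1.0)
    H, b1, flags = compute_hidden_activations(
        Xs, mask, m_theta, linear=linear_activation, pip_snp=pip_in
    )
    ok = ~flags
    alpha_w = np.zeros(G)
    m_w = np.zeros(G)
    if ok.any():
        Hok = H[:, ok]
        pi_w_grid = hidden_prior.pi_w_grid
        if pi_w_grid is None:
            pi_w_grid = log_spaced_grid(1.0 / G, grid_size)
        pi_w_grid = np.asarray(pi_w_grid, dtype=np.float64)
        if model_averaging:
            outer_states = []
            children = outer_seeds.spawn(len(pi_w_grid))
            for i, pi in enumerate(pi_w_grid):
                rng = np.random.default_rng(children[i])
                outer_states.append(
                    fit_outer(Hok, ys, hidden_prior, pi, tol=tol, max_sweeps=max_sweeps, rng=rng)
                )
            elbos_out = np.array([s.elbo_trace[-1] for s in outer_states])
            w_out, alpha_out, m_w_ok = average_over_grid(outer_states, elbos_out)
        else:
            rng = np.random.default_rng(outer_seeds)
            state = _fit_layer(
                Hok, ys, (hidden_prior.sigma2_w,), (1.0,),
                pi=float(np.exp(0.5 * np.log(1.0 / G))), tol=tol, max_sweeps=max_sweeps,
                rng=rng, update_pi=True, pi_min=1.0 / G,
            )
            outer_states = [state]
            elbos_out = np.array([state.elbo_trace[-1]])
            w_out = np.array([1.0])
            alpha_out, m_w_ok = state.alpha, state.m
        alpha_w[ok] = np.asarray(alpha_out).ravel()
        m_w[ok] = m_w_ok
    else:
        outer_states = []
        elbos_out = np.zeros(0)
        w_out = np.zeros(0)

    pip_snp, pip_set = compute_pips(alpha_in, alpha_w.reshape(-1, 1))
    pve_snp = _layer_pve(Xs, ys, inner_states, w_in)
    if outer_states:
        Hok = H[:, ~flags]
        pve_set = _layer_pve(Hok, ys, outer_states, w_out)
    else:
        pve_set = 0.0
    return FitResult(
        pip_snp=pip_snp,
        pip_set=pip_set,
        m_theta=np.asarray(m_theta),
        m_w=m_w,
        bias_hidden=b1,
        bias_output=float(ys.mean()),
        pve_snp=pve_snp,
        pve_set=pve_set,
        grid_elbos_inner=elbos_in,
        grid_elbos_outer=elbos_out,
        grid_weights_inner=w_in,
        grid_weights_outer=w_out,
        elbo_trace_inner=[s.elbo_trace for s in inner_states],
        elbo_trace_outer=[s.elbo_trace for s in outer_states],
        converged=all(s.converged for s in inner_states + outer_states),
        n_sweeps=sum(s.n_sweeps for s in inner_states + outer_states),
        dropped_sets=flags,
    )


class BANN(RegressorMixin, BaseEstimator):
    """Biologically annotated Bayesian network regression on individual data.

    Parameters
    ----------
    membership : J x G binary SNP-set membership (AnnotationMask or array).
        Defines the partially connected architecture; required at fit time.
    K : number of nonzero mixture components in the SNP-weight prior.
    sigma2_init : initial slab variances, strictly decreasing (geometric
        decades by default); refined by M-step updates during fitting.
    sigma2_w : slab variance of the SNP-set weight prior.
    grid_size : number of log-spaced inclusion-probability grid values per
        layer ([1/J, 1] inner, [1/G, 1] outer).
    tol, max_sweeps : convergence tolerance on the lower-bound change and
        sweep cap for each grid point.
    linear_activation : replace the leaky ReLU by the identity (fully linear
        hierarchical model ablation).
    model_averaging : average fits over the grid with softmax(ELBO) weights;
        when False a single model is fit with pi updated in the M-step.
    random_state : seed for prior-draw initialization.

    Attributes
    ----------
    pip_snp_, pip_set_ : posterior inclusion probabilities per SNP / SNP-set.
    coef_snp_, coef_set_ : posterior mean weights.
    pve_snp_, pve_set_ : estimated phenotypic variance explained.
    result_ : the full :class:`FitResult`.
    """

    def __init__(
        self,
        membership=None,
        K: int = 3,
        sigma2_init=(1.0, 0.1, 0.01),
        eta=None,
        sigma2_w: float = 1.0,
        grid_size: int = 20,
        tol: float = DEFAULT_TOL,
        max_sweeps: int = DEFAULT_MAX_SWEEPS,
        linear_activation: bool = False,
        model_averaging: bool = True,
        random_state: int = 0,
    ):
        self.membership = membership
        self.K = K
        self.sigma2_init = sigma2_init
        self.eta = eta
        self.sigma2_w = sigma2_w
        self.grid_size = grid_size
        self.tol = tol
        self.max_sweeps = max_sweeps
        self.linear_activation = linear_activation
        self.model_averaging = model_averaging
        self.random_state = random_state

    def _priors(self):
        sigma2 = tuple(self.sigma2_init)[: self.K]
        if len(sigma2) != self.K:
            raise ValueError("sigma2_init must provide K variances")
        return (
            InputLayerPrior(sigma2=sigma2, eta=self.eta),
            HiddenLayerPrior(sigma2_w=self.sigma2_w),
        )

    def fit(self, X, y, covariates=None, snp_ids=None):
        if self.membership is None:
            raise ValueError("membership (SNP-set annotation mask) is required")
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with rows matching y")
        membership = (
            self.membership.membership
            if isinstance(self.membership, AnnotationMask)
            else self.membership
        )
        if membership.shape[0] != X.shape[1]:
            raise ValueError(
                f"membership has {membership.shape[0]} SNP rows but X has {X.shape[1]} columns"
            )
        Xs, ys, info = standardize(X, y, covariates=covariates, snp_ids=snp_ids)
        input_prior, hidden_prior = self._priors()
        result = _two_stage_fit(
            Xs, ys, self.membership, input_prior, hidden_prior,
            grid_size=self.grid_size, tol=self.tol, max_sweeps=self.max_sweeps,
            seed=self.random_state, linear_activation=self.linear_activation,
            model_averaging=self.model_averaging,
        )
        self.standardize_info_ = info
        self.result_ = result
        self.pip_snp_ = result.pip_snp
        self.pip_set_ = result.pip_set
        self.coef_snp_ = result.m_theta
        self.coef_set_ = result.m_w
        self.pve_snp_ = result.pve_snp
        self.pve_set_ = result.pve_set
        self.converged_ = result.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "result_")
        X = np.asarray(X, dtype=np.float64)
        info = self.standardize_info_
        Xs = (X - info["x_center"]) / info["x_scale"]
        H, _, _ = compute_hidden_activations(
            Xs, self.membership, self.coef_snp_, linear=self.linear_activation,
            pip_snp=self.pip_snp_,
        )
        yhat = H @ self.coef_set_
        return yhat * info["y_scale"] + info["y_center"]


def fit(X, y, mask, covariates=None, **params) -> FitResult:
    """Functional entry point: fit the network and return its FitResult."""
    model = BANN(membership=mask, **params)
    model.fit(X, y, covariates=covariates)
    return model.result_
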