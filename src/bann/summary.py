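"""Summary-statistics mode: fit the network from marginal effects and LD.

When individual genotypes are unavailable, the observed ordinary-least-
squares marginal effects theta_hat and the J x J LD correlation matrix R act
as proxies for the phenotype and genotypes: asymptotically
E[theta_hat_j] = sum_j' r(x_j, x_j') theta_j', a regression of theta_hat on R
with the true SNP effects as coefficients.  The same two-stage variational EM
is therefore run with response theta_hat and design R; hidden activations use
the R_g columns, and the output contract matches the individual-level fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .annotation import AnnotationMask
from .inference import (
    FitResult,
    HiddenLayerPrior,
    InputLayerPrior,
    _two_stage_fit,
    DEFAULT_TOL,
    DEFAULT_MAX_SWEEPS,
)

__all__ = ["SummaryData", "ols_effects", "ld_matrix", "fit_ss", "BANNSummary"]


@dataclass
class SummaryData:
    """GWA summary statistics: OLS marginal effects, SEs, and LD matrix."""

    theta_hat: np.ndarray
    se: np.ndarray
    ld: np.ndarray
    n_effective: int

    def validate(self) -> None:
        J = len(self.theta_hat)
        R = np.asarray(self.ld)
        if R.shape != (J, J):
            raise ValueError(f"LD matrix shape {R.shape} does not match J={J}")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-6):
            raise ValueError("LD matrix diagonal is not 1")
        if np.abs(R).max() > 1 + 1e-6:
            raise ValueError("LD entries outside [-1, 1]")


def ols_effects(X, y):
    """Per-SNP univariate OLS effects and standard errors.

    theta_hat_j = x_j'y / x_j'x_j on (standardized) inputs; the standard
    error uses the classical single-regressor residual variance with an N-2
    denominator.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    xtx = np.einsum("ij,ij->j", X, X)
    if (xtx <= 0).any():
        raise ValueError(f"zero-variance columns: {np.flatnonzero(xtx <= 0).tolist()}")
    theta_hat = (X.T @ y) / xtx
    n = len(y)
    rss = (y @ y) - theta_hat**2 * xtx  # ||y - x theta||^2 per SNP
    se = np.sqrt(np.maximum(rss, 0.0) / max(n - 2, 1) / xtx)
    return theta_hat, se


def ld_matrix(X):
    """Empirical LD: pairwise Pearson correlations of genotype columns."""
    X = np.asarray(X, dtype=np.float64)
    if (X.std(axis=0) <= 0).any():
        raise ValueError(
            f"zero-variance columns: {np.flatnonzero(X.std(axis=0) <= 0).tolist()}"
        )
    R = np.corrcoef(X, rowvar=False)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


class BANNSummary(BaseEstimator):
    """Network fit from GWA summary statistics (LD design, OLS response).

    Parameters mirror :class:`bann.inference.BANN`; ``shrinkage`` optionally
    regularizes the LD matrix as (1 - lambda) R + lambda I for rank-deficient
    external panels (default 0: in-sample LD needs none).  theta_hat is used
    raw — the residual variance absorbs its scale.
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
        shrinkage: float = 0.0,
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
        self.shrinkage = shrinkage
        self.random_state = random_state

    def fit(self, R, theta_hat):
        if self.membership is None:
            raise ValueError("membership (SNP-set annotation mask) is required")
        R = np.asarray(R, dtype=np.float64)
        theta_hat = np.asarray(theta_hat, dtype=np.float64).ravel()
        if R.shape[0] != R.shape[1] or R.shape[0] != len(theta_hat):
            raise ValueError("R must be J x J matching theta_hat")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("LD matrix is not symmetric")
        membership = (
            self.membership.membership
            if isinstance(self.membership, AnnotationMask)
            else self.membership
        )
        if membership.shape[0] != len(theta_hat):
            raise ValueError("membership rows do not match the number of SNPs")
        if self.shrinkage:
            R = (1 - self.shrinkage) * R + self.shrinkage * np.eye(len(theta_hat))
        sigma2 = tuple(self.sigma2_init)[: self.K]
        result = _two_stage_fit(
            R,
            theta_hat,
            self.membership,
            InputLayerPrior(sigma2=sigma2, eta=self.eta),
            HiddenLayerPrior(sigma2_w=self.sigma2_w),
            grid_size=self.grid_size,
            tol=self.tol,
            max_sweeps=self.max_sweeps,
            seed=self.random_state,
            linear_activation=self.linear_activation,
            model_averaging=self.model_averaging,
        )
        self.result_ = result
        self.pip_snp_ = result.pip_snp
        self.pip_set_ = result.pip_set
        self.coef_snp_ = result.m_theta
        self.coef_set_ = result.m_w
        self.pve_snp_ = result.pve_snp
        self.pve_set_ = result.pve_set
        self.converged_ = result.converged
        return self


def fit_ss(summary: SummaryData, mask, **params) -> FitResult:
    """Fit the network from summary statistics; contract mirrors ``fit``."""
    summary.validate()
    model = BANNSummary(membership=mask, **params)
    model.fit(summary.ld, summary.theta_hat)
    return model.result_
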