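"""Generalized least squares and the Q quadratic forms (pivots).

Every estimator in this package rests on quadratic forms of the type

    Q(V) = (Y - Yhat)' V^{-1} (Y - Yhat),    Yhat = X (X'V^{-1}X)^{-1} X'V^{-1} Y,

which follows a chi-square distribution with n - c degrees of freedom when
Y is multivariate normal with covariance V and a mean that is linear in c
location parameters.  Evaluated with the total covariance
``tau_beta^2 M1 + tau_omega^2 M2 + S`` these quadratic forms are pivots:
continuous, strictly decreasing in each variance argument, and vanishing as
that argument grows, which makes moment-matching estimation well posed.

All V-inverse products go through symmetric positive-definite Cholesky
factorizations; a factorization failure raises rather than silently
regularizing, since hidden ridging would bias the variance estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .data import DesignSubmodel, NetworkMatrices
from .exceptions import NumericalError

__all__ = [
    "VarianceComponents",
    "GlsResult",
    "QDecomposition",
    "PivotEvaluation",
    "gls_fit",
    "q_pivot_net",
    "q_pivot_het",
    "q_decompose",
    "total_covariance",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Between-study heterogeneity and inconsistency variances.

    ``truncated_*`` flags record when a moment estimate was negative (or at
    the boundary) and was set to zero.
    """

    tau_beta_sq: float
    tau_omega_sq: float = 0.0
    truncated_beta: bool = False
    truncated_omega: bool = False

    def __post_init__(self):
        if self.tau_beta_sq < 0 or self.tau_omega_sq < 0:
            raise ValueError("variance components must be nonnegative")

    def astuple(self) -> tuple[float, float]:
        return (self.tau_beta_sq, self.tau_omega_sq)


@dataclass(frozen=True, eq=False)
class GlsResult:
    delta_hat: np.ndarray
    cov_delta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray


@dataclass(frozen=True)
class QDecomposition:
    """Split of the network Q statistic (within-study weights) into
    per-design heterogeneity terms and a between-design inconsistency term."""

    q_net: float
    q_het_by_design: dict
    q_inc: float

    @property
    def q_het_total(self) -> float:
        return float(sum(self.q_het_by_design.values()))


@dataclass(frozen=True)
class PivotEvaluation:
    value: float
    df: int
    at: VarianceComponents


def _as_vc(vc) -> VarianceComponents:
    if isinstance(vc, VarianceComponents):
        return vc
    tb, tw = vc
    return VarianceComponents(float(tb), float(tw))


def total_covariance(net: NetworkMatrices, vc) -> np.ndarray:
    """The marginal covariance of Y: tau_beta^2 M1 + tau_omega^2 M2 + S."""
    vc = _as_vc(vc)
    return vc.tau_beta_sq * net.M1 + vc.tau_omega_sq * net.M2 + net.S


def _gls_core(Y, X, V, context=""):
    """GLS fit plus the weighted residual quadratic form, via one Cholesky."""
    try:
        f = cho_factor(V, lower=True, check_finite=False)
    except (LinAlgError, ValueError) as exc:
        raise NumericalError(
            f"covariance matrix is not positive definite{context}: {exc}"
        ) from exc
    Vi_X = cho_solve(f, X, check_finite=False)
    Vi_Y = cho_solve(f, Y, check_finite=False)
    XtViX = X.T @ Vi_X
    try:
        g = cho_factor(XtViX, lower=True, check_finite=False)
    except (LinAlgError, ValueError) as exc:
        raise NumericalError(
            f"design matrix is rank deficient under these weights{context}: {exc}"
        ) from exc
    delta = cho_solve(g, X.T @ Vi_Y, check_finite=False)
    cov = cho_solve(g, np.eye(XtViX.shape[0]), check_finite=False)
    cov = 0.5 * (cov + cov.T)
    fitted = X @ delta
    resid = Y - fitted
    q = float(resid @ cho_solve(f, resid, check_finite=False))
    return delta, cov, fitted, resid, q


def gls_fit(Y: np.ndarray, X: np.ndarray, V: np.ndarray) -> GlsResult:
    """Weighted regression of Y on X with weight matrix V^{-1}.

    delta_hat = (X'V^{-1}X)^{-1} X'V^{-1} Y with covariance (X'V^{-1}X)^{-1};
    all products use linear solves on Cholesky factors, never an explicit
    inverse of V.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    V = np.atleast_2d(np.asarray(V, dtype=float))
    delta, cov, fitted, resid, _ = _gls_core(Y, X, V)
    return GlsResult(delta, cov, fitted, resid)


def q_pivot_net(net: NetworkMatrices, vc) -> PivotEvaluation:
    """The whole-network Q pivot at the given variance components.

    At (0, 0) this is the classical network Q statistic with within-study
    weights; at (tau_beta^2, 0) it is the consistency-model pivot; in general
    it weights by the full-model total precision.  Distribution under the
    generating model: chi-square with n - c degrees of freedom.
    """
    vc = _as_vc(vc)
    V = total_covariance(net, vc)
    *_, q = _gls_core(net.Y, net.X, V, context=" (network pivot)")
    return PivotEvaluation(value=q, df=net.n - net.c, at=vc)


def q_pivot_het(design: DesignSubmodel, tau_beta_sq: float) -> PivotEvaluation:
    """The single-design heterogeneity Q pivot at the given tau_beta^2.

    Uses only the design's own data; degrees of freedom (n_d - 1) c_d.  A
    design observed in one study is saturated and contributes exactly zero.
    """
    vc = VarianceComponents(float(tau_beta_sq), 0.0)
    if design.n_d == 1:
        return PivotEvaluation(value=0.0, df=0, at=vc)
    V = tau_beta_sq * design.M_d + design.S_d
    *_, q = _gls_core(
        design.Y_d, design.X_d, V, context=f" (design {design.design_id})"
    )
    return PivotEvaluation(value=q, df=design.df_het, at=vc)


def q_het_total(net: NetworkMatrices, tau_beta_sq: float) -> float:
    """Sum of the per-design heterogeneity pivots at a common tau_beta^2."""
    return float(
        sum(q_pivot_het(d, tau_beta_sq).value for d in net.designs if d.n_d > 1)
    )


def q_decompose(net: NetworkMatrices) -> QDecomposition:
    """Q_net = sum_d Q_d_het + Q_inc at within-study weights (both variance
    components zero); the inconsistency term is obtained by subtraction and
    is nonnegative up to round-off."""
    q_net = q_pivot_net(net, (0.0, 0.0)).value
    per_design = {d.design_id: q_pivot_het(d, 0.0).value for d in net.designs}
    q_inc = q_net - sum(per_design.values())
    return QDecomposition(q_net=q_net, q_het_by_design=per_design, q_inc=q_inc)
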