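"""Estimators of the heterogeneity and inconsistency variances.

Three classical estimators of (tau_beta^2, tau_omega^2) are provided.

* Paule-Mandel (``estimate_pm_full`` / ``estimate_pm_consistency``): match
  each Q pivot, evaluated with total-precision weights, to its chi-square
  expectation.  Under the full model the summed single-design pivots depend
  on tau_beta^2 alone and are matched to sum_d (n_d - 1) c_d; the resulting
  estimate is then held fixed while the whole-network pivot is matched to
  n - c to estimate tau_omega^2.  Under the consistency assumption
  (tau_omega^2 = 0) the whole-network pivot alone estimates tau_beta^2.
  Because each pivot is continuous, strictly decreasing in its variance
  argument and vanishes at infinity, every estimating equation has a unique
  root (or is truncated to zero), so no convergence diagnostics are needed.

* DerSimonian-Laird (``estimate_dl``): the same moment-matching idea with
  within-study weights, which makes both expectations linear in the unknown
  variances and the estimates closed form.

* REML / ML (``estimate_reml`` / ``estimate_ml``): numerical maximization of
  the (restricted) Gaussian log-likelihood over the nonnegative quadrant.
  REML is the fully parametric gold standard; the moment estimators are
  semiparametric in that their estimating equations only use second moments.

Negative or boundary solutions are truncated to zero and flagged.  All
estimators are deterministic given the data; no randomness is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import brentq, minimize

from .data import NetworkMatrices
from .exceptions import ConvergenceError, IdentifiabilityError, NumericalError
from .gls import VarianceComponents, q_het_total, q_pivot_net, total_covariance

__all__ = [
    "EstimationResult",
    "DlCoefficients",
    "solve_monotone",
    "estimate_pm_full",
    "estimate_pm_consistency",
    "dl_moment_coefficients",
    "estimate_dl",
    "restricted_loglik",
    "marginal_loglik",
    "estimate_reml",
    "estimate_ml",
    "estimate",
]


@dataclass(frozen=True)
class EstimationResult:
    vc: VarianceComponents
    method: str  # PM, DL, REML or ML
    model: str  # full or consistency
    diagnostics: dict


# ---------------------------------------------------------------------------
# root finding for monotone pivots
# ---------------------------------------------------------------------------


def solve_monotone(pivot, target_df: float, upper0: float = 1.0):
    """Solve ``pivot(x) = target_df`` for a continuous, strictly decreasing
    ``pivot`` with ``pivot(x) -> 0`` as ``x -> inf``.

    Returns ``(root, truncated)``.  If ``pivot(0) <= target_df`` the solution
    is truncated to zero (the data show less variation than expected with a
    zero variance component).  Otherwise the unique root is bracketed by
    doubling an upper bound and found by bisection-type iteration.
    """
    f0 = float(pivot(0.0))
    if not np.isfinite(f0):
        raise NumericalError("pivot evaluation at 0 is not finite")
    if f0 <= target_df:
        return 0.0, True
    u = max(float(upper0), 1e-8)
    for _ in range(200):
        fu = float(pivot(u))
        if not np.isfinite(fu):
            raise NumericalError(f"pivot evaluation at {u} is not finite")
        if fu < target_df:
            break
        u *= 2.0
    else:
        raise NumericalError("failed to bracket the pivot root")
    root = brentq(
        lambda t: float(pivot(t)) - target_df,
        0.0,
        u,
        xtol=1e-13,
        rtol=8.9e-16,
        maxiter=500,
    )
    return float(root), False


def _default_upper(net: NetworkMatrices) -> float:
    return 1.0 + float(np.max(np.diag(net.S)))


# ---------------------------------------------------------------------------
# Paule-Mandel
# ---------------------------------------------------------------------------


def _require_multiple_designs(net: NetworkMatrices):
    if len(net.designs) < 2:
        raise IdentifiabilityError(
            "the full model needs at least two designs: with a single design "
            "the design means and the inconsistency effects are aliased"
        )


def _pm_tau_beta_full(net: NetworkMatrices):
    df_het = sum(d.df_het for d in net.designs)
    if df_het == 0:
        warnings.warn(
            "no design is observed in more than one study, so the "
            "between-study variance is not identifiable under the full "
            "model; reporting tau_beta^2 = 0",
            stacklevel=3,
        )
        return 0.0, True, float(df_het), True
    tb, trunc = solve_monotone(
        lambda t: q_het_total(net, t), float(df_het), _default_upper(net)
    )
    return tb, trunc, float(df_het), False


def estimate_pm_full(net: NetworkMatrices) -> EstimationResult:
    """Paule-Mandel estimates of both variance components under the full
    design-by-treatment interaction model."""
    _require_multiple_designs(net)
    tb, trunc_b, df_het, no_repl = _pm_tau_beta_full(net)
    target = float(net.n - net.c)
    tw, trunc_w = solve_monotone(
        lambda w: q_pivot_net(net, (tb, w)).value, target, _default_upper(net)
    )
    vc = VarianceComponents(tb, tw, truncated_beta=trunc_b, truncated_omega=trunc_w)
    diag = {
        "residual_het": 0.0 if trunc_b else q_het_total(net, tb) - df_het,
        "residual_net": 0.0 if trunc_w else q_pivot_net(net, (tb, tw)).value - target,
        "df_het": df_het,
        "df_net": target,
        "no_replication": no_repl,
        "converged": True,
    }
    return EstimationResult(vc=vc, method="PM", model="full", diagnostics=diag)


def estimate_pm_consistency(net: NetworkMatrices) -> EstimationResult:
    """Paule-Mandel estimate of tau_beta^2 under the consistency assumption
    (tau_omega^2 = 0), matching the whole-network pivot to n - c."""
    target = float(net.n - net.c)
    tb, trunc = solve_monotone(
        lambda t: q_pivot_net(net, (t, 0.0)).value, target, _default_upper(net)
    )
    vc = VarianceComponents(tb, 0.0, truncated_beta=trunc)
    diag = {
        "residual_net": 0.0 if trunc else q_pivot_net(net, (tb, 0.0)).value - target,
        "df_net": target,
        "converged": True,
    }
    return EstimationResult(vc=vc, method="PM", model="consistency", diagnostics=diag)


# ---------------------------------------------------------------------------
# DerSimonian-Laird moments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DlCoefficients:
    """Coefficients of the linear moment equations with within-study weights.

    E[Q_net]        = a0 + a1 tau_beta^2 + a2 tau_omega^2,  a0 = n - c
    E[sum Q_d_het]  = df_het + b1 tau_beta^2
    """

    a0: float
    a1: float
    a2: float
    b1: float
    df_het: float
    q_net0: float
    q_het0: float


def _annihilator(Y, X, S, context=""):
    """A = W - W H with W = S^{-1} and H the weighted hat matrix, plus Y'AY."""
    try:
        f = cho_factor(S, lower=True, check_finite=False)
    except (LinAlgError, ValueError) as exc:
        raise NumericalError(f"S is not positive definite{context}") from exc
    W = cho_solve(f, np.eye(S.shape[0]), check_finite=False)
    U = W @ X
    G = X.T @ U
    A = W - U @ np.linalg.solve(G, U.T)
    A = 0.5 * (A + A.T)
    return A, float(Y @ A @ Y)


def dl_moment_coefficients(net: NetworkMatrices) -> DlCoefficients:
    """Coefficients of the DerSimonian-Laird moment-matching equations."""
    A, q_net0 = _annihilator(net.Y, net.X, net.S, " (network)")
    a1 = float(np.sum(A * net.M1))
    a2 = float(np.sum(A * net.M2))
    b1 = 0.0
    q_het0 = 0.0
    df_het = 0.0
    for d in net.designs:
        if d.n_d == 1:
            continue
        A_d, q_d = _annihilator(d.Y_d, d.X_d, d.S_d, f" (design {d.design_id})")
        b1 += float(np.sum(A_d * d.M_d))
        q_het0 += q_d
        df_het += d.df_het
    return DlCoefficients(
        a0=float(net.n - net.c),
        a1=a1,
        a2=a2,
        b1=b1,
        df_het=df_het,
        q_net0=q_net0,
        q_het0=q_het0,
    )


def estimate_dl(net: NetworkMatrices, model: str = "full") -> EstimationResult:
    """Closed-form method-of-moments estimates with within-study weights.

    Full model: tau_beta^2 from the heterogeneity equation, substituted into
    the network equation to give tau_omega^2.  Consistency model: tau_beta^2
    from the network equation with tau_omega^2 = 0.  Negative solutions are
    truncated to zero.
    """
    coef = dl_moment_coefficients(net)
    if model == "consistency":
        raw = (coef.q_net0 - coef.a0) / coef.a1
        tb = max(0.0, raw)
        vc = VarianceComponents(tb, 0.0, truncated_beta=raw <= 0.0)
        diag = {"coefficients": coef, "converged": True}
        return EstimationResult(vc=vc, method="DL", model="consistency", diagnostics=diag)
    if model != "full":
        raise ValueError(f"unknown model {model!r}")
    _require_multiple_designs(net)
    no_repl = coef.df_het == 0
    if no_repl:
        warnings.warn(
            "no design is observed in more than one study, so the "
            "between-study variance is not identifiable under the full "
            "model; reporting tau_beta^2 = 0",
            stacklevel=2,
        )
        tb, trunc_b = 0.0, True
    else:
        raw_b = (coef.q_het0 - coef.df_het) / coef.b1
        tb, trunc_b = max(0.0, raw_b), raw_b <= 0.0
    raw_w = (coef.q_net0 - coef.a0 - coef.a1 * tb) / coef.a2
    tw, trunc_w = max(0.0, raw_w), raw_w <= 0.0
    vc = VarianceComponents(tb, tw, truncated_beta=trunc_b, truncated_omega=trunc_w)
    diag = {"coefficients": coef, "no_replication": no_repl, "converged": True}
    return EstimationResult(vc=vc, method="DL", model="full", diagnostics=diag)


# ---------------------------------------------------------------------------
# likelihood-based estimation
# ---------------------------------------------------------------------------


def _loglik_core(net: NetworkMatrices, tb, tw, restricted, want_grad=False):
    V = tb * net.M1 + tw * net.M2 + net.S
    try:
        f = cho_factor(V, lower=True, check_finite=False)
    except (LinAlgError, ValueError) as exc:
        raise NumericalError("total covariance is not positive definite") from exc
    n = net.n
    Vi = cho_solve(f, np.eye(n), check_finite=False)
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(f[0]))))
    Vi_X = Vi @ net.X
    G = net.X.T @ Vi_X
    try:
        g = cho_factor(G, lower=True, check_finite=False)
    except (LinAlgError, ValueError) as exc:
        raise NumericalError("X'V^{-1}X is singular") from exc
    delta = cho_solve(g, Vi_X.T @ net.Y, check_finite=False)
    r = net.Y - net.X @ delta
    Vi_r = Vi @ r
    ll = -0.5 * (logdet_v + float(r @ Vi_r))
    if restricted:
        ll -= float(np.sum(np.log(np.diag(g[0]))))  # 0.5 * logdet(G)
    if not want_grad:
        return ll, None
    if restricted:
        # P = V^{-1} - V^{-1} X G^{-1} X' V^{-1}; note P Y = V^{-1} r
        K = cho_solve(g, Vi_X.T, check_finite=False)
        P = Vi - Vi_X @ K
        grad = np.array(
            [
                -0.5 * (float(np.sum(P * M)) - float(Vi_r @ M @ Vi_r))
                for M in (net.M1, net.M2)
            ]
        )
    else:
        grad = np.array(
            [
                -0.5 * (float(np.sum(Vi * M)) - float(Vi_r @ M @ Vi_r))
                for M in (net.M1, net.M2)
            ]
        )
    return ll, grad


def restricted_loglik(net: NetworkMatrices, vc) -> float:
    """Restricted log-likelihood (constants dropped):
    -0.5 [log det V + log det(X'V^{-1}X) + r'V^{-1}r]."""
    tb, tw = vc.astuple() if isinstance(vc, VarianceComponents) else vc
    return _loglik_core(net, float(tb), float(tw), restricted=True)[0]


def marginal_loglik(net: NetworkMatrices, vc) -> float:
    """Profile (marginal) log-likelihood with the basic parameters replaced
    by their GLS estimates: -0.5 [log det V + r'V^{-1}r]."""
    tb, tw = vc.astuple() if isinstance(vc, VarianceComponents) else vc
    return _loglik_core(net, float(tb), float(tw), restricted=False)[0]


def _optimize_loglik(net, model, restricted, label):
    if model not in ("full", "consistency"):
        raise ValueError(f"unknown model {model!r}")
    if model == "full":
        _require_multiple_designs(net)

    # moment estimates double as starting values
    def _safe(fn):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn().vc.astuple()
        except Exception:
            return None

    if model == "full":
        pm = _safe(lambda: estimate_pm_full(net))
        dl = _safe(lambda: estimate_dl(net, "full"))
    else:
        pm = _safe(lambda: estimate_pm_consistency(net))
        dl = _safe(lambda: estimate_dl(net, "consistency"))
    anchor = max(
        [v for point in (pm, dl) if point is not None for v in point], default=1.0
    )
    bound = 10.0 * (anchor + 1.0)
    starts = [(0.0, 0.0)]
    for point in (dl, pm):
        if point is not None and point not in starts:
            starts.append(point)
    if len(starts) == 1:
        starts.append((0.1, 0.1))

    free = (0, 1) if model == "full" else (0,)

    def objective(theta):
        tb = theta[0] if 0 in free else 0.0
        tw = theta[free.index(1)] if 1 in free else 0.0
        try:
            ll, grad = _loglik_core(net, tb, tw, restricted, want_grad=True)
        except NumericalError:
            return np.inf, np.zeros(len(free))
        return -ll, -grad[list(free)]

    best = None
    tried = 0
    for start in starts:
        x0 = np.clip([start[i] for i in free], 0.0, bound)
        tried += 1
        res = minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, bound)] * len(free),
            options={"ftol": 1e-12, "gtol": 1e-8, "maxiter": 300},
        )
        if best is None or (res.success and not best[1]) or (
            res.success == best[1] and res.fun < best[0].fun
        ):
            best = (res, res.success)
    res, converged = best
    tb = float(res.x[0]) if 0 in free else 0.0
    tw = float(res.x[free.index(1)]) if 1 in free else 0.0
    vc = VarianceComponents(max(tb, 0.0), max(tw, 0.0))
    diag = {
        "loglik": -float(res.fun),
        "iterations": int(res.nit),
        "converged": bool(converged),
        "starts_tried": tried,
        "bound": bound,
        "message": str(res.message),
    }
    result = EstimationResult(vc=vc, method=label, model=model, diagnostics=diag)
    if not converged:
        raise ConvergenceError(
            f"{label} failed to converge from every start: {res.message}",
            best=result,
        )
    return result


def estimate_reml(net: NetworkMatrices, model: str = "full") -> EstimationResult:
    """REML estimates via bounded quasi-Newton maximization with analytic
    gradients and multiple starts (origin plus both moment estimates)."""
    return _optimize_loglik(net, model, restricted=True, label="REML")


def estimate_ml(net: NetworkMatrices, model: str = "full") -> EstimationResult:
    """Maximum-likelihood estimates (biased downwards in small networks;
    REML is preferred and is the default elsewhere in the package)."""
    return _optimize_loglik(net, model, restricted=False, label="ML")


_METHODS = {
    ("pm", "full"): estimate_pm_full,
    ("pm", "consistency"): estimate_pm_consistency,
    ("dl", "full"): lambda net: estimate_dl(net, "full"),
    ("dl", "consistency"): lambda net: estimate_dl(net, "consistency"),
    ("reml", "full"): lambda net: estimate_reml(net, "full"),
    ("reml", "consistency"): lambda net: estimate_reml(net, "consistency"),
    ("ml", "full"): lambda net: estimate_ml(net, "full"),
    ("ml", "consistency"): lambda net: estimate_ml(net, "consistency"),
}


def estimate(net: NetworkMatrices, method: str = "pm", model: str = "full") -> EstimationResult:
    """Dispatch to one of the variance-component estimators."""
    key = (method.lower(), model.lower())
    if key not in _METHODS:
        raise ValueError(f"unknown method/model combination {key!r}")
    return _METHODS[key](net)
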