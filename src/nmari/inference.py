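"""Treatment-effect inference and variance-component confidence intervals.

After the variance components are estimated, inference for the basic
parameters proceeds as a weighted regression in which the plugged-in weights
are treated as fixed and known: the GLS estimate of the basic parameters is
multivariate normal with covariance (X'V^{-1}X)^{-1}, and any pairwise
average effect is a difference of two basic parameters.  Wald intervals use
normal quantiles throughout (no small-sample adjustment), matching the
fixed-weight framing under which the coverage simulations are interpreted.

Two kinds of interval for the variance components are provided:

* Q-profile intervals for tau_beta^2 under the consistency model, obtained
  by inverting the chi-square distribution of the monotone network pivot;
* profile-likelihood intervals around the REML estimates, profiling out the
  other variance component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2, norm

from .data import NetworkMatrices
from .estimators import (
    EstimationResult,
    estimate,
    estimate_reml,
    restricted_loglik,
    solve_monotone,
)
from .gls import (
    GlsResult,
    VarianceComponents,
    gls_fit,
    q_decompose,
    q_pivot_net,
    total_covariance,
)

__all__ = [
    "NMAFit",
    "VarianceCI",
    "fit_network",
    "q_profile_ci_consistency",
    "profile_likelihood_ci",
]


@dataclass(frozen=True, eq=False)
class NMAFit:
    """A complete network meta-analysis fit.

    ``basic`` tabulates the basic parameters (effects relative to the
    reference); ``pairwise`` tabulates every unordered treatment comparison
    with its estimate, standard error and Wald interval.
    """

    network: NetworkMatrices
    est: EstimationResult
    gls: GlsResult
    basic: pd.DataFrame
    pairwise: pd.DataFrame
    level: float

    @property
    def reference(self) -> str:
        return self.network.reference

    @property
    def vc(self) -> VarianceComponents:
        return self.est.vc


@dataclass(frozen=True)
class VarianceCI:
    parameter: str  # tau_beta_sq or tau_omega_sq
    lower: float
    upper: float
    level: float
    method: str  # q_profile_consistency or profile_likelihood
    degenerate: bool = False
    open_upper: bool = False


def _basic_table(net: NetworkMatrices, gls: GlsResult, z: float) -> pd.DataFrame:
    se = np.sqrt(np.diag(gls.cov_delta))
    return pd.DataFrame(
        {
            "treatment": list(net.basic_labels),
            "estimate": gls.delta_hat,
            "se": se,
            "ci_low": gls.delta_hat - z * se,
            "ci_high": gls.delta_hat + z * se,
        }
    )


def _pairwise_table(net: NetworkMatrices, gls: GlsResult, z: float) -> pd.DataFrame:
    labels = net.treatments
    idx = {t: i for i, t in enumerate(net.basic_labels)}
    c = net.c

    def contrast_vector(t):
        v = np.zeros(c)
        if t != net.reference:
            v[idx[t]] = 1.0
        return v

    rows = []
    for a, i in zip(labels, range(len(labels))):
        for b in labels[i + 1 :]:
            v = contrast_vector(b) - contrast_vector(a)
            est = float(v @ gls.delta_hat)
            se = float(np.sqrt(v @ gls.cov_delta @ v))
            rows.append(
                {
                    "comparison": f"{a}{b}",
                    "treatment_1": a,
                    "treatment_2": b,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - z * se,
                    "ci_high": est + z * se,
                }
            )
    return pd.DataFrame(rows)


def fit_network(
    net: NetworkMatrices,
    method: str = "pm",
    model: str = "full",
    level: float = 0.95,
) -> NMAFit:
    """Estimate the variance components by the chosen method, then run GLS
    at the plugged-in total covariance and tabulate all treatment effects."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    est = estimate(net, method, model)
    V = total_covariance(net, est.vc)
    gls = gls_fit(net.Y, net.X, V)
    z = norm.ppf(0.5 + level / 2)
    return NMAFit(
        network=net,
        est=est,
        gls=gls,
        basic=_basic_table(net, gls, z),
        pairwise=_pairwise_table(net, gls, z),
        level=level,
    )


def q_profile_ci_consistency(net: NetworkMatrices, level: float = 0.95) -> VarianceCI:
    """Q-profile interval for tau_beta^2 under the consistency model.

    The network pivot at (tau_beta^2, 0) is chi-square with n - c degrees of
    freedom and strictly decreasing in tau_beta^2, so the interval bounds
    are the values at which the pivot crosses the upper and lower chi-square
    quantiles.  Crossings below zero are truncated; if the pivot at zero is
    already below the lower quantile the interval is degenerate at [0, 0].
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    df = net.n - net.c
    alpha = 1.0 - level
    hi_q = chi2.ppf(1 - alpha / 2, df)
    lo_q = chi2.ppf(alpha / 2, df)

    def pivot(t):
        return q_pivot_net(net, (t, 0.0)).value

    upper0 = 1.0 + float(np.max(np.diag(net.S)))
    lower, _ = solve_monotone(pivot, hi_q, upper0)
    q0 = pivot(0.0)
    if q0 <= lo_q:
        return VarianceCI(
            "tau_beta_sq", 0.0, 0.0, level, "q_profile_consistency", degenerate=True
        )
    upper, _ = solve_monotone(pivot, lo_q, upper0)
    return VarianceCI("tau_beta_sq", lower, upper, level, "q_profile_consistency")


def profile_likelihood_ci(
    net: NetworkMatrices,
    parameter: str = "tau_beta_sq",
    level: float = 0.95,
    reml_fit: EstimationResult | None = None,
) -> VarianceCI:
    """Profile-restricted-likelihood interval for one variance component.

    The other component is profiled out by a bounded one-dimensional
    maximization; the bounds are where twice the drop from the maximized
    restricted log-likelihood crosses the chi-square(1) quantile.  The upper
    search is capped; hitting the cap flags the interval as open-ended.
    """
    if parameter not in ("tau_beta_sq", "tau_omega_sq"):
        raise ValueError(f"unknown parameter {parameter!r}")
    fit = reml_fit if reml_fit is not None else estimate_reml(net, "full")
    max_ll = fit.diagnostics.get("loglik")
    if max_ll is None:
        max_ll = restricted_loglik(net, fit.vc)
    point = getattr(fit.vc, parameter)
    other_point = (
        fit.vc.tau_omega_sq if parameter == "tau_beta_sq" else fit.vc.tau_beta_sq
    )
    cap = max(10.0 * (point + 1.0), 10.0 * (other_point + 1.0))
    crit = chi2.ppf(level, 1)

    def profile_ll(value):
        def nll(other):
            vc = (
                (value, other) if parameter == "tau_beta_sq" else (other, value)
            )
            return -restricted_loglik(net, vc)

        res = minimize_scalar(nll, bounds=(0.0, cap), method="bounded",
                              options={"xatol": 1e-10})
        return -res.fun

    def g(value):
        # positive outside the confidence set
        return 2.0 * (max_ll - profile_ll(value)) - crit

    # lower bound
    if g(0.0) <= 0:
        lower = 0.0
    else:
        lower = brentq(g, 0.0, max(point, 1e-12), xtol=1e-10)
    # upper bound: expand a bracket beyond the point estimate
    hi = max(2.0 * point, 0.5)
    open_upper = False
    while g(hi) <= 0:
        hi *= 2.0
        if hi > cap:
            open_upper = True
            break
    if open_upper:
        upper = cap
    else:
        upper = brentq(g, max(point, 0.0), hi, xtol=1e-10)
    return VarianceCI(
        parameter, lower, upper, level, "profile_likelihood", open_upper=open_upper
    )


def q_decomposition_table(net: NetworkMatrices) -> pd.DataFrame:
    """The Q decomposition as a tidy table (one row per design plus totals)."""
    dec = q_decompose(net)
    rows = [
        {
            "component": "heterogeneity",
            "design": ":".join(d.design_id),
            "q": dec.q_het_by_design[d.design_id],
            "df": d.df_het,
        }
        for d in net.designs
    ]
    rows.append(
        {"component": "inconsistency", "design": "*", "q": dec.q_inc,
         "df": net.n - net.c - sum(d.df_het for d in net.designs)}
    )
    rows.append(
        {"component": "network", "design": "*", "q": dec.q_net, "df": net.n - net.c}
    )
    return pd.DataFrame(rows)
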