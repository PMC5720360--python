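"""Independent brute-force oracles for univariate random-effects meta-analysis.

These are deliberately written from the classical textbook formulas with no
shared code paths with the package: weighted means, grid scans and closed
forms only.
"""

import numpy as np
from scipy.stats import chi2


def uni_q(y, v, tau_sq):
    """Q(tau^2) = sum w_i (y_i - ybar_w)^2 with total-precision weights."""
    y = np.asarray(y, float)
    w = 1.0 / (np.asarray(v, float) + tau_sq)
    ybar = np.sum(w * y) / np.sum(w)
    return float(np.sum(w * (y - ybar) ** 2))


def _grid_crossing(y, v, target, hi=10.0, step=1e-4):
    """First tau^2 at which the decreasing Q(tau^2) reaches ``target``:
    brute-force scan plus linear interpolation inside the bracketing step."""
    y = np.asarray(y, float)[:, None]
    v = np.asarray(v, float)[:, None]
    t = np.arange(0.0, hi + step, step)[None, :]
    w = 1.0 / (v + t)
    ybar = np.sum(w * y, axis=0) / np.sum(w, axis=0)
    q = np.sum(w * (y - ybar) ** 2, axis=0)
    if q[0] <= target:
        return 0.0
    below = np.nonzero(q <= target)[0]
    if below.size == 0:
        raise ValueError("crossing beyond scan range")
    j = below[0]
    t0, t1, q0, q1 = t[0, j - 1], t[0, j], q[j - 1], q[j]
    return float(t0 + (q0 - target) * (t1 - t0) / (q0 - q1))


def uni_pm(y, v):
    """Paule-Mandel estimate: Q(tau^2) = k - 1, solved by grid scan."""
    return _grid_crossing(y, v, len(y) - 1)


def uni_dl(y, v):
    """Classical DerSimonian-Laird closed form."""
    y = np.asarray(y, float)
    w = 1.0 / np.asarray(v, float)
    ybar = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - ybar) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return float(max(0.0, (q - (len(y) - 1)) / denom))


def uni_q_profile(y, v, level=0.95):
    """Classical Q-profile interval: invert Q(tau^2) at chi-square quantiles."""
    df = len(y) - 1
    alpha = 1 - level
    lower = _grid_crossing(y, v, chi2.ppf(1 - alpha / 2, df))
    if uni_q(y, v, 0.0) <= chi2.ppf(alpha / 2, df):
        return 0.0, 0.0
    upper = _grid_crossing(y, v, chi2.ppf(alpha / 2, df))
    return lower, upper


def uni_restricted_loglik(y, v, tau_sq):
    """Closed-form restricted log-likelihood (constants dropped)."""
    y = np.asarray(y, float)
    w = 1.0 / (np.asarray(v, float) + tau_sq)
    ybar = np.sum(w * y) / np.sum(w)
    return float(
        -0.5 * (np.sum(np.log(1.0 / w)) + np.log(np.sum(w)) + np.sum(w * (y - ybar) ** 2))
    )
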