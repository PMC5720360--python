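"""Data generation from the stacked model and the Monte-Carlo harness.

``simulate_dataset`` draws outcome vectors directly from the model: per
study a heterogeneity effect with covariance tau_beta^2 P, per design an
inconsistency effect with covariance tau_omega^2 P shared by all studies of
the design, and a within-study error with the fixed covariance S.  The
within-study covariance is held at its layout value across replicates, so
the generating model is exactly the model being fitted.

``synthetic_layout`` builds network layouts that emulate a realistic
cognitive-enhancer evidence base: many two-arm trials, a few three- and
four-arm trials, most comparisons anchored on a common control, and highly
variable within-study variances.  Per-arm variances are drawn from a
log-normal calibrated so the implied two-arm contrast variances have mean
0.53 and median 0.29 (heavy right skew, as seen in real mini-mental-state
data); multi-arm covariances follow the shared-baseline-arm rule.

``run_grid`` fits every requested estimator to every replicate over a grid
of true (tau_beta^2, tau_omega^2) values and summarizes estimator means and
spreads, coverage of the nominal Wald intervals for the basic parameters
(pooled across parameters), and correlations between the methods' estimates.
Replicate streams are indexed by (seed, grid point, replicate) so all
methods see identical data and the cross-method correlations are meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import (
    ContrastBlock,
    NetworkMatrices,
    assemble_network,
    p_matrix,
    treatment_labels,
)
from .estimators import estimate
from .exceptions import ConvergenceError, InvalidDataError, NumericalError
from .gls import gls_fit, total_covariance

__all__ = [
    "ARM_VARIANCE_LOGNORMAL",
    "DEFAULT_GRID",
    "SimulationConfig",
    "SimulatedDataset",
    "SimulationSummary",
    "simulate_dataset",
    "synthetic_layout",
    "run_grid",
]

# Log-normal parameters for per-arm variances, calibrated so that the sum of
# two independent draws (a two-arm contrast variance) has mean 0.53 and
# median 0.29.
ARM_VARIANCE_LOGNORMAL = (-2.2699, 1.3725)  # (mu, sigma) on the log scale

# heterogeneity grid crossed with inconsistency grid: 15 settings
DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (tb, tw) for tb in (0.0, 0.25, 0.5, 0.75, 1.0) for tw in (0.0, 0.25, 0.5)
)

DEFAULT_DESIGN_MIX: dict[int, int] = {2: 37, 3: 3, 4: 1}


@dataclass(frozen=True, eq=False)
class SimulationConfig:
    layout: NetworkMatrices
    delta: np.ndarray | None = None
    grid: tuple[tuple[float, float], ...] = DEFAULT_GRID
    reps: int = 1000
    seed: int = 0
    nominal_level: float = 0.95
    methods: tuple[str, ...] = ("pm", "dl", "reml")

    def __post_init__(self):
        if self.reps < 1:
            raise InvalidDataError("reps must be >= 1")
        if any(tb < 0 or tw < 0 for tb, tw in self.grid):
            raise InvalidDataError("grid variances must be nonnegative")
        delta = self.delta
        if delta is None:
            delta = np.zeros(self.layout.c)
        delta = np.asarray(delta, dtype=float)
        if delta.shape != (self.layout.c,):
            raise InvalidDataError(
                f"delta must have length {self.layout.c} (one per basic parameter)"
            )
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "grid", tuple((float(a), float(b)) for a, b in self.grid))


@dataclass(frozen=True, eq=False)
class SimulatedDataset:
    Y: np.ndarray
    heterogeneity: np.ndarray
    inconsistency: np.ndarray
    error: np.ndarray


@dataclass(frozen=True, eq=False)
class SimulationSummary:
    """Per grid point and method: estimator means/SDs, coverage of nominal
    Wald intervals pooled across basic parameters, cross-method correlation
    triples in the order (PM-DL, PM-REML, DL-REML), and failure counts."""

    table: pd.DataFrame
    estimates: pd.DataFrame | None = field(default=None, repr=False)


def _rng_for(seed: int, grid_point, rep_index: int) -> np.random.Generator:
    tb, tw = grid_point
    key = (int(seed), int(round(tb * 1e6)), int(round(tw * 1e6)), int(rep_index))
    return np.random.default_rng(np.random.SeedSequence(key))


def _chol_psd(M):
    return np.linalg.cholesky(M)


def simulate_dataset(
    config: SimulationConfig, grid_point, rep_index: int
) -> SimulatedDataset:
    """One replicate outcome vector, reproducible from (seed, grid point,
    replicate index).  Latent draws are retained for diagnostics; the
    identity Y = X delta + heterogeneity + inconsistency + error holds
    exactly."""
    tb, tw = float(grid_point[0]), float(grid_point[1])
    net = config.layout
    rng = _rng_for(config.seed, (tb, tw), rep_index)
    n = net.n

    het = np.zeros(n)
    inc = np.zeros(n)
    for d in net.designs:
        L = _chol_psd(p_matrix(d.c_d))
        omega = np.sqrt(tw) * (L @ rng.standard_normal(d.c_d))
        for s in range(d.n_d):
            rows = d.rows[s * d.c_d : (s + 1) * d.c_d]
            het[rows] = np.sqrt(tb) * (L @ rng.standard_normal(d.c_d))
            inc[rows] = omega
    err = _chol_psd(net.S) @ rng.standard_normal(n)
    Y = net.X @ config.delta + het + inc + err
    return SimulatedDataset(Y=Y, heterogeneity=het, inconsistency=inc, error=err)


# ---------------------------------------------------------------------------
# synthetic layouts
# ---------------------------------------------------------------------------


def synthetic_layout(
    n_treatments: int = 9,
    design_mix: dict[int, int] | None = None,
    variance_model: tuple[float, float] = ARM_VARIANCE_LOGNORMAL,
    seed: int = 0,
    anchor_share: float = 0.6,
    max_tries: int = 1000,
) -> NetworkMatrices:
    """Generate a connected network layout (X, S, M1, M2; outcomes zero).

    ``design_mix`` maps arm count to number of studies (default: 37 two-arm,
    3 three-arm and 1 four-arm study on 9 treatments).  Each study includes
    the first treatment (the common control) with probability
    ``anchor_share``, mirroring control-anchored evidence bases.  Per-arm
    variances are log-normal with parameters ``variance_model``; a study's
    contrast covariance has diagonal v_baseline + v_arm and off-diagonal
    v_baseline.  Layouts are redrawn until the treatment graph is connected
    and every treatment appears.
    """
    design_mix = dict(DEFAULT_DESIGN_MIX if design_mix is None else design_mix)
    if any(k < 2 for k in design_mix):
        raise InvalidDataError("designs need at least two arms")
    if max(design_mix) > n_treatments:
        raise InvalidDataError("a design cannot include more treatments than exist")
    labels = treatment_labels(n_treatments)
    mu, sigma = variance_model
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x5A11)))

    arm_counts = [k for k, m in sorted(design_mix.items()) for _ in range(m)]
    for _ in range(max_tries):
        blocks = []
        used = set()
        ok = True
        for i, k in enumerate(arm_counts):
            if rng.random() < anchor_share:
                others = rng.choice(len(labels) - 1, size=k - 1, replace=False) + 1
                design = (labels[0], *(labels[j] for j in others))
            else:
                design = tuple(
                    labels[j] for j in rng.choice(len(labels), size=k, replace=False)
                )
            used.update(design)
            design = tuple(sorted(design))
            v = np.exp(mu + sigma * rng.standard_normal(k))
            S = np.diag(v[1:]) + v[0]
            blocks.append(
                ContrastBlock(
                    study_id=f"s{i + 1:03d}",
                    baseline=design[0],
                    comparators=design[1:],
                    y=np.zeros(k - 1),
                    S=S,
                )
            )
        if used != set(labels):
            ok = False
        if ok:
            try:
                return assemble_network(blocks, reference=labels[0])
            except Exception:
                pass
    raise InvalidDataError(
        "could not generate a connected layout covering all treatments; "
        "check the design mix"
    )


# ---------------------------------------------------------------------------
# the Monte-Carlo grid
# ---------------------------------------------------------------------------

_CORR_PAIRS = (("pm", "dl"), ("pm", "reml"), ("dl", "reml"))


def _corr(x, y):
    mask = np.isfinite(x) & np.isfinite(y)
    if mask.sum() < 2 or np.std(x[mask]) == 0 or np.std(y[mask]) == 0:
        return np.nan
    return float(np.corrcoef(x[mask], y[mask])[0, 1])


def run_grid(config: SimulationConfig, keep_estimates: bool = False) -> SimulationSummary:
    """Fit every method to every replicate at every grid point.

    Replicates where a method fails to converge are excluded from that
    method's summaries and counted as failures; coverage is the fraction of
    (replicate x basic parameter) Wald intervals containing the truth.
    """
    net = config.layout
    z = norm.ppf(0.5 + config.nominal_level / 2)
    methods = tuple(m.lower() for m in config.methods)
    rows = []
    raw = [] if keep_estimates else None

    for tb, tw in config.grid:
        est_tb = {m: np.full(config.reps, np.nan) for m in methods}
        est_tw = {m: np.full(config.reps, np.nan) for m in methods}
        cover = {m: [] for m in methods}
        failures = {m: 0 for m in methods}

        for rep in range(config.reps):
            data = simulate_dataset(config, (tb, tw), rep)
            net_rep = net.with_outcomes(data.Y)
            for m in methods:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = estimate(net_rep, m, "full")
                except (ConvergenceError, NumericalError):
                    failures[m] += 1
                    continue
                est_tb[m][rep] = res.vc.tau_beta_sq
                est_tw[m][rep] = res.vc.tau_omega_sq
                V = total_covariance(net_rep, res.vc)
                gls = gls_fit(data.Y, net.X, V)
                se = np.sqrt(np.diag(gls.cov_delta))
                cover[m].append(
                    np.abs(gls.delta_hat - config.delta) <= z * se
                )
                if raw is not None:
                    raw.append(
                        {
                            "tau_beta_sq": tb,
                            "tau_omega_sq": tw,
                            "rep": rep,
                            "method": m,
                            "tb_hat": res.vc.tau_beta_sq,
                            "tw_hat": res.vc.tau_omega_sq,
                        }
                    )

        row = {"tau_beta_sq": tb, "tau_omega_sq": tw}
        for m in methods:
            ok = np.isfinite(est_tb[m])
            row[f"{m}_mean_tb"] = float(np.mean(est_tb[m][ok])) if ok.any() else np.nan
            row[f"{m}_sd_tb"] = (
                float(np.std(est_tb[m][ok], ddof=1)) if ok.sum() > 1 else np.nan
            )
            row[f"{m}_mean_tw"] = float(np.mean(est_tw[m][ok])) if ok.any() else np.nan
            row[f"{m}_sd_tw"] = (
                float(np.std(est_tw[m][ok], ddof=1)) if ok.sum() > 1 else np.nan
            )
            row[f"{m}_cp"] = (
                float(np.mean(np.concatenate(cover[m]))) if cover[m] else np.nan
            )
            row[f"{m}_failures"] = failures[m]
        for a, b in _CORR_PAIRS:
            if a in methods and b in methods:
                row[f"rho_beta_{a}_{b}"] = _corr(est_tb[a], est_tb[b])
                row[f"rho_omega_{a}_{b}"] = _corr(est_tw[a], est_tw[b])
        rows.append(row)

    return SimulationSummary(
        table=pd.DataFrame(rows),
        estimates=pd.DataFrame(raw) if raw is not None else None,
    )
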