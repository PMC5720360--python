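"""Study-level data structures and assembly of the stacked network model.

A contrast-based network meta-analysis represents each study by a vector of
estimated relative treatment effects against a study-design baseline (a log
odds ratio or a mean difference per non-baseline arm), together with the
within-study covariance matrix implied by the shared baseline arm.  Stacking
all studies yields

    Y ~ N(X delta,  tau_beta^2 M1 + tau_omega^2 M2 + S)

where ``delta`` holds the basic parameters (average effects of each
treatment relative to the network reference), ``S`` is the block-diagonal
within-study covariance, ``M1`` encodes which rows share a study and ``M2``
which rows share a design (the unordered set of treatments compared).  The
two variance components quantify between-study heterogeneity and
design-by-treatment inconsistency respectively.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .exceptions import (
    DegenerateStudyError,
    DisconnectedNetworkError,
    InvalidDataError,
)

__all__ = [
    "BinaryArm",
    "ContinuousArm",
    "ContrastBlock",
    "DesignSubmodel",
    "NetworkMatrices",
    "p_matrix",
    "contrasts_from_binary",
    "contrasts_from_continuous",
    "assemble_network",
    "split_by_design",
    "treatment_labels",
]


# ---------------------------------------------------------------------------
# arm-level records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BinaryArm:
    """One arm of a study with a binary outcome (events out of total)."""

    study: str
    treatment: str
    events: float
    total: float

    def __post_init__(self):
        if self.total < 1:
            raise InvalidDataError(
                f"study {self.study!r} arm {self.treatment!r}: total must be >= 1"
            )
        if not 0 <= self.events <= self.total:
            raise InvalidDataError(
                f"study {self.study!r} arm {self.treatment!r}: "
                f"events must lie in [0, total]"
            )


@dataclass(frozen=True)
class ContinuousArm:
    """One arm of a study with a continuous outcome (mean, sd, sample size)."""

    study: str
    treatment: str
    mean: float
    sd: float
    n: float

    def __post_init__(self):
        if self.sd <= 0:
            raise InvalidDataError(
                f"study {self.study!r} arm {self.treatment!r}: sd must be > 0"
            )
        if self.n < 2:
            raise InvalidDataError(
                f"study {self.study!r} arm {self.treatment!r}: n must be >= 2"
            )


# ---------------------------------------------------------------------------
# contrast-level block for one study
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ContrastBlock:
    """Relative-effect vector and within-study covariance for one study.

    ``y[j]`` estimates the effect of ``comparators[j]`` relative to
    ``baseline``; ``S`` is the within-study covariance whose off-diagonal
    entries come from the shared baseline arm.
    """

    study_id: str
    baseline: str
    comparators: tuple[str, ...]
    y: np.ndarray
    S: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "y", np.atleast_1d(np.asarray(self.y, dtype=float)))
        object.__setattr__(self, "S", np.atleast_2d(np.asarray(self.S, dtype=float)))
        object.__setattr__(self, "comparators", tuple(self.comparators))
        k = len(self.comparators)
        if k < 1:
            raise InvalidDataError(f"study {self.study_id!r}: needs >= 1 comparator")
        if self.baseline in self.comparators:
            raise InvalidDataError(
                f"study {self.study_id!r}: baseline {self.baseline!r} repeated "
                "among comparators"
            )
        if len(set(self.comparators)) != k:
            raise InvalidDataError(f"study {self.study_id!r}: duplicate comparators")
        if self.y.shape != (k,) or self.S.shape != (k, k):
            raise InvalidDataError(
                f"study {self.study_id!r}: y/S shapes inconsistent with "
                f"{k} comparators"
            )
        if not np.allclose(self.S, self.S.T, atol=1e-10):
            raise InvalidDataError(f"study {self.study_id!r}: S is not symmetric")
        if np.linalg.eigvalsh(self.S).min() <= 0:
            raise InvalidDataError(
                f"study {self.study_id!r}: S is not positive definite"
            )

    @property
    def design_id(self) -> tuple[str, ...]:
        """The design: the sorted set of treatments compared in the study."""
        return tuple(sorted((self.baseline, *self.comparators)))

    @property
    def c_d(self) -> int:
        return len(self.comparators)


@dataclass(frozen=True, eq=False)
class DesignSubmodel:
    """The single-design submodel: all studies of one design estimate the
    same design-level mean (the sum of the basic-parameter contrasts and the
    design's inconsistency effect), with heterogeneity covariance
    ``tau_beta^2 * M_d`` where ``M_d = I_{n_d} (x) P_{c_d}``."""

    design_id: tuple[str, ...]
    n_d: int
    c_d: int
    Y_d: np.ndarray
    X_d: np.ndarray
    S_d: np.ndarray
    M_d: np.ndarray
    rows: np.ndarray  # indices into the stacked system
    studies: tuple[str, ...]

    @property
    def df_het(self) -> int:
        """Degrees of freedom for within-design heterogeneity: (n_d - 1) c_d."""
        return (self.n_d - 1) * self.c_d


@dataclass(frozen=True, eq=False)
class NetworkMatrices:
    """The assembled stacked model for the whole network."""

    Y: np.ndarray
    X: np.ndarray
    S: np.ndarray
    M1: np.ndarray
    M2: np.ndarray
    row_map: tuple[tuple[str, tuple[str, ...], tuple[str, str]], ...]
    treatments: tuple[str, ...]
    reference: str
    designs: tuple[DesignSubmodel, ...] = field(default=(), repr=False)

    @property
    def n(self) -> int:
        return len(self.Y)

    @property
    def c(self) -> int:
        return len(self.treatments) - 1

    @property
    def basic_labels(self) -> tuple[str, ...]:
        """Non-reference treatments, in design-matrix column order."""
        return tuple(t for t in self.treatments if t != self.reference)

    def with_outcomes(self, Y: np.ndarray) -> "NetworkMatrices":
        """A copy of the network with a new outcome vector (same layout)."""
        Y = np.asarray(Y, dtype=float)
        if Y.shape != (self.n,):
            raise InvalidDataError(f"outcome vector must have length {self.n}")
        designs = tuple(
            replace(d, Y_d=Y[d.rows]) for d in self.designs
        )
        return replace(self, Y=Y, designs=designs)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def p_matrix(k: int) -> np.ndarray:
    """The k x k correlation-pattern matrix with ones on the diagonal and
    halves off it: P_k = (I + J)/2.  Positive definite for all k >= 1."""
    if k < 1 or int(k) != k:
        raise InvalidDataError(f"p_matrix requires integer k >= 1, got {k!r}")
    k = int(k)
    return 0.5 * (np.eye(k) + np.ones((k, k)))


def treatment_labels(count: int) -> tuple[str, ...]:
    """Deterministic treatment labels A, B, C, ... (T27, T28, ... beyond Z)."""
    letters = string.ascii_uppercase
    if count <= len(letters):
        return tuple(letters[:count])
    return tuple(letters) + tuple(f"T{i}" for i in range(27, count + 1))


def _check_one_study(arms, kind):
    if len(arms) < 2:
        raise InvalidDataError("a study needs at least 2 arms")
    studies = {a.study for a in arms}
    if len(studies) != 1:
        raise InvalidDataError(f"arms from multiple studies passed: {sorted(studies)}")
    treatments = [a.treatment for a in arms]
    if len(set(treatments)) != len(treatments):
        raise InvalidDataError(
            f"study {arms[0].study!r}: duplicate treatment arms {sorted(treatments)}"
        )


def _resolve_baseline(arms, baseline):
    treatments = sorted(a.treatment for a in arms)
    if baseline is None:
        return treatments[0]
    if baseline not in treatments:
        raise InvalidDataError(
            f"baseline {baseline!r} not among study treatments {treatments}"
        )
    return baseline


def _block_from_arm_variances(study, baseline, arms, effect, variance):
    """Shared baseline-arm construction: diag = v_b + v_j, off-diag = v_b."""
    by_t = {a.treatment: a for a in arms}
    comparators = tuple(sorted(t for t in by_t if t != baseline))
    v_b = variance(by_t[baseline])
    e_b = effect(by_t[baseline])
    y = np.array([effect(by_t[t]) - e_b for t in comparators])
    v = np.array([variance(by_t[t]) for t in comparators])
    S = np.diag(v) + v_b
    return ContrastBlock(study, baseline, comparators, y, S)


def contrasts_from_binary(arms: list[BinaryArm], baseline: str | None = None) -> ContrastBlock:
    """Log-odds-ratio contrasts for one study with a binary outcome.

    The variance of each arm's log odds is 1/events + 1/(total - events);
    the contrast variance sums both arms' contributions and multi-arm
    contrasts covary through the baseline arm's contribution.  If any cell
    of the study's 2 x arms table is zero, 0.5 is added to every cell of
    every arm (events + 0.5, total + 1) before taking logs.
    """
    _check_one_study(arms, "binary")
    baseline = _resolve_baseline(arms, baseline)
    correct = any(a.events == 0 or a.events == a.total for a in arms)
    if correct:
        arms = [
            BinaryArm(a.study, a.treatment, a.events + 0.5, a.total + 1.0)
            for a in arms
        ]
    for a in arms:
        if a.events <= 0 or a.total - a.events <= 0:
            raise DegenerateStudyError(
                f"study {a.study!r} arm {a.treatment!r} has an empty cell even "
                "after continuity correction"
            )

    def effect(a):
        return np.log(a.events / (a.total - a.events))

    def variance(a):
        return 1.0 / a.events + 1.0 / (a.total - a.events)

    return _block_from_arm_variances(arms[0].study, baseline, arms, effect, variance)


def contrasts_from_continuous(arms: list[ContinuousArm], baseline: str | None = None) -> ContrastBlock:
    """Mean-difference contrasts for one study with a continuous outcome.

    Arm variances are sd^2 / n with no pooled-variance assumption; a two-arm
    contrast has variance s1^2/N1 + s2^2/N2 and multi-arm contrasts covary
    through the baseline arm's sd_b^2 / N_b.
    """
    _check_one_study(arms, "continuous")
    baseline = _resolve_baseline(arms, baseline)
    return _block_from_arm_variances(
        arms[0].study,
        baseline,
        arms,
        effect=lambda a: a.mean,
        variance=lambda a: a.sd**2 / a.n,
    )


# ---------------------------------------------------------------------------
# network assembly
# ---------------------------------------------------------------------------


def rebase_block(block: ContrastBlock, new_baseline: str) -> ContrastBlock:
    """Re-express a study's contrasts against a different baseline arm.

    The transform is exact: new contrasts are linear combinations of the old
    ones, so ``y`` and ``S`` map through the corresponding matrix.
    """
    design = block.design_id
    if new_baseline not in design:
        raise InvalidDataError(
            f"study {block.study_id!r}: {new_baseline!r} is not in the design"
        )
    if new_baseline == block.baseline:
        order = tuple(sorted(block.comparators))
        idx = [block.comparators.index(t) for t in order]
        return ContrastBlock(
            block.study_id, block.baseline, order,
            block.y[idx], block.S[np.ix_(idx, idx)],
        )
    new_comparators = tuple(t for t in design if t != new_baseline)
    # coefficient of treatment t in the old contrast basis
    def coef(t):
        v = np.zeros(block.c_d)
        if t != block.baseline:
            v[block.comparators.index(t)] = 1.0
        return v

    T = np.array([coef(t) - coef(new_baseline) for t in new_comparators])
    return ContrastBlock(
        block.study_id, new_baseline, new_comparators, T @ block.y, T @ block.S @ T.T
    )


def assemble_network(blocks: list[ContrastBlock], reference: str | None = None) -> NetworkMatrices:
    """Stack per-study contrast blocks into the full network model.

    Rows are grouped by design (sorted by the design's treatment set), then
    by study id, with comparators sorted within each study; each design uses
    its lexicographically smallest treatment as baseline.  The design matrix
    encodes each contrast as a signed difference of basic-parameter
    indicators so that designs not containing the reference yield rows like
    ``delta_AD - delta_AC``.
    """
    if not blocks:
        raise InvalidDataError("no studies supplied")
    seen = {}
    for b in blocks:
        if b.study_id in seen:
            raise InvalidDataError(f"duplicate study id {b.study_id!r}")
        seen[b.study_id] = b

    treatments = tuple(sorted({t for b in blocks for t in b.design_id}))
    if reference is None:
        reference = treatments[0]
    if reference not in treatments:
        raise InvalidDataError(f"reference {reference!r} does not appear in the network")

    graph = nx.Graph()
    graph.add_nodes_from(treatments)
    for b in blocks:
        graph.add_edges_from(itertools.combinations(b.design_id, 2))
    if not nx.is_connected(graph):
        raise DisconnectedNetworkError(nx.connected_components(graph))

    # canonical baseline (smallest treatment in the design), sorted comparators
    blocks = [rebase_block(b, min(b.design_id)) for b in blocks]
    blocks.sort(key=lambda b: (b.design_id, b.study_id))

    basic = tuple(t for t in treatments if t != reference)
    col = {t: i for i, t in enumerate(basic)}
    c = len(basic)

    rows_x, row_map, y_parts, s_blocks = [], [], [], []
    for b in blocks:
        for t in b.comparators:
            x = np.zeros(c)
            if t != reference:
                x[col[t]] += 1.0
            if b.baseline != reference:
                x[col[b.baseline]] -= 1.0
            rows_x.append(x)
            row_map.append((b.study_id, b.design_id, (b.baseline, t)))
        y_parts.append(b.y)
        s_blocks.append(b.S)

    X = np.array(rows_x)
    Y = np.concatenate(y_parts)
    n = len(Y)

    S = np.zeros((n, n))
    pos = 0
    for sb in s_blocks:
        k = sb.shape[0]
        S[pos : pos + k, pos : pos + k] = sb
        pos += k

    studies = np.array([r[0] for r in row_map])
    designs_of = [r[1] for r in row_map]
    comparisons = [r[2] for r in row_map]

    same_study = studies[:, None] == studies[None, :]
    M1 = np.where(same_study, 0.5, 0.0)
    np.fill_diagonal(M1, 1.0)

    same_design = np.array(
        [[designs_of[i] == designs_of[j] for j in range(n)] for i in range(n)]
    )
    same_comp = np.array(
        [[comparisons[i] == comparisons[j] for j in range(n)] for i in range(n)]
    )
    M2 = np.where(same_design & same_comp, 1.0, np.where(same_design, 0.5, 0.0))
    np.fill_diagonal(M2, 1.0)

    if np.linalg.matrix_rank(X) < c:
        raise DisconnectedNetworkError(nx.connected_components(graph))

    design_models = _build_design_submodels(Y, S, row_map)

    return NetworkMatrices(
        Y=Y,
        X=X,
        S=S,
        M1=M1,
        M2=M2,
        row_map=tuple(row_map),
        treatments=treatments,
        reference=reference,
        designs=design_models,
    )


def _build_design_submodels(Y, S, row_map):
    order = []
    rows_by_design = {}
    for i, (_study, design, _comp) in enumerate(row_map):
        if design not in rows_by_design:
            rows_by_design[design] = []
            order.append(design)
        rows_by_design[design].append(i)

    out = []
    for design in order:
        rows = np.array(rows_by_design[design])
        c_d = len(design) - 1
        studies = tuple(dict.fromkeys(row_map[i][0] for i in rows))
        n_d = len(studies)
        X_d = np.tile(np.eye(c_d), (n_d, 1))
        M_d = np.kron(np.eye(n_d), p_matrix(c_d))
        out.append(
            DesignSubmodel(
                design_id=design,
                n_d=n_d,
                c_d=c_d,
                Y_d=Y[rows],
                X_d=X_d,
                S_d=S[np.ix_(rows, rows)],
                M_d=M_d,
                rows=rows,
                studies=studies,
            )
        )
    return tuple(out)


def split_by_design(net: NetworkMatrices) -> tuple[DesignSubmodel, ...]:
    """Single-design submodels of the assembled network."""
    return net.designs
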