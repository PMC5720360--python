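"""Readers and writers for the CSV/JSON file interfaces.

Arm-level schemas (comma separated, header row, UTF-8):

* binary:      ``study,treatment,events,total``
* continuous:  ``study,treatment,mean,sd,n``

Contrast-level long schema: ``study,design,baseline,comparator,estimate``
with a companion covariance file ``study,row,col,value`` (row/col index the
study's comparators in file order, zero-based; only the lower triangle is
required).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    BinaryArm,
    ContinuousArm,
    ContrastBlock,
    NetworkMatrices,
    assemble_network,
    contrasts_from_binary,
    contrasts_from_continuous,
)
from .exceptions import InvalidDataError
from .inference import NMAFit, q_decomposition_table

__all__ = [
    "read_arm_csv",
    "read_contrast_csv",
    "network_from_arms",
    "read_network",
    "write_arm_csv",
    "write_results",
    "dump_matrices",
]

_SCHEMAS = {
    "binary": ("study", "treatment", "events", "total"),
    "continuous": ("study", "treatment", "mean", "sd", "n"),
}


def _load_table(path, kind):
    if kind not in _SCHEMAS:
        raise InvalidDataError(f"unknown input kind {kind!r}")
    try:
        df = pd.read_csv(path, dtype={"study": str, "treatment": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise InvalidDataError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in _SCHEMAS[kind] if c not in df.columns]
    if missing:
        raise InvalidDataError(
            f"{path}: missing columns {missing} for kind {kind!r} "
            f"(expected {list(_SCHEMAS[kind])})"
        )
    return df


def read_arm_csv(path, kind: str = "binary"):
    """Read and validate an arm-level CSV; malformed rows are reported with
    their line number (header is line 1)."""
    df = _load_table(path, kind)
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if kind == "binary":
                records.append(
                    BinaryArm(str(row.study), str(row.treatment),
                              float(row.events), float(row.total))
                )
            else:
                records.append(
                    ContinuousArm(str(row.study), str(row.treatment),
                                  float(row.mean), float(row.sd), float(row.n))
                )
        except (InvalidDataError, TypeError, ValueError) as exc:
            raise InvalidDataError(f"{path}, line {pos}: {exc}") from exc
    return records


def read_contrast_csv(estimates_path, covariance_path):
    """Read contrast-level data: per-study relative effects plus a long-form
    within-study covariance table."""
    est = pd.read_csv(estimates_path, dtype=str)
    need = {"study", "baseline", "comparator", "estimate"}
    if not need.issubset(est.columns):
        raise InvalidDataError(
            f"{estimates_path}: missing columns {sorted(need - set(est.columns))}"
        )
    cov = pd.read_csv(covariance_path, dtype={"study": str})
    need_cov = {"study", "row", "col", "value"}
    if not need_cov.issubset(cov.columns):
        raise InvalidDataError(
            f"{covariance_path}: missing columns {sorted(need_cov - set(cov.columns))}"
        )
    blocks = []
    for study, grp in est.groupby("study", sort=True):
        baselines = grp["baseline"].unique()
        if len(baselines) != 1:
            raise InvalidDataError(f"study {study!r}: multiple baselines listed")
        comparators = tuple(grp["comparator"])
        y = grp["estimate"].astype(float).to_numpy()
        k = len(comparators)
        S = np.zeros((k, k))
        sub = cov[cov["study"] == study]
        if sub.empty:
            raise InvalidDataError(f"study {study!r}: no covariance rows")
        for r in sub.itertuples(index=False):
            i, j = int(r.row), int(r.col)
            if not (0 <= i < k and 0 <= j < k):
                raise InvalidDataError(
                    f"study {study!r}: covariance index ({i},{j}) out of range"
                )
            S[i, j] = S[j, i] = float(r.value)
        blocks.append(ContrastBlock(str(study), str(baselines[0]), comparators, y, S))
    return blocks


def network_from_arms(records, kind: str, reference: str | None = None) -> NetworkMatrices:
    """Group arm records by study, form contrasts and assemble the network."""
    by_study: dict[str, list] = {}
    for rec in records:
        by_study.setdefault(rec.study, []).append(rec)
    make = contrasts_from_binary if kind == "binary" else contrasts_from_continuous
    blocks = [make(arms) for _, arms in sorted(by_study.items())]
    return assemble_network(blocks, reference=reference)


def read_network(path, kind: str, covariance_path=None, reference=None) -> NetworkMatrices:
    """One-call reader: arm-level (binary/continuous) or contrast-level."""
    if kind == "contrast":
        if covariance_path is None:
            raise InvalidDataError("contrast input needs a covariance CSV")
        return assemble_network(read_contrast_csv(path, covariance_path), reference)
    return network_from_arms(read_arm_csv(path, kind), kind, reference)


def write_arm_csv(records, path):
    """Write arm records back to the schema they were read from."""
    if not records:
        raise InvalidDataError("no records to write")
    if isinstance(records[0], BinaryArm):
        cols = _SCHEMAS["binary"]
    else:
        cols = _SCHEMAS["continuous"]
    df = pd.DataFrame([{c: getattr(r, c if c != "study" else "study") for c in cols}
                       for r in records])
    df.to_csv(path, index=False)


def _comparison_label(fit: NMAFit, t1: str, t2: str) -> str:
    ref = fit.reference
    parts = []
    if t2 != ref:
        parts.append(f"d[{ref}{t2}]")
    if t1 != ref:
        parts.append(f"-d[{ref}{t1}]" if parts else f"-d[{ref}{t1}]")
    return " ".join(parts) if parts else "0"


def write_results(fit: NMAFit, out_dir) -> dict[str, Path]:
    """Write a fit to ``variance_components.json``, ``pairwise.csv``,
    ``basic.csv`` and ``qdecomp.csv`` with a deterministic field order.
    JSON carries full float precision; the CSVs are rounded for reading."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vc_path = out / "variance_components.json"
    payload = {
        "method": fit.est.method,
        "model": fit.est.model,
        "reference": fit.reference,
        "level": fit.level,
        "tau_beta_sq": fit.vc.tau_beta_sq,
        "tau_omega_sq": fit.vc.tau_omega_sq,
        "truncated_beta": fit.vc.truncated_beta,
        "truncated_omega": fit.vc.truncated_omega,
        "diagnostics": {
            k: v
            for k, v in fit.est.diagnostics.items()
            if isinstance(v, (int, float, bool, str))
        },
    }
    vc_path.write_text(json.dumps(payload, indent=2, sort_keys=False))

    pw = fit.pairwise.copy()
    pw.insert(
        1,
        "parameters",
        [
            _comparison_label(fit, a, b)
            for a, b in zip(pw["treatment_1"], pw["treatment_2"])
        ],
    )
    pw_path = out / "pairwise.csv"
    pw.round(2).to_csv(pw_path, index=False)

    basic_path = out / "basic.csv"
    fit.basic.round(2).to_csv(basic_path, index=False)

    q_path = out / "qdecomp.csv"
    q_decomposition_table(fit.network).round(6).to_csv(q_path, index=False)
    return {
        "variance_components": vc_path,
        "pairwise": pw_path,
        "basic": basic_path,
        "qdecomp": q_path,
    }


def dump_matrices(net: NetworkMatrices, out_dir) -> None:
    """Export the stacked matrices (Y, X, S, M1, M2, row map) for audit."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "Y.csv", net.Y, delimiter=",")
    np.savetxt(out / "X.csv", net.X, delimiter=",")
    np.savetxt(out / "S.csv", net.S, delimiter=",")
    np.savetxt(out / "M1.csv", net.M1, delimiter=",")
    np.savetxt(out / "M2.csv", net.M2, delimiter=",")
    pd.DataFrame(
        [
            {"study": s, "design": ":".join(d), "baseline": c[0], "comparator": c[1]}
            for s, d, c in net.row_map
        ]
    ).to_csv(out / "row_map.csv", index=False)
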