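"""Readers, writers and evaluation reports.

Canonical on-disk formats are diff-able text: dense TSV for connectivity
and consensus matrices, two-column TSV for partitions (0-based node id,
1-based module label), TSV for purity profiles and JSON for run reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import ICSCResult
from .partition import (
    Modularization,
    PurityProfile,
    ami,
    mcc,
    purity,
)
from .spectral import ConnectivityMatrix

__all__ = [
    "read_config",
    "read_matrix",
    "write_matrix",
    "read_partition",
    "write_partition",
    "write_purity",
    "write_report",
    "read_report",
    "validate_report",
    "EvaluationReport",
    "evaluate",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# run configuration

#: Keys a run-configuration file may set (mirrors the fit CLI options).
CONFIG_KEYS = frozenset(
    {"lmin", "lmax", "restarts", "seed", "cost_tolerance", "max_iterations"}
)


def read_config(path: str | Path) -> dict:
    """Read a YAML run-configuration file; unknown keys are rejected."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ValueError(f"{Path(path).name}: expected a key-value mapping")
    unknown = set(raw) - CONFIG_KEYS
    if unknown:
        raise ValueError(
            f"{Path(path).name}: unknown config keys {sorted(unknown)}"
        )
    return dict(raw)


# ---------------------------------------------------------------------------
# matrices


def write_matrix(W: ConnectivityMatrix | np.ndarray, path: str | Path) -> None:
    """Write a square matrix as dense TSV with 12 significant digits."""
    w = W.weights if isinstance(W, ConnectivityMatrix) else np.asarray(W, float)
    np.savetxt(path, w, delimiter="\t", fmt="%.12g")


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    """Read a dense TSV/CSV connectivity matrix.

    An optional single header row of node ids is accepted.  Validation
    and normalization (symmetry tolerance, negative clipping, diagonal
    zeroing) follow :meth:`ConnectivityMatrix.ingest`; clipped counts are
    logged.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else r"\s+"
    try:
        df = pd.read_csv(path, sep=sep, header=None, dtype=float)
        node_ids = None
    except ValueError:
        df = pd.read_csv(path, sep=sep, header=0)
        node_ids = [str(c) for c in df.columns]
        df = df.astype(float)
    values = df.to_numpy()
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"{path.name}: expected a square table, got {values.shape}"
        )
    if not np.isfinite(values).all():
        bad = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"{path.name}: non-finite entry at row {bad[0]}, col {bad[1]}"
        )
    cm = ConnectivityMatrix.ingest(values, node_ids=node_ids)
    if cm.n_clipped:
        logger.info("%s: clipped %d negative entries", path.name, cm.n_clipped)
    return cm


# ---------------------------------------------------------------------------
# partitions and purity profiles


def write_partition(s: Modularization, path: str | Path) -> None:
    df = pd.DataFrame(
        {"node": np.arange(s.n_nodes), "module": s.labels}
    )
    df.to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> Modularization:
    """Read a two-column partition TSV (``node``, ``module``).

    Node ids must be unique and form 0..n-1; non-contiguous labels are
    accepted and canonicalized to 1..L with the mapping logged.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["node", "module"]:
        raise ValueError(f"{path.name}: expected header 'node\\tmodule'")
    nodes = df["node"].to_numpy()
    if np.unique(nodes).size != nodes.size:
        raise ValueError(f"{path.name}: duplicate node ids")
    if not np.array_equal(np.sort(nodes), np.arange(nodes.size)):
        raise ValueError(f"{path.name}: node ids must be 0..n-1")
    labels = df.sort_values("node")["module"].to_numpy()
    s = Modularization(labels)
    canon = s.canonicalized()
    if not np.array_equal(canon.labels, s.labels):
        pairs = sorted(
            {(int(a), int(b)) for a, b in zip(s.labels, canon.labels)}
        )
        logger.info("%s: canonicalized labels %s", path.name, pairs)
    return canon


def write_purity(profile: PurityProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node": np.arange(profile.node_purity.size),
            "modal_label": profile.modal_labels,
            "purity": profile.node_purity,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# reports

#: Minimal structural schema for run reports (field name -> required type).
REPORT_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "consensus_cost": (int, float),
    "group_n_modules": int,
    "individual_counts": list,
    "n_iterations": int,
    "converged": bool,
    "cost_trace": list,
    "seed": int,
}


def validate_report(report: Mapping) -> None:
    """Check a run report against the published structural schema."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required field {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report field {key!r} has type {type(report[key]).__name__}"
            )


def result_report(result: ICSCResult, config_echo: Mapping | None = None) -> dict:
    """Serializable summary of an ICSC result (derived, never authoritative)."""
    report = {
        "consensus_cost": float(result.cost),
        "group_n_modules": int(result.group_count),
        "individual_counts": [int(c) for c in result.individual_counts],
        "n_iterations": int(result.n_iterations),
        "converged": bool(result.converged),
        "cost_trace": [float(c) for c in result.cost_trace],
        "seed": int(result.seed),
    }
    if result.initial_pairwise_ami is not None:
        report["initial_pairwise_ami"] = float(result.initial_pairwise_ami)
        report["final_pairwise_ami"] = float(result.final_pairwise_ami)
    if config_echo is not None:
        report["config"] = dict(config_echo)
    return report


def write_report(report: Mapping, path: str | Path) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(dict(report), indent=2, sort_keys=True))


def read_report(path: str | Path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvaluationReport:
    """Derived metrics of a run, all recomputable from serialized artifacts."""

    consensus_cost: float
    group_n_modules: int
    individual_count_histogram: dict[int, int]
    n_iterations: int
    group_ami_vs_truth: float | None = None
    group_mcc_vs_truth: float | None = None
    individual_ami_vs_truth: tuple[float, ...] | None = None
    mean_node_purity: float | None = None
    sd_node_purity: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["individual_count_histogram"] = {
            str(k): v for k, v in self.individual_count_histogram.items()
        }
        return d


def evaluate(
    result: ICSCResult,
    truth: Modularization | None = None,
    individual_truths: Sequence[Modularization] | None = None,
) -> EvaluationReport:
    """Score an ICSC result, optionally against planted ground truth.

    Computes the group partition's AMI and MCC against ``truth``,
    per-individual AMIs against ``individual_truths`` and the node-purity
    summary of the individual partitions around the group partition.
    """
    if truth is not None and truth.n_nodes != result.group.n_nodes:
        raise ValueError("truth covers a different node set than the result")
    hist: dict[int, int] = {}
    for c in result.individual_counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    prof = purity(result.group, list(result.individuals))
    kwargs: dict = {
        "consensus_cost": float(result.cost),
        "group_n_modules": int(result.group_count),
        "individual_count_histogram": hist,
        "n_iterations": int(result.n_iterations),
        "mean_node_purity": float(prof.node_purity.mean()),
        "sd_node_purity": float(prof.node_purity.std()),
    }
    if truth is not None:
        kwargs["group_ami_vs_truth"] = ami(result.group, truth)
        kwargs["group_mcc_vs_truth"] = mcc(result.group, truth)
    if individual_truths is not None:
        if len(individual_truths) != result.n_individuals:
            raise ValueError("one truth per individual required")
        kwargs["individual_ami_vs_truth"] = tuple(
            ami(s, t) for s, t in zip(result.individuals, individual_truths)
        )
    return EvaluationReport(**kwargs)
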