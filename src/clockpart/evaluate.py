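"""Accuracy/precision/coverage measures for posterior node-age estimates.

Four per-node, per-replicate measures are computed against the true
timetree: relative error of the posterior mean d = |t_hat - t| / t,
relative HPD width sw = w / t, the root-mean-square error
sqrt(MSE) = sqrt(V + (t_hat - t)^2) with the interval-implied variance
V ~= (w / (2 * 1.96))^2, and a coverage indicator (95% HPD interval
contains the true age; closed intervals, boundary counts as covered).
Aggregation averages over replicates per node first, then over nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mcmc import PosteriorSummary
from .trees import SpeciesTimeTree

__all__ = [
    "NodeMetrics",
    "SchemeReport",
    "node_metrics_from_values",
    "compute_node_metrics",
    "aggregate_report",
]

_Z95 = 2.0 * 1.96  # w / (2 * 1.96) approximates the posterior sd


@dataclass(frozen=True)
class NodeMetrics:
    """The four measures for one node in one replicate."""

    node: int
    replicate: int
    rel_error: float
    rel_hpd_width: float
    sqrt_mse: float
    covered: int

    def __post_init__(self) -> None:
        if min(self.rel_error, self.rel_hpd_width, self.sqrt_mse) < 0:
            raise ValueError("measures must be non-negative")
        if self.covered not in (0, 1):
            raise ValueError("covered must be 0 or 1")


def node_metrics_from_values(
    node: int,
    replicate: int,
    true_age: float,
    mean_age: float,
    hpd_lo: float,
    hpd_hi: float,
) -> NodeMetrics:
    """Measures from raw values (any time unit; the relative measures are
    unit-free, sqrt(MSE) is in the unit of the inputs)."""
    if true_age <= 0:
        raise ValueError("true age must be positive")
    w = hpd_hi - hpd_lo
    if w < 0:
        raise ValueError("HPD interval must have non-negative width")
    return NodeMetrics(
        node=node,
        replicate=replicate,
        rel_error=abs((mean_age - true_age) / true_age),
        rel_hpd_width=w / true_age,
        sqrt_mse=math.sqrt((w / _Z95) ** 2 + (mean_age - true_age) ** 2),
        covered=int(hpd_lo <= true_age <= hpd_hi),
    )


def compute_node_metrics(
    summary: PosteriorSummary,
    truth: SpeciesTimeTree,
    replicate: int = 0,
) -> list[NodeMetrics]:
    """All four measures for every internal node of one replicate."""
    out = []
    for lab in truth.internal_labels:
        if lab not in summary.node_labels:
            raise KeyError(f"node {lab} missing from the posterior summary")
        t = float(truth.ages[truth.node_index(lab)])
        lo, hi = summary.hpd(lab)
        out.append(
            node_metrics_from_values(
                node=lab,
                replicate=replicate,
                true_age=t,
                mean_age=summary.mean_age(lab),
                hpd_lo=lo,
                hpd_hi=hi,
            )
        )
    return out


@dataclass
class SchemeReport:
    """Per-node and overall averages of the four measures."""

    label: str
    per_node: pd.DataFrame       # indexed by node
    overall: dict[str, float]
    n_replicates: int


def metrics_frame(metrics: list[NodeMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "node": [m.node for m in metrics],
            "replicate": [m.replicate for m in metrics],
            "rel_error": [m.rel_error for m in metrics],
            "rel_hpd_width": [m.rel_hpd_width for m in metrics],
            "sqrt_mse": [m.sqrt_mse for m in metrics],
            "covered": [m.covered for m in metrics],
        }
    )


def aggregate_report(
    metrics: list[NodeMetrics] | pd.DataFrame, label: str = ""
) -> SchemeReport:
    """Average replicates-then-nodes; coverage as a percentage.

    The per-node table holds the replicate means per node; the overall
    numbers are unweighted means of the per-node means, so the overall
    average equals the mean of the per-node averages by construction.
    """
    df = metrics if isinstance(metrics, pd.DataFrame) else metrics_frame(metrics)
    if df.empty:
        raise ValueError("no metrics to aggregate")
    per_node = df.groupby("node")[
        ["rel_error", "rel_hpd_width", "sqrt_mse", "covered"]
    ].mean()
    per_node["coverage_pct"] = 100.0 * per_node.pop("covered")
    overall = per_node.mean(axis=0).to_dict()
    n_reps = int(df.groupby("node")["replicate"].nunique().max())
    return SchemeReport(
        label=label, per_node=per_node, overall=overall, n_replicates=n_reps
    )
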