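"""End-to-end pipelines: plain ANP and hybrid DEMATEL-ANP (DANP).

Both pipelines take a decision network plus an (aggregated) judgment set and
produce local, relative and global weights, composed alternative scores and
a ranking.  The plain ANP run uses identity within-cluster blocks — the
network degenerates to a hierarchy — while the DANP run replaces every
declared within-cluster block with the cluster's DEMATEL inner-dependence
matrix, so that feedback among cluster elements redistributes weight before
it is absorbed by the alternatives.  That coupling rule is isolated in
:func:`dematel_coupling` so alternative conventions can be swapped in.

Cluster relative weights (RW) default to the network's declared values
(equal split when absent).  Under ``cluster_weighting="dematel"`` the DANP
run instead derives RW for the criterion clusters by normalizing each
cluster's total-relation mass — the only cluster-level signal available
when influence is elicited within clusters only.

Consistency ratios are computed for every comparison matrix.  By default a
matrix with CR > 0.1 produces a warning and the run continues (consistency
is reported post hoc); under ``strict=True`` the run aborts listing the
offending contexts.
"""

from __future__ import annotations

import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .anp_core import (
    CR_THRESHOLD,
    ConsistencyReport,
    Ranking,
    Supermatrix,
    block_normalize,
    build_supermatrix,
    default_cluster_weight_matrix,
    limit_supermatrix,
    priorities_with_consistency,
    rank_alternatives,
    validate_reciprocal,
    weight_supermatrix,
)
from .dematel_core import TotalRelationResult, analyze
from .errors import DanpError, DegenerateInputError, PipelineError, ValidationError
from .network_model import (
    DecisionNetwork,
    JudgmentSet,
    WeightTable,
    aggregate_judgments,
    check_judgments_cover,
)


@dataclass
class PipelineResult:
    method: str  # "ANP" | "DANP"
    consistency: dict[str, ConsistencyReport]
    weight_table: WeightTable
    ranking: Ranking
    supermatrix: Supermatrix
    local_weights: dict[str, np.ndarray]
    dematel: dict[str, TotalRelationResult] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    manifest: dict = field(default_factory=dict)


def _as_single_set(judgments) -> JudgmentSet:
    if isinstance(judgments, JudgmentSet):
        return judgments
    return aggregate_judgments(list(judgments))


def _context_priorities(network: DecisionNetwork, judgments: JudgmentSet):
    """Priorities + consistency for every elicited comparison context."""
    local: dict[str, np.ndarray] = {}
    alt_priorities: dict[str, np.ndarray] = {}
    reports: dict[str, ConsistencyReport] = {}

    for c in network.clusters:
        if len(c.elements) == 1:
            local[c.label] = np.array([1.0])
            continue
        cm = judgments.anp_matrices[c.label]
        report = validate_reciprocal(cm)
        if not report.valid:
            raise ValidationError(
                f"comparison matrix for cluster {c.label!r} is not a valid "
                f"reciprocal matrix: {report}"
            )
        pr, cons = priorities_with_consistency(cm)
        local[c.label] = pr.weights
        reports[c.label] = cons

    n_alt = len(network.alternatives)
    for e in network.subcriteria():
        if n_alt == 1:
            alt_priorities[e] = np.array([1.0])
            continue
        cm = judgments.anp_matrices[e]
        report = validate_reciprocal(cm)
        if not report.valid:
            raise ValidationError(
                f"alternative comparison matrix for {e!r} is not a valid "
                f"reciprocal matrix: {report}"
            )
        pr, cons = priorities_with_consistency(cm)
        alt_priorities[e] = pr.weights
        reports[e] = cons
    return local, alt_priorities, reports


def _gate_consistency(reports, strict: bool, warnings_out: list[str]) -> None:
    bad = [ctx for ctx, r in reports.items() if not r.acceptable]
    if not bad:
        return
    msg = (
        f"consistency ratio above {CR_THRESHOLD} for context(s): "
        + ", ".join(f"{c} (CR={reports[c].CR:.3f})" for c in bad)
    )
    if strict:
        raise PipelineError(msg)
    warnings_out.append(msg)


def dematel_coupling(
    network: DecisionNetwork, judgments: JudgmentSet
) -> tuple[dict[str, TotalRelationResult], dict[str, np.ndarray]]:
    """DEMATEL per cluster -> (analysis results, inner-dependence blocks).

    This is the single place where DEMATEL output parameterizes the ANP
    supermatrix: each cluster's column-normalized total-relation matrix
    becomes the cluster's within-cluster block.
    """
    results: dict[str, TotalRelationResult] = {}
    blocks: dict[str, np.ndarray] = {}
    for c in network.clusters:
        if len(c.elements) == 1:
            blocks[c.label] = np.array([[1.0]])
            continue
        infl = judgments.dematel_matrices[c.label]
        try:
            res = analyze(infl, name=c.label)
        except DanpError as exc:
            raise type(exc)(f"cluster {c.label!r}: {exc}") from exc
        results[c.label] = res
        blocks[c.label] = res.inner_dependence
    return results, blocks


def dematel_cluster_weights(
    network: DecisionNetwork, dematel: dict[str, TotalRelationResult]
) -> dict[str, float]:
    """RW per criterion cluster from normalized total-relation mass."""
    crit = network.criterion_clusters()
    masses = {}
    for c in crit:
        if c.label not in dematel:
            raise PipelineError(
                f"no DEMATEL result for cluster {c.label!r}: cannot derive "
                "cluster weights"
            )
        masses[c.label] = float(dematel[c.label].S.sum())
    total = sum(masses.values())
    if total <= 0:
        raise DegenerateInputError("zero total-relation mass across clusters")
    return {k: v / total for k, v in masses.items()}


def _manifest(network, method, options) -> dict:
    return {
        "method": method,
        "options": options,
        "goal": network.goal_label,
        "clusters": {c.label: list(c.elements) for c in network.clusters},
        "alternatives": list(network.alternatives),
        "versions": {
            "danp_select": _pkg_version,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }


def _run(
    network: DecisionNetwork,
    judgments,
    method: str,
    strict: bool,
    block_norm: str,
    cluster_weighting: str,
) -> PipelineResult:
    js = _as_single_set(judgments)
    check_judgments_cover(network, js, method)
    warnings_out: list[str] = []

    local, alt_priorities, reports = _context_priorities(network, js)
    _gate_consistency(reports, strict, warnings_out)

    dematel: dict[str, TotalRelationResult] = {}
    inner_blocks: dict[str, np.ndarray] | None = None
    net = network
    if method == "DANP":
        dematel, inner_blocks = dematel_coupling(network, js)
        if cluster_weighting == "dematel":
            rw = dematel_cluster_weights(network, dematel)
            net = DecisionNetwork(
                goal_label=network.goal_label,
                clusters=network.clusters,
                alternatives=list(network.alternatives),
                blocks=list(network.blocks),
                cluster_weights=rw,
            )

    sm = build_supermatrix(net, alt_priorities, inner_blocks)
    cwm = default_cluster_weight_matrix(net, sm)
    weight_supermatrix(sm, cwm, net)
    sm.limit, sm.limit_method = limit_supermatrix(sm.weighted)
    table = block_normalize(sm, net, local, mode=block_norm)
    ranking = rank_alternatives(table)

    options = {
        "strict": strict,
        "block_norm": block_norm,
        "cluster_weighting": cluster_weighting,
        "limit_method": sm.limit_method,
    }
    return PipelineResult(
        method=method,
        consistency=reports,
        weight_table=table,
        ranking=ranking,
        supermatrix=sm,
        local_weights=local,
        dematel=dematel,
        warnings=warnings_out,
        manifest=_manifest(net, method, options),
    )


def run_anp(
    network: DecisionNetwork,
    judgments,
    strict: bool = False,
    block_norm: str = "unit",
) -> PipelineResult:
    """Plain ANP: eigenvector priorities, hierarchy supermatrix, ranking."""
    return _run(network, judgments, "ANP", strict, block_norm, "fixed")


def run_danp(
    network: DecisionNetwork,
    judgments,
    strict: bool = False,
    block_norm: str = "unit",
    cluster_weighting: str = "fixed",
) -> PipelineResult:
    """Hybrid DEMATEL-ANP: inner-dependence blocks from DEMATEL.

    ``cluster_weighting="fixed"`` (default) keeps the network's declared RW;
    ``"dematel"`` derives RW from total-relation mass per cluster.
    """
    if cluster_weighting not in ("fixed", "dematel"):
        raise PipelineError(f"unknown cluster weighting {cluster_weighting!r}")
    return _run(network, judgments, "DANP", strict, block_norm, cluster_weighting)
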