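"""Robustness and agility comparison harness.

Two families of checks compare decision methods on the same model:

* *Adequacy to change*: clone an existing alternative (or sub-criterion)
  into the model — the clone copies every judgment of its target, with a
  mutual importance of 1 — rerun the method, and measure whether the
  relative order of the original items survived (rank-reversal testing).

* *Agility*: count the pairwise judgments a method demands from the
  decision makers.  A judgment is an ordered off-diagonal matrix entry —
  both a_ij and a_ji are counted, for comparison and influence matrices
  alike; this is the convention under which the standard elicitation
  worksheets are filled cell by cell.

The elicited matrices are: one within-cluster comparison matrix per cluster,
one alternative-comparison matrix per sub-criterion, and (for the hybrid
method) one influence matrix per cluster.  Incremental counts follow the
published accounting convention in which adding a sub-criterion charges
only its new alternative-comparison matrix under plain ANP (within-cluster
additions excluded), while the hybrid additionally charges the enlarged
influence matrix; the internally consistent count that also charges the
enlarged within-cluster comparison matrix is available under
``include_within_cluster=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DanpError, SchemaError
from .network_model import (
    Cluster,
    ComparisonMatrix,
    DecisionNetwork,
    InfluenceMatrix,
    JudgmentSet,
)

# ---------------------------------------------------------------------------
# Change scenarios
# ---------------------------------------------------------------------------


@dataclass
class ChangeScenario:
    base_network: DecisionNetwork
    base_judgments: JudgmentSet
    change: dict  # {"kind": ..., "clone_of": ..., ["cluster": ...], "new_label": ...}
    network: DecisionNetwork
    judgments: JudgmentSet


def _insert_comparison_clone(cm: ComparisonMatrix, target: str,
                             new_label: str) -> ComparisonMatrix:
    """Append a row/column copying ``target``'s comparisons; mutual = 1."""
    idx = cm.labels.index(target)
    A = cm.values
    n = A.shape[0]
    B = np.empty((n + 1, n + 1))
    B[:n, :n] = A
    B[n, :n] = A[idx, :]
    B[:n, n] = A[:, idx]
    B[n, idx] = 1.0
    B[idx, n] = 1.0
    B[n, n] = 1.0
    return ComparisonMatrix(cm.labels + [new_label], B, cm.context)


def _insert_influence_clone(im: InfluenceMatrix, target: str,
                            new_label: str) -> InfluenceMatrix:
    idx = im.labels.index(target)
    A = im.values
    n = A.shape[0]
    B = np.empty((n + 1, n + 1))
    B[:n, :n] = A
    B[n, :n] = A[idx, :]
    B[:n, n] = A[:, idx]
    B[n, idx] = A[idx, idx]
    B[idx, n] = A[idx, idx]
    B[n, n] = 0.0
    return InfluenceMatrix(im.labels + [new_label], B)


def add_duplicate_alternative(
    network: DecisionNetwork,
    judgments: JudgmentSet,
    clone_of: str,
    new_label: str | None = None,
) -> ChangeScenario:
    """Insert an alternative rated identically to ``clone_of`` everywhere."""
    if clone_of not in network.alternatives:
        raise SchemaError(f"unknown alternative {clone_of!r}")
    new_label = new_label or f"{clone_of}_clone"
    if new_label in network.node_order():
        raise SchemaError(f"label {new_label!r} already in use")
    net = DecisionNetwork(
        goal_label=network.goal_label,
        clusters=[Cluster(c.label, c.kind, list(c.elements)) for c in network.clusters],
        alternatives=list(network.alternatives) + [new_label],
        blocks=list(network.blocks),
        cluster_weights=dict(network.cluster_weights)
        if network.cluster_weights
        else None,
    )
    js = judgments.copy()
    elements = set(network.elements())
    for ctx, cm in list(js.anp_matrices.items()):
        if ctx in elements and set(cm.labels) == set(network.alternatives):
            js.anp_matrices[ctx] = _insert_comparison_clone(cm, clone_of, new_label)
    if len(network.alternatives) == 1:
        # a single alternative needed no comparison matrices; the clone is
        # rated equal to its target, so every context becomes an all-ones 2x2
        for e in network.subcriteria():
            js.anp_matrices[e] = ComparisonMatrix(
                net.alternatives[:], np.ones((2, 2)), context=e
            )
    change = {"kind": "add_alternative", "clone_of": clone_of, "new_label": new_label}
    return ChangeScenario(network, judgments, change, net, js)


def add_duplicate_subcriterion(
    network: DecisionNetwork,
    judgments: JudgmentSet,
    cluster: str,
    clone_of: str,
    new_label: str | None = None,
) -> ChangeScenario:
    """Insert into ``cluster`` a sub-criterion weighted like ``clone_of``.

    The cluster's comparison and influence matrices gain a duplicated
    row/column, and a new alternative-comparison matrix copies the clone
    target's.
    """
    try:
        cl = network.cluster(cluster)
    except KeyError:
        raise SchemaError(f"unknown cluster {cluster!r}") from None
    if clone_of not in cl.elements:
        raise SchemaError(f"{clone_of!r} is not an element of cluster {cluster!r}")
    new_label = new_label or f"{clone_of}_clone"
    if new_label in network.node_order():
        raise SchemaError(f"label {new_label!r} already in use")
    net = DecisionNetwork(
        goal_label=network.goal_label,
        clusters=[
            Cluster(
                c.label,
                c.kind,
                list(c.elements) + ([new_label] if c.label == cluster else []),
            )
            for c in network.clusters
        ],
        alternatives=list(network.alternatives),
        blocks=list(network.blocks),
        cluster_weights=dict(network.cluster_weights)
        if network.cluster_weights
        else None,
    )
    js = judgments.copy()
    if cluster in js.anp_matrices:
        js.anp_matrices[cluster] = _insert_comparison_clone(
            js.anp_matrices[cluster], clone_of, new_label
        )
    if cluster in js.dematel_matrices:
        js.dematel_matrices[cluster] = _insert_influence_clone(
            js.dematel_matrices[cluster], clone_of, new_label
        )
    if clone_of in js.anp_matrices:  # alternative comparisons w.r.t. the target
        src = js.anp_matrices[clone_of]
        js.anp_matrices[new_label] = ComparisonMatrix(
            list(src.labels), src.values.copy(), context=new_label
        )
    change = {
        "kind": "add_subcriterion",
        "cluster": cluster,
        "clone_of": clone_of,
        "new_label": new_label,
    }
    return ChangeScenario(network, judgments, change, net, js)


# ---------------------------------------------------------------------------
# Rank stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    rank_before: list[str]
    rank_after: list[str]
    preserved: bool
    kendall_tau: float
    displacements: dict[str, int]  # positive = moved down (worsened)


def rank_stability(rank_before: list[str], rank_after: list[str]) -> StabilityReport:
    """Stability of the original items' relative order after a change.

    All metrics are computed over the original item set only: items added
    by the change are ignored; every original item must still be present.
    """
    missing = [a for a in rank_before if a not in rank_after]
    if missing:
        raise DanpError(f"items missing from the new ranking: {missing}")
    filtered = [a for a in rank_after if a in set(rank_before)]
    pos_before = {a: i for i, a in enumerate(rank_before)}
    pos_after = {a: i for i, a in enumerate(filtered)}
    displacements = {a: pos_after[a] - pos_before[a] for a in rank_before}
    preserved = filtered == rank_before
    if len(rank_before) > 1:
        tau = stats.kendalltau(
            [pos_before[a] for a in rank_before],
            [pos_after[a] for a in rank_before],
        ).statistic
    else:
        tau = 1.0
    return StabilityReport(
        rank_before=list(rank_before),
        rank_after=list(rank_after),
        preserved=preserved,
        kendall_tau=float(tau),
        displacements=displacements,
    )


# ---------------------------------------------------------------------------
# Agility: judgment counting
# ---------------------------------------------------------------------------


def _ordered_cells(n: int) -> int:
    """Ordered off-diagonal entries of an n x n elicited matrix."""
    return n * (n - 1)


def elicited_matrix_sizes(network: DecisionNetwork, method: str) -> dict[str, int]:
    """Order of every matrix a method elicits, keyed by a descriptive name.

    Used both for direct counting and as the enumeration the brute-force
    oracle in the test suite walks over.
    """
    method = method.upper()
    if method not in ("ANP", "DANP"):
        raise DanpError(f"unknown method {method!r}")
    sizes: dict[str, int] = {}
    for c in network.clusters:
        sizes[f"anp:cluster:{c.label}"] = len(c.elements)
    n_alt = len(network.alternatives)
    if n_alt > 1:
        for e in network.subcriteria():
            sizes[f"anp:alternatives:{e}"] = n_alt
    if method == "DANP":
        for c in network.clusters:
            sizes[f"dematel:cluster:{c.label}"] = len(c.elements)
    return sizes


def count_judgments(network: DecisionNetwork, method: str) -> int:
    """Total ordered pairwise judgments a method asks of the group."""
    return sum(_ordered_cells(n) for n in elicited_matrix_sizes(network, method).values())


@dataclass
class JudgmentDelta:
    total: int
    detail: dict = field(default_factory=dict)


def incremental_judgments(
    network: DecisionNetwork,
    change: dict,
    method: str,
    include_within_cluster: bool = False,
) -> JudgmentDelta:
    """Additional judgments a change demands, under the published accounting.

    ``change`` is the descriptor produced by the scenario builders
    (``{"kind": "add_alternative"}`` or
    ``{"kind": "add_subcriterion", "cluster": ...}``).

    Adding an alternative charges ``2 m`` ordered judgments per
    alternative-comparison matrix (``m`` alternatives before insertion).
    Adding a sub-criterion charges its new alternative-comparison matrix,
    ``m (m - 1)``, for both methods; the hybrid additionally charges the
    ``2 c`` new influence entries of the enlarged cluster (size ``c``
    before insertion).  The enlarged within-cluster comparison matrix
    (another ``2 c``) is excluded by default to match the published
    figures; ``include_within_cluster=True`` switches to the internally
    consistent accounting in which the increment equals the difference of
    the before/after totals.
    """
    method = method.upper()
    if method not in ("ANP", "DANP"):
        raise DanpError(f"unknown method {method!r}")
    kind = change.get("kind")
    m = len(network.alternatives)
    if kind == "add_alternative":
        n_matrices = len(network.subcriteria()) if m + 1 > 1 else 0
        per_matrix = 2 * m
        return JudgmentDelta(
            total=per_matrix * n_matrices,
            detail={
                "per_alternative_matrix": per_matrix,
                "alternative_matrices": n_matrices,
            },
        )
    if kind == "add_subcriterion":
        cl = network.cluster(change["cluster"])
        c = len(cl.elements)
        new_alt_matrix = _ordered_cells(m) if m > 1 else 0
        detail = {"new_alternative_matrix": new_alt_matrix, "cluster_size": c}
        total = new_alt_matrix
        if method == "DANP":
            detail["influence_entries"] = 2 * c
            total += 2 * c
        if include_within_cluster:
            detail["within_cluster_comparisons"] = 2 * c
            total += 2 * c
        return JudgmentDelta(total=total, detail=detail)
    raise DanpError(f"unknown change kind {kind!r}")
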