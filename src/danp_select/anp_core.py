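"""ANP: eigenvector priorities, consistency, and supermatrix machinery.

A pairwise-comparison matrix ``A`` on the Saaty 1-9 scale is positive,
reciprocal (``a_ji = 1/a_ij``) with unit diagonal.  Its principal
eigenvector, normalized to sum 1, gives the local weights of the compared
elements; the principal eigenvalue ``lambda_max`` (= n for a fully
consistent matrix) drives the consistency index

    CI = (lambda_max - n) / (n - 1),        CR = CI / RI(n),

with the random index RI tabulated for 2 <= n <= 10 and CR <= 0.1 deemed
acceptable.

The network stage assembles a partitioned supermatrix over all elements and
alternatives: the column of a node holds the priority vectors of the nodes
that influence it, block by declared block.  Alternatives are modelled as
absorbing sinks (identity block), so that for a plain hierarchy the limit
supermatrix reproduces the classical weighted-sum composition.  Blocks are
scaled by cluster weights to make every non-zero column sum to 1, the
weighted supermatrix is raised to limiting powers (repeated squaring) until
the columns are stationary — with a Cesaro average as the documented
fallback for cyclic structures — and the stationary weights are normalized
by blocks into the final weight table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DanpError,
    DegenerateInputError,
    NonConvergenceError,
    PipelineError,
    ValidationError,
)
from .network_model import (
    ALTERNATIVES,
    ComparisonMatrix,
    DecisionNetwork,
    WeightTable,
)

#: Random index per matrix order (2..10); CR = CI / RI.
RANDOM_INDEX = {2: 0.0, 3: 0.58, 4: 0.9, 5: 1.12, 6: 1.24, 7: 1.32, 8: 1.41,
                9: 1.45, 10: 1.51}

CR_THRESHOLD = 0.1

SAATY_MIN, SAATY_MAX = 1.0 / 9.0, 9.0


def round_half_up(x: float, digits: int = 5) -> float:
    """Round with ties away from zero, the convention of printed tables."""
    factor = 10.0**digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


# ---------------------------------------------------------------------------
# Reciprocal-matrix validation
# ---------------------------------------------------------------------------


@dataclass
class ReciprocityReport:
    n: int
    reciprocity_violations: list[tuple[int, int]]
    diagonal_violations: list[int]
    range_violations: list[tuple[int, int]]

    @property
    def valid(self) -> bool:
        return not (
            self.reciprocity_violations
            or self.diagonal_violations
            or self.range_violations
        )


def validate_reciprocal(matrix: ComparisonMatrix, tol: float = 1e-9) -> ReciprocityReport:
    """Check unit diagonal, reciprocity and Saaty scale range.

    Non-positive entries are a hard error; structural violations are
    reported so that callers can decide whether to warn or abort.
    """
    A = matrix.values
    if np.any(A <= 0):
        i, j = map(int, np.argwhere(A <= 0)[0])
        raise ValidationError(
            f"comparison matrix {matrix.context!r}: non-positive entry at "
            f"({matrix.labels[i]}, {matrix.labels[j]})"
        )
    n = matrix.n
    diag = [i for i in range(n) if abs(A[i, i] - 1.0) > tol]
    recip = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if abs(A[j, i] - 1.0 / A[i, j]) > tol * max(1.0, abs(A[j, i]))
    ]
    rng = [
        (i, j)
        for i in range(n)
        for j in range(n)
        if i != j and not (SAATY_MIN - tol <= A[i, j] <= SAATY_MAX + tol)
    ]
    return ReciprocityReport(n, recip, diag, rng)


# ---------------------------------------------------------------------------
# Priorities and consistency
# ---------------------------------------------------------------------------


@dataclass
class PriorityResult:
    weights: np.ndarray  # sums to 1
    lambda_max: float
    iterations: int


def principal_priorities(
    matrix: ComparisonMatrix | np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> PriorityResult:
    """Principal eigenvector of a positive matrix by power iteration.

    Starts from the uniform vector, renormalizes to sum 1 each step and
    stops when the sup-norm update falls below ``tol``.  ``lambda_max`` is
    the Rayleigh quotient at convergence.  For a positive matrix the
    iteration converges to the Perron vector; the iteration cap is a guard
    only.
    """
    A = matrix.values if isinstance(matrix, ComparisonMatrix) else np.asarray(matrix, float)
    n = A.shape[0]
    if n == 1:
        return PriorityResult(np.array([1.0]), float(A[0, 0]), 0)
    if np.any(A <= 0):
        raise ValidationError("power iteration requires a strictly positive matrix")
    w = np.full(n, 1.0 / n)
    for it in range(1, max_iter + 1):
        y = A @ w
        y_norm = y / y.sum()
        delta = np.abs(y_norm - w).max()
        w = y_norm
        if delta < tol:
            lam = float((A @ w).sum())  # w sums to 1, so sum(A w) = lambda
            return PriorityResult(w, lam, it)
    raise NonConvergenceError(
        f"power iteration did not converge in {max_iter} iterations"
    )


@dataclass
class ConsistencyReport:
    n: int
    lambda_max: float
    CI: float
    RI: float
    CR: float
    acceptable: bool


def consistency(lambda_max: float, n: int, tol: float = 1e-9) -> ConsistencyReport:
    """Consistency index and ratio for an order-``n`` comparison matrix."""
    if n < 2:
        raise ValidationError("consistency is defined for n >= 2")
    if n > max(RANDOM_INDEX):
        raise ValidationError(
            f"no random index tabulated for n = {n} (supported: 2..{max(RANDOM_INDEX)})"
        )
    if lambda_max < n - 1e-9:
        raise ValidationError(
            f"lambda_max = {lambda_max} below n = {n}: not a reciprocal-matrix "
            "principal eigenvalue"
        )
    CI = max(0.0, (lambda_max - n) / (n - 1))
    RI = RANDOM_INDEX[n]
    if RI == 0.0:
        if CI > tol:
            raise ValidationError(
                f"order-{n} reciprocal matrices are consistent by construction "
                f"but CI = {CI}: upstream computation is wrong"
            )
        CR = 0.0
    else:
        CR = CI / RI
    return ConsistencyReport(n, float(lambda_max), CI, RI, CR, CR <= CR_THRESHOLD)


def priorities_with_consistency(
    matrix: ComparisonMatrix,
) -> tuple[PriorityResult, ConsistencyReport]:
    pr = principal_priorities(matrix)
    return pr, consistency(pr.lambda_max, matrix.n)


# ---------------------------------------------------------------------------
# Supermatrix
# ---------------------------------------------------------------------------


@dataclass
class Supermatrix:
    """Partitioned supermatrix over cluster elements plus alternatives."""

    node_order: list[str]
    cluster_slices: dict[str, slice]  # cluster label (incl. "alternatives") -> rows
    raw: np.ndarray
    weighted: np.ndarray | None = None
    limit: np.ndarray | None = None
    limit_method: str | None = None  # "power" | "cesaro"

    def slice_of(self, cluster: str) -> slice:
        return self.cluster_slices[cluster]


def build_supermatrix(
    network: DecisionNetwork,
    priority_tables: dict,
    inner_blocks: dict[str, np.ndarray] | None = None,
) -> Supermatrix:
    """Assemble the raw (unweighted) supermatrix from declared blocks.

    ``priority_tables`` maps a context to a priority vector: the context of
    an ``alternatives -> cluster`` block column is the column element
    itself (its alternative-comparison priorities); a generic outer block
    ``source -> target`` looks up ``(source, element)``.  ``inner_blocks``
    supplies a column-stochastic matrix per cluster for declared
    within-cluster (self) blocks; identity is used when a self block is
    declared but no matrix is supplied, which makes a plain hierarchy.
    Undeclared blocks stay zero; every alternative column carries an
    identity entry (alternatives are absorbing sinks).
    """
    inner_blocks = inner_blocks or {}
    nodes = network.node_order()
    index = {lbl: i for i, lbl in enumerate(nodes)}
    slices: dict[str, slice] = {}
    pos = 0
    for c in network.clusters:
        slices[c.label] = slice(pos, pos + len(c.elements))
        pos += len(c.elements)
    slices[ALTERNATIVES] = slice(pos, pos + len(network.alternatives))

    W = np.zeros((len(nodes), len(nodes)))
    for blk in network.blocks:
        tgt_sl = slices[blk.target]
        src_sl = slices[blk.source]
        if blk.target == ALTERNATIVES:
            continue  # alternative columns are fixed identity sinks
        tgt_elements = network.cluster(blk.target).elements
        for j_local, element in enumerate(tgt_elements):
            col = tgt_sl.start + j_local
            if blk.source == blk.target:
                inner = inner_blocks.get(blk.source)
                vec = (
                    inner[:, j_local]
                    if inner is not None
                    else np.eye(len(tgt_elements))[:, j_local]
                )
            elif blk.source == ALTERNATIVES:
                if element not in priority_tables:
                    raise PipelineError(
                        f"missing alternative priorities for context {element!r}"
                    )
                vec = np.asarray(priority_tables[element], float)
            else:
                key = (blk.source, element)
                if key not in priority_tables:
                    raise PipelineError(
                        f"missing priorities for block {blk.source!r} -> "
                        f"{blk.target!r} at column {element!r}"
                    )
                vec = np.asarray(priority_tables[key], float)
            if vec.shape[0] != src_sl.stop - src_sl.start:
                raise PipelineError(
                    f"priority vector for column {element!r} has length "
                    f"{vec.shape[0]}, expected {src_sl.stop - src_sl.start}"
                )
            W[src_sl, col] = vec
    alt_sl = slices[ALTERNATIVES]
    W[alt_sl, alt_sl] = np.eye(len(network.alternatives))
    return Supermatrix(node_order=nodes, cluster_slices=slices, raw=W)


def default_cluster_weight_matrix(
    network: DecisionNetwork, sm: Supermatrix
) -> pd.DataFrame:
    """Equal split of column weight over the declared source clusters of
    each target cluster (rows: source clusters, columns: target clusters)."""
    labels = [c.label for c in network.clusters] + [ALTERNATIVES]
    C = pd.DataFrame(0.0, index=labels, columns=labels)
    sources: dict[str, list[str]] = {t: [] for t in labels}
    for blk in network.blocks:
        if blk.target != ALTERNATIVES and blk.source not in sources[blk.target]:
            sources[blk.target].append(blk.source)
    sources[ALTERNATIVES] = [ALTERNATIVES]
    for tgt, srcs in sources.items():
        for s in srcs:
            C.loc[s, tgt] = 1.0 / len(srcs)
    return C


def weight_supermatrix(
    sm: Supermatrix,
    cluster_weight_matrix: pd.DataFrame,
    network: DecisionNetwork,
    tol: float = 1e-9,
) -> np.ndarray:
    """Scale each block by its cluster weight so columns sum to 1.

    Each non-zero block column is first normalized to sum 1, then multiplied
    by the (source, target) entry of the cluster weight matrix; the cluster
    weight matrix columns must sum to 1 over the source clusters that have
    declared blocks.  A zero column that is not an alternative sink raises a
    stochasticity error.
    """
    W = sm.raw.copy()
    out = np.zeros_like(W)
    alt_sl = sm.cluster_slices[ALTERNATIVES]
    cluster_labels = [c.label for c in network.clusters] + [ALTERNATIVES]
    for tgt in cluster_labels:
        tgt_sl = sm.cluster_slices[tgt]
        for col in range(tgt_sl.start, tgt_sl.stop):
            colsum = 0.0
            for src in cluster_labels:
                src_sl = sm.cluster_slices[src]
                share = float(cluster_weight_matrix.loc[src, tgt])
                block_col = W[src_sl, col]
                mass = block_col.sum()
                if mass > 0 and share > 0:
                    out[src_sl, col] = block_col / mass * share
                    colsum += share
            if colsum == 0.0:
                if tgt == ALTERNATIVES:
                    out[col, col] = 1.0
                    colsum = 1.0
                else:
                    raise DegenerateInputError(
                        f"column for node {sm.node_order[col]!r} has no incoming "
                        "weight: supermatrix cannot be made column-stochastic"
                    )
            out[:, col] /= colsum  # renormalize if some declared share had no mass
    colsums = out.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > tol):
        bad = int(np.argmax(np.abs(colsums - 1.0)))
        raise DegenerateInputError(
            f"weighted supermatrix column {sm.node_order[bad]!r} sums to "
            f"{colsums[bad]!r}, expected 1"
        )
    sm.weighted = out
    return out


def limit_supermatrix(
    weighted: np.ndarray,
    tol: float = 1e-10,
    max_squarings: int = 60,
) -> tuple[np.ndarray, str]:
    """Raise the weighted supermatrix to limiting powers.

    Repeated squaring until successive powers differ by less than ``tol``
    in max-norm.  If the squared sequence is stationary but one further
    multiplication moves it (a period-2 cycle), the Cesaro average of the
    two alternating limits is returned and flagged.
    """
    P = np.asarray(weighted, dtype=float)
    n = P.shape[0]
    colsums = P.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-8):
        raise DegenerateInputError("limit requires a column-stochastic matrix")
    prev = P
    for _ in range(max_squarings):
        nxt = prev @ prev
        if np.abs(nxt - prev).max() < tol:
            stepped = weighted @ nxt
            if np.abs(stepped - nxt).max() < 10 * max(tol, 1e-12) * n:
                return nxt, "power"
            cesaro = 0.5 * (nxt + stepped)
            if np.abs(weighted @ cesaro - cesaro).max() < 1e-8:
                return cesaro, "cesaro"
            raise NonConvergenceError(
                "supermatrix powers cycle with period > 2; no limit"
            )
        prev = nxt
    raise NonConvergenceError(
        f"limit supermatrix did not stabilize within 2^{max_squarings} powers"
    )


# ---------------------------------------------------------------------------
# Weight assembly
# ---------------------------------------------------------------------------


def global_weights(LW, RW):
    """Global weight: GW_i = LW_i * RW of the element's cluster."""
    return np.asarray(LW, dtype=float) * np.asarray(RW, dtype=float)


def block_normalize(
    sm: Supermatrix,
    network: DecisionNetwork,
    local_weights: dict[str, np.ndarray],
    mode: str = "unit",
) -> WeightTable:
    """Assemble the final weight table from the converged limit supermatrix.

    ``local_weights`` maps each cluster label to its within-cluster priority
    vector (LW).  Global weights of sub-criteria are GW = LW x RW with RW
    the cluster relative weight; each alternative's score composes the limit
    supermatrix's absorption columns with the sub-criterion global weights.

    ``mode="unit"`` rescales every cluster block of the table to sum 1.
    ``mode="paper"`` reproduces the printed-table convention in which each
    criterion cluster's LW column and the alternative block each sum to 0.5
    (exactly the unit-mode values multiplied by 0.5).
    """
    if sm.limit is None:
        raise DanpError("block_normalize requires a converged limit supermatrix")
    if mode not in ("unit", "paper"):
        raise DanpError(f"unknown block normalization mode {mode!r}")
    scale = 1.0 if mode == "unit" else 0.5

    rows = []
    gw_unit: dict[str, float] = {}
    for c in network.clusters:
        lw = np.asarray(local_weights[c.label], dtype=float)
        mass = lw.sum()
        if mass <= 0:
            raise DegenerateInputError(f"zero local-weight mass in cluster {c.label!r}")
        lw = lw / mass
        rw = network.relative_weight(c.label) if c.kind == "criterion" else float("nan")
        blk_scale = scale if c.kind == "criterion" else 1.0
        for e, w in zip(c.elements, lw):
            if c.kind == "criterion":
                gw_unit[e] = w * network.relative_weight(c.label)
            rows.append(
                {
                    "cluster": c.label,
                    "element": e,
                    "LW": w * blk_scale,
                    "RW": rw,
                    "GW": w * blk_scale * rw if c.kind == "criterion" else float("nan"),
                }
            )
    elements_df = pd.DataFrame(rows, columns=["cluster", "element", "LW", "RW", "GW"])

    alt_sl = sm.cluster_slices[ALTERNATIVES]
    node_index = {lbl: i for i, lbl in enumerate(sm.node_order)}
    sub = network.subcriteria()
    if sub:
        gw_vec = np.array([gw_unit[e] for e in sub])
        gw_vec = gw_vec / gw_vec.sum()
        cols = [node_index[e] for e in sub]
        absorption = sm.limit[alt_sl, :][:, cols]  # alt x subcriterion
        scores = absorption @ gw_vec
    else:
        scores = np.full(len(network.alternatives), 1.0 / len(network.alternatives))
    total = scores.sum()
    if total <= 0:
        raise DegenerateInputError("zero alternative score mass in limit supermatrix")
    scores = scores / total * scale
    alternatives_df = pd.DataFrame(
        {"alternative": list(network.alternatives), "score": scores}
    )
    return WeightTable(elements=elements_df, alternatives=alternatives_df, mode=mode)


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------


@dataclass
class Ranking:
    order: list[str]  # best first
    scores: dict[str, float]
    full_tie: bool = False


def rank_alternatives(weights) -> Ranking:
    """Descending ranking; ties keep declaration order (stable sort).

    Accepts a :class:`WeightTable`, a mapping label -> weight, or parallel
    sequences via ``dict(zip(...))`` upstream.
    """
    if isinstance(weights, WeightTable):
        scores = weights.alternative_scores()
    else:
        scores = {str(k): float(v) for k, v in dict(weights).items()}
    if not scores:
        raise DanpError("no alternatives to rank")
    labels = list(scores)
    order = sorted(labels, key=lambda a: (-scores[a], labels.index(a)))
    full_tie = len(set(scores.values())) == 1 and len(labels) > 1
    return Ranking(order=order, scores=scores, full_tie=full_tie)
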