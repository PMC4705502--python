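"""DEMATEL: total-relation analysis of a direct-influence matrix.

Given a direct-relation matrix ``A`` of pairwise influence scores, the
method normalizes it with the constant

    k = min( 1 / max_i sum_j |a_ij| , 1 / max_j sum_i |a_ij| ),   M = k * A,

sums direct and indirect influence into the total-relation matrix

    S = M + M^2 + M^3 + ... = M (I - M)^{-1},

and summarizes each element by its prominence D + R (overall involvement)
and relation D - R (net causal direction), where D is the row sum and R the
column sum of S.  Elements with positive D - R are *dispatchers* (net causes,
prioritized in the decision), elements with negative D - R are *receivers*
(net effects).  A zero relation is classified *neutral*.  Column-normalizing
S yields the inner-dependence matrix used as the within-cluster block of a
hybrid DEMATEL-ANP supermatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, NonConvergenceError
from .network_model import InfluenceMatrix

#: |D - R| at or below this is classified neutral (neither cause nor effect).
ROLE_TOLERANCE = 1e-9

#: Condition number above which the (I - M) solve emits a warning.
CONDITION_WARN = 1e12

DISPATCHER = "dispatcher"
RECEIVER = "receiver"
NEUTRAL = "neutral"


@dataclass
class TotalRelationResult:
    """Full DEMATEL analysis of one influence matrix."""

    labels: list[str]
    k: float
    M: np.ndarray  # normalized direct-relation matrix
    S: np.ndarray  # total-relation matrix
    D: np.ndarray  # row sums of S
    R: np.ndarray  # column sums of S
    prominence: np.ndarray  # D + R
    relation: np.ndarray  # D - R
    role: list[str]
    inner_dependence: np.ndarray  # column-stochastic


def normalize_direct_matrix(influence: InfluenceMatrix) -> tuple[float, np.ndarray]:
    """Normalization constant ``k`` and normalized matrix ``M = k A``.

    ``k`` is the two-term minimum over the largest absolute row sum and the
    largest absolute column sum.
    """
    A = influence.values
    row_max = np.abs(A).sum(axis=1).max()
    col_max = np.abs(A).sum(axis=0).max()
    if row_max == 0 or col_max == 0:
        raise DegenerateInputError(
            "all-zero influence matrix: normalization constant undefined"
        )
    k = min(1.0 / row_max, 1.0 / col_max)
    return k, k * A


def total_relation(M: np.ndarray, name: str = "M") -> np.ndarray:
    """Total-relation matrix ``S = M (I - M)^{-1}``.

    Requires the spectral radius of ``M`` to be strictly below 1 so that the
    influence power series converges.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    rho = np.abs(np.linalg.eigvals(M)).max() if n else 0.0
    if rho >= 1.0 - 1e-12:
        raise NonConvergenceError(
            f"influence series for {name!r} does not converge "
            f"(spectral radius {rho:.6g} >= 1)"
        )
    I_minus_M = np.eye(n) - M
    cond = np.linalg.cond(I_minus_M)
    if cond > CONDITION_WARN:
        warnings.warn(
            f"(I - M) for {name!r} is ill-conditioned (cond={cond:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )
    return np.linalg.solve(I_minus_M.T, M.T).T


def prominence_relation(
    S: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Row sums D, column sums R, prominence D + R and relation D - R."""
    S = np.asarray(S, dtype=float)
    D = S.sum(axis=1)
    R = S.sum(axis=0)
    return D, R, D + R, D - R


def classify_roles(relation: np.ndarray, tol: float = ROLE_TOLERANCE) -> list[str]:
    """Dispatcher (D - R > tol), receiver (D - R < -tol) or neutral."""
    out = []
    for v in np.asarray(relation, dtype=float):
        if v > tol:
            out.append(DISPATCHER)
        elif v < -tol:
            out.append(RECEIVER)
        else:
            out.append(NEUTRAL)
    return out


def inner_dependence(S: np.ndarray, labels: list[str] | None = None) -> np.ndarray:
    """Column-normalize the total-relation matrix (each column sums to 1)."""
    S = np.asarray(S, dtype=float)
    colsums = S.sum(axis=0)
    bad = np.where(colsums <= 0)[0]
    if bad.size:
        which = labels[bad[0]] if labels else f"column {bad[0]}"
        raise DegenerateInputError(
            f"zero column sum in total-relation matrix at {which}"
        )
    return S / colsums


def analyze(influence: InfluenceMatrix, name: str = "") -> TotalRelationResult:
    """Run the full chain on one influence matrix."""
    k, M = normalize_direct_matrix(influence)
    S = total_relation(M, name=name or "M")
    D, R, prom, rel = prominence_relation(S)
    return TotalRelationResult(
        labels=list(influence.labels),
        k=k,
        M=M,
        S=S,
        D=D,
        R=R,
        prominence=prom,
        relation=rel,
        role=classify_roles(rel),
        inner_dependence=inner_dependence(S, influence.labels),
    )


def role_table(result: TotalRelationResult) -> pd.DataFrame:
    """Tidy per-element summary: label, D, R, D+R, D-R, role."""
    return pd.DataFrame(
        {
            "element": result.labels,
            "D": result.D,
            "R": result.R,
            "D_plus_R": result.prominence,
            "D_minus_R": result.relation,
            "role": result.role,
        }
    )
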