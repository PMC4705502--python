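"""Synthetic decision models with known ground truth, plus the embedded
healthcare case-study fixture.

The generator emulates the study conditions of a six-sigma project-selection
exercise in a medical centre: a strategy cluster of 3 elements, four
criterion clusters of sizes 5/4/3/3 (15 sub-criteria), 6 project
alternatives and 6 participants.  Ground truth consists of a positive
priority vector per comparison context and an integer 0-4 influence matrix
per cluster; participants are simulated by perturbing the implied perfectly
consistent judgments — multiplicative log-normal noise on the comparison
ratios (then snapped back to the Saaty scale), additive Gaussian noise on
influence scores (then rounded and clipped to 0..4).  Everything is
deterministic under the seed.

:func:`case_study_fixture` returns the case-study network structure with
the two published elicitation-example matrices embedded, and the module
exposes the published per-cluster summary values (prominence/relation,
local/global weights, alternative weights, consistency ratios) as anchor
data for tests and reproduction scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DanpError
from .network_model import (
    Block,
    Cluster,
    ComparisonMatrix,
    DecisionNetwork,
    InfluenceMatrix,
    JudgmentSet,
)

#: Admissible Saaty-scale values: 1/9 .. 1/2, then 1 .. 9.
SAATY_SCALE = np.array([1.0 / d for d in range(9, 1, -1)] + list(range(1, 10)), float)
_LOG_SCALE = np.log(SAATY_SCALE)


def saaty_snap(x: float) -> float:
    """Nearest admissible scale value, in log space (symmetric in x vs 1/x)."""
    if x <= 0:
        raise DanpError("cannot snap a non-positive ratio to the Saaty scale")
    return float(SAATY_SCALE[np.argmin(np.abs(_LOG_SCALE - np.log(x)))])


def consistent_matrix_from_weights(
    w, labels=None, context: str = "", snap: bool = False
) -> ComparisonMatrix:
    """Fully consistent comparison matrix ``a_ij = w_i / w_j``.

    With ``snap`` each upper-triangle entry is mapped to the nearest
    Saaty-scale value (in log space) and the lower triangle is filled as the
    exact reciprocal, so reciprocity is preserved while entries stay on the
    discrete elicitation scale.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise DanpError("weights must be strictly positive")
    n = w.size
    labels = list(labels) if labels is not None else [f"E{i+1}" for i in range(n)]
    A = np.outer(w, 1.0 / w)
    if snap:
        for i in range(n):
            for j in range(i + 1, n):
                A[i, j] = saaty_snap(A[i, j])
                A[j, i] = 1.0 / A[i, j]
    np.fill_diagonal(A, 1.0)
    return ComparisonMatrix(labels, A, context)


# ---------------------------------------------------------------------------
# Synthesis
# ---------------------------------------------------------------------------


@dataclass
class SynthesisSpec:
    """Study-shaped synthetic model specification.

    Defaults reproduce the case-study conditions: 3 strategies, criterion
    clusters of sizes 5/4/3/3, 6 alternatives, 6 participants.  ``noise_anp``
    is the standard deviation of the log-normal multiplicative perturbation
    on comparison ratios; ``noise_dematel`` the standard deviation of the
    additive perturbation on 0-4 influence scores.  ``separation`` bounds the
    ratio between consecutively ranked true priorities, and ``min_score_gap``
    is the smallest gap (on normalized scores summing to 1) allowed between
    consecutively ranked true alternative scores: snapping judgments to the
    discrete Saaty scale perturbs composed scores by up to roughly 0.01, so
    closer ground-truth ties are not identifiable by any elicitation on that
    scale and are rejected at generation time.

    Alternative merit is correlated across contexts, as in real selection
    problems: one latent quality ordering of the alternatives is drawn, and
    each context perturbs it locally (each adjacent pair swapped with
    probability ``context_discord``) before assigning its separated priority
    magnitudes.
    """

    n_strategies: int = 3
    cluster_sizes: tuple[int, ...] = (5, 4, 3, 3)
    n_alternatives: int = 6
    n_participants: int = 6
    noise_anp: float = 0.1
    noise_dematel: float = 0.5
    snap: bool = True
    separation: tuple[float, float] = (1.3, 1.9)
    min_score_gap: float = 0.02
    context_discord: float = 0.3
    seed: int = 0
    true_priorities: dict | None = None  # context -> weight vector (optional)
    true_influence: dict | None = None  # cluster -> integer matrix (optional)


@dataclass
class SynthesisResult:
    network: DecisionNetwork
    true_local: dict[str, np.ndarray]  # cluster -> LW
    true_alt_priorities: dict[str, np.ndarray]  # sub-criterion -> alt priorities
    true_influence: dict[str, InfluenceMatrix]
    true_scores: dict[str, float]
    true_ranking: list[str]
    judgment_sets: list[JudgmentSet] = field(default_factory=list)
    clip_count: int = 0  # out-of-scale influence draws clipped back


def _spec_network(spec: SynthesisSpec) -> DecisionNetwork:
    clusters = [Cluster("Strategies", "strategy",
                        [f"ST{i+1}" for i in range(spec.n_strategies)])]
    e = 0
    for ci, size in enumerate(spec.cluster_sizes):
        clusters.append(
            Cluster(f"Criteria{ci+1}", "criterion",
                    [f"S{e + i + 1}" for i in range(size)])
        )
        e += size
    alternatives = [f"A{i+1}" for i in range(spec.n_alternatives)]
    blocks = [Block(c.label, c.label) for c in clusters]
    blocks += [Block("alternatives", c.label) for c in clusters if c.kind == "criterion"]
    rw = 1.0 / len(spec.cluster_sizes)
    return DecisionNetwork(
        goal_label="synthetic goal",
        clusters=clusters,
        alternatives=alternatives,
        blocks=blocks,
        cluster_weights={c.label: rw for c in clusters if c.kind == "criterion"},
    )


def _separated_weights(n: int, rng: np.random.Generator,
                       separation: tuple[float, float]) -> np.ndarray:
    """Priority vector whose sorted entries differ by a ratio in ``separation``."""
    ratios = rng.uniform(*separation, size=n - 1) if n > 1 else np.array([])
    w = np.concatenate([[1.0], np.cumprod(ratios)])
    w = w / w.sum()
    return w[rng.permutation(n)]


def _random_influence(n: int, rng: np.random.Generator) -> np.ndarray:
    """Integer 0-4 influence matrix in which every element both exerts and
    receives at least some influence (zero rows/columns would leave the
    inner-dependence block undefined)."""
    if n == 1:
        return np.zeros((1, 1))
    while True:
        A = rng.integers(0, 5, size=(n, n)).astype(float)
        np.fill_diagonal(A, 0.0)
        if np.all(A.sum(axis=0) > 0) and np.all(A.sum(axis=1) > 0):
            return A


def synthesize(spec: SynthesisSpec) -> SynthesisResult:
    """Build the network, the ground truth and the per-participant judgments."""
    rng = np.random.default_rng(spec.seed)
    network = _spec_network(spec)

    true_local: dict[str, np.ndarray] = {}
    true_alt: dict[str, np.ndarray] = {}
    supplied = spec.true_priorities or {}
    for c in network.clusters:
        true_local[c.label] = np.asarray(
            supplied.get(c.label, _separated_weights(len(c.elements), rng,
                                                     spec.separation)),
            float,
        )
    def _draw_alt_priorities() -> dict[str, np.ndarray]:
        n_alt = len(network.alternatives)
        latent = rng.permutation(n_alt)  # latent quality ordering, best first
        out: dict[str, np.ndarray] = {}
        for e in network.subcriteria():
            if e in supplied:
                out[e] = np.asarray(supplied[e], float)
                continue
            order = list(latent)
            for i in range(n_alt - 1):  # local discord between contexts
                if rng.uniform() < spec.context_discord:
                    order[i], order[i + 1] = order[i + 1], order[i]
            ratios = rng.uniform(*spec.separation, size=max(n_alt - 1, 0))
            mags = np.concatenate([[1.0], np.cumprod(1.0 / ratios)])
            w = np.empty(n_alt)
            w[order] = mags  # order[k] is the k-th best alternative
            out[e] = w / w.sum()
        return out

    def _composed_scores(alt: dict[str, np.ndarray]) -> dict[str, float]:
        s = {a: 0.0 for a in network.alternatives}
        for c in network.criterion_clusters():
            rw = network.relative_weight(c.label)
            lw = true_local[c.label] / true_local[c.label].sum()
            for e, w in zip(c.elements, lw):
                for a, p in zip(network.alternatives, alt[e]):
                    s[a] += rw * w * p
        return s

    # enforce ground-truth identifiability: reject draws whose composed true
    # scores tie more closely than the Saaty scale can resolve
    for attempt in range(500):
        true_alt = _draw_alt_priorities()
        scores = _composed_scores(true_alt)
        vals = sorted(scores.values(), reverse=True)
        total = sum(vals)
        gaps = [(a - b) / total for a, b in zip(vals, vals[1:])]
        if not gaps or min(gaps) >= spec.min_score_gap:
            break
        if supplied:  # user-pinned priorities are taken as-is
            break
    else:
        raise DanpError(
            "could not draw alternative priorities with the requested "
            f"min_score_gap={spec.min_score_gap}"
        )
    true_infl: dict[str, InfluenceMatrix] = {}
    supplied_infl = spec.true_influence or {}
    for c in network.clusters:
        A = np.asarray(
            supplied_infl.get(c.label, _random_influence(len(c.elements), rng)),
            float,
        )
        true_infl[c.label] = InfluenceMatrix(list(c.elements), A)

    ranking = sorted(scores, key=lambda a: (-scores[a], network.alternatives.index(a)))

    clip_count = 0
    judgment_sets: list[JudgmentSet] = []
    for p in range(spec.n_participants):
        anp: dict[str, ComparisonMatrix] = {}
        for ctx, w in list(true_local.items()) + list(true_alt.items()):
            labels = (
                network.cluster(ctx).elements
                if ctx in {c.label for c in network.clusters}
                else list(network.alternatives)
            )
            n = w.size
            A = np.outer(w, 1.0 / w)
            if spec.noise_anp > 0:
                for i in range(n):
                    for j in range(i + 1, n):
                        A[i, j] *= float(np.exp(rng.normal(0.0, spec.noise_anp)))
                        A[j, i] = 1.0 / A[i, j]
            if spec.snap:
                for i in range(n):
                    for j in range(i + 1, n):
                        A[i, j] = saaty_snap(A[i, j])
                        A[j, i] = 1.0 / A[i, j]
            np.fill_diagonal(A, 1.0)
            anp[ctx] = ComparisonMatrix(list(labels), A, context=ctx)
        dem: dict[str, InfluenceMatrix] = {}
        for ctx, im in true_infl.items():
            A = im.values.copy()
            if spec.noise_dematel > 0:
                A = A + rng.normal(0.0, spec.noise_dematel, size=A.shape)
            A = np.rint(A)
            clipped = np.clip(A, 0.0, 4.0)
            clip_count += int((clipped != A).sum())
            A = clipped
            np.fill_diagonal(A, 0.0)
            if A.sum() == 0:  # keep the cluster analysable
                A = im.values.copy()
            dem[ctx] = InfluenceMatrix(list(im.labels), A)
        judgment_sets.append(JudgmentSet(f"participant_{p+1}", anp, dem))

    return SynthesisResult(
        network=network,
        true_local=true_local,
        true_alt_priorities=true_alt,
        true_influence=true_infl,
        true_scores=scores,
        true_ranking=ranking,
        judgment_sets=judgment_sets,
        clip_count=clip_count,
    )


def synth_judgment_sets(spec: SynthesisSpec) -> list[JudgmentSet]:
    """Per-participant judgment sets only (see :func:`synthesize`)."""
    return synthesize(spec).judgment_sets


# ---------------------------------------------------------------------------
# Case-study fixture (healthcare six-sigma project selection)
# ---------------------------------------------------------------------------

#: Long names of the 15 sub-criteria, cluster by cluster.
CASE_STUDY_SUBCRITERIA = {
    "Benefit": {
        "S1": "Cash flow",
        "S2": "Quality level",
        "S3": "Efficiency",
        "S4": "User satisfaction",
        "S5": "Reduction of operational cost",
    },
    "Opportunity": {
        "S6": "Operational performance",
        "S7": "Market share increase",
        "S8": "User loyalty",
        "S9": "Employees' performance",
    },
    "Cost": {
        "S10": "Training",
        "S11": "Human resources",
        "S12": "Associated costs",
    },
    "Risk": {
        "S13": "Technical risks",
        "S14": "Delay risk",
        "S15": "Cost overrun",
    },
}

#: Published per-cluster prominence (D+R), relation (D-R) and role of every
#: element in the case study (group-level DEMATEL results).
CASE_STUDY_PROMINENCE = {
    "Strategies": [
        ("OE", 13.222, 0.842, "dispatcher"),
        ("RG", 12.938, -1.424, "receiver"),
        ("HP", 12.926, 0.582, "dispatcher"),
    ],
    "Benefit": [
        ("S1", 12.045, -0.861, "receiver"),
        ("S2", 12.397, -0.375, "receiver"),
        ("S3", 13.764, 0.728, "dispatcher"),
        ("S4", 13.931, 0.165, "dispatcher"),
        ("S5", 12.063, 0.343, "dispatcher"),
    ],
    "Opportunity": [
        ("S6", 10.494, 0.556, "dispatcher"),
        ("S7", 4.852, -2.407, "receiver"),
        ("S8", 9.75, 0.206, "dispatcher"),
        ("S9", 9.639, 1.645, "dispatcher"),
    ],
    "Cost": [
        ("S10", 4.756, 0.89, "dispatcher"),
        ("S11", 2.808, 0.0, "neutral"),
        ("S12", 4.754, -0.89, "receiver"),
    ],
    "Risk": [
        ("S13", 7.297, -0.46, "receiver"),
        ("S14", 7.163, -0.618, "receiver"),
        ("S15", 15.39, 1.078, "dispatcher"),
    ],
}

#: Published case-study sub-criterion weights: cluster -> (RW, {element: (GW, LW)}).
CASE_STUDY_WEIGHTS = {
    "Benefit": (0.25, {
        "S1": (0.02414, 0.09655),
        "S2": (0.02812, 0.11248),
        "S3": (0.02741, 0.10965),
        "S4": (0.02345, 0.09382),
        "S5": (0.02187, 0.0875),
    }),
    "Opportunity": (0.25, {
        "S6": (0.0356, 0.14241),
        "S7": (0.0212, 0.08482),
        "S8": (0.0321, 0.12841),
        "S9": (0.03609, 0.14436),
    }),
    "Cost": (0.25, {
        "S10": (0.0289, 0.11562),
        "S11": (0.05471, 0.21883),
        "S12": (0.04139, 0.16555),
    }),
    "Risk": (0.25, {
        "S13": (0.04029, 0.16116),
        "S14": (0.0396, 0.1584),
        "S15": (0.04511, 0.18044),
    }),
}

#: Published global weights of the six project alternatives.
CASE_STUDY_ALTERNATIVE_WEIGHTS = {
    "C1": 0.05339,
    "C2": 0.0892,
    "C3": 0.09166,
    "C4": 0.1168,
    "C5": 0.0853,
    "C6": 0.06366,
}

#: Published consistency ratios per cluster matrix.
CASE_STUDY_CONSISTENCY = {
    "Strategies": 0.01,
    "Benefit": 0.03,
    "Opportunity": 0.09,
    "Cost": 0.04,
    "Risk": 0.07,
}

#: Published strategy-cluster influence elicitation example (0-4 scale).
CASE_STUDY_INFLUENCE_EXAMPLE = InfluenceMatrix(
    ["OE", "RG", "HP"],
    np.array([[0, 4, 3], [3, 0, 3], [3, 4, 0]], float),
)

#: Published cost-cluster importance elicitation example (Saaty scale).
CASE_STUDY_COMPARISON_EXAMPLE = ComparisonMatrix(
    ["AC", "T", "HR"],
    np.array([[1, 9, 8], [1 / 9, 1, 1 / 9], [1 / 8, 9, 1]], float),
    context="Cost",
)


def case_study_network() -> DecisionNetwork:
    """The case-study decision network: 3 strategies, 15 sub-criteria in
    clusters of sizes 5/4/3/3, 6 project alternatives, equal cluster weights."""
    clusters = [Cluster("Strategies", "strategy", ["OE", "RG", "HP"])]
    for label, members in CASE_STUDY_SUBCRITERIA.items():
        clusters.append(Cluster(label, "criterion", list(members)))
    blocks = [Block(c.label, c.label) for c in clusters]
    blocks += [Block("alternatives", c.label) for c in clusters if c.kind == "criterion"]
    return DecisionNetwork(
        goal_label="Select the most suitable six-sigma project",
        clusters=clusters,
        alternatives=[f"C{i}" for i in range(1, 7)],
        blocks=blocks,
        cluster_weights={lbl: rw for lbl, (rw, _) in CASE_STUDY_WEIGHTS.items()},
    )


def case_study_fixture() -> tuple[DecisionNetwork, dict]:
    """Case-study network plus the two embedded elicitation-example matrices."""
    fragments = {
        "influence_example": CASE_STUDY_INFLUENCE_EXAMPLE.copy(),
        "comparison_example": CASE_STUDY_COMPARISON_EXAMPLE.copy(),
    }
    return case_study_network(), fragments


def case_study_synthesis_spec(seed: int = 0, **overrides) -> SynthesisSpec:
    """A :class:`SynthesisSpec` shaped exactly like the case study."""
    return SynthesisSpec(seed=seed, **overrides)
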