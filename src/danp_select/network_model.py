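"""Decision-network data model, validation, file I/O and group-judgment aggregation.

A decision network consists of a goal, an ordered list of element clusters
(one *strategy* cluster and one or more *criterion* clusters in the typical
model), a list of project alternatives, and a set of declared dependency
blocks that say which cluster's elements receive weight in which other
cluster's supermatrix columns.  Element ordering is authoritative from the
configuration document; matrices are always interpreted in that order.

Judgments come in two flavours:

* pairwise *importance* comparisons on the Saaty 1-9 ratio scale
  (:class:`ComparisonMatrix`), reciprocal by construction, and
* pairwise *influence* scores on a discrete 0-4 scale
  (:class:`InfluenceMatrix`), zero on the diagonal.

Multi-participant judgment sets are merged with
:func:`aggregate_judgments` — element-wise geometric mean for reciprocal
comparison matrices (which preserves reciprocity) and element-wise
arithmetic mean for influence matrices (which keeps the bounded scale
interpretable).  Both schemes are selectable per matrix kind.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import AggregationError, DanpError, SchemaError, ValidationError

#: Reserved pseudo-cluster label used in dependency blocks to refer to the
#: list of project alternatives.
ALTERNATIVES = "alternatives"

SCHEMA_VERSION = 1

_CELL_RE = re.compile(r"^\s*(-?\d+(?:[.,]\d+)?(?:[eE][+-]?\d+)?)\s*(?:/\s*(-?\d+(?:[.,]\d+)?))?\s*$")


def parse_cell(text: str) -> float:
    """Parse one matrix cell: plain number, decimal-comma number or fraction.

    Accepts ``"3"``, ``"0.117"``, ``"0,117"`` and ``"1/9"`` (also with
    decimal-comma operands).  Decimal commas, as printed in many European
    tables, are normalized to decimal points.
    """
    m = _CELL_RE.match(text)
    if not m:
        raise ValidationError(f"cannot parse matrix cell {text!r}")
    num = float(m.group(1).replace(",", "."))
    if m.group(2) is not None:
        den = float(m.group(2).replace(",", "."))
        if den == 0:
            raise ValidationError(f"zero denominator in cell {text!r}")
        return num / den
    return num


# ---------------------------------------------------------------------------
# Matrix containers
# ---------------------------------------------------------------------------


@dataclass
class InfluenceMatrix:
    """Direct-relation (influence) matrix on the 0-4 scale.

    Entries may be real-valued after group aggregation; the diagonal is
    always zero (an element does not influence itself).
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"influence matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if np.any(self.values < 0):
            raise ValidationError("influence scores must be non-negative")
        if np.any(np.abs(np.diag(self.values)) > 1e-12):
            raise ValidationError("influence matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return len(self.labels)

    def copy(self) -> "InfluenceMatrix":
        return InfluenceMatrix(list(self.labels), self.values.copy())


@dataclass
class ComparisonMatrix:
    """Positive reciprocal pairwise-comparison matrix on the Saaty scale.

    ``context`` names the parent element or cluster the comparison is made
    "with respect to".  Structural validation (reciprocity, unit diagonal,
    scale range) is performed by :func:`danp_select.anp_core.validate_reciprocal`;
    this container only checks shape and positivity so that deliberately
    malformed matrices can be constructed for validation tests.
    """

    labels: list[str]
    values: np.ndarray
    context: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"comparison matrix for context {self.context!r} has shape "
                f"{self.values.shape}, expected ({n}, {n})"
            )

    @property
    def n(self) -> int:
        return len(self.labels)

    def copy(self) -> "ComparisonMatrix":
        return ComparisonMatrix(list(self.labels), self.values.copy(), self.context)


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    label: str
    kind: str  # "strategy" | "criterion"
    elements: list[str]

    def __post_init__(self) -> None:
        if self.kind not in ("strategy", "criterion"):
            raise SchemaError(f"cluster {self.label!r}: unknown kind {self.kind!r}")
        if not self.elements:
            raise SchemaError(f"cluster {self.label!r} has no elements")
        if len(set(self.elements)) != len(self.elements):
            dup = [e for e in self.elements if self.elements.count(e) > 1][0]
            raise SchemaError(f"cluster {self.label!r}: duplicate element {dup!r}")


@dataclass(frozen=True)
class Block:
    """Declared dependency: elements of ``source`` receive weight in the
    supermatrix columns of ``target``."""

    source: str
    target: str


@dataclass
class DecisionNetwork:
    goal_label: str
    clusters: list[Cluster]
    alternatives: list[str]
    blocks: list[Block] = field(default_factory=list)
    cluster_weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if not self.clusters:
            raise SchemaError("network needs at least one cluster")
        if not self.alternatives:
            raise SchemaError("network needs at least one alternative")
        seen: set[str] = set()
        for c in self.clusters:
            for e in c.elements:
                if e in seen:
                    raise SchemaError(f"duplicate element label {e!r} across clusters")
                seen.add(e)
        for a in self.alternatives:
            if a in seen:
                raise SchemaError(f"alternative label {a!r} collides with an element")
            seen.add(a)
        labels = {c.label for c in self.clusters} | {ALTERNATIVES}
        if len(labels) != len(self.clusters) + 1:
            raise SchemaError("duplicate cluster labels")
        for b in self.blocks:
            for ref in (b.source, b.target):
                if ref not in labels:
                    raise SchemaError(f"block references unknown cluster {ref!r}")
        if self.cluster_weights is not None:
            for lbl in self.cluster_weights:
                if lbl not in labels - {ALTERNATIVES}:
                    raise SchemaError(f"cluster weight for unknown cluster {lbl!r}")
            crit = [
                self.cluster_weights[c.label]
                for c in self.criterion_clusters()
                if c.label in self.cluster_weights
            ]
            if crit and abs(sum(crit) - 1.0) > 1e-9:
                raise SchemaError(
                    f"criterion cluster weights sum to {sum(crit)!r}, expected 1"
                )

    # -- convenience --------------------------------------------------------

    def cluster(self, label: str) -> Cluster:
        for c in self.clusters:
            if c.label == label:
                return c
        raise KeyError(label)

    def criterion_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.kind == "criterion"]

    def strategy_clusters(self) -> list[Cluster]:
        return [c for c in self.clusters if c.kind == "strategy"]

    def subcriteria(self) -> list[str]:
        """All elements of criterion clusters, in declaration order."""
        return [e for c in self.criterion_clusters() for e in c.elements]

    def elements(self) -> list[str]:
        return [e for c in self.clusters for e in c.elements]

    def node_order(self) -> list[str]:
        """Supermatrix node order: cluster elements then alternatives."""
        return self.elements() + list(self.alternatives)

    def cluster_of(self, element: str) -> str:
        for c in self.clusters:
            if element in c.elements:
                return c.label
        if element in self.alternatives:
            return ALTERNATIVES
        raise KeyError(element)

    def relative_weight(self, cluster_label: str) -> float:
        """RW of a criterion cluster; equal split when no weights declared."""
        if self.cluster_weights and cluster_label in self.cluster_weights:
            return float(self.cluster_weights[cluster_label])
        crit = self.criterion_clusters()
        if not crit:
            return 1.0
        return 1.0 / len(crit)

    def has_block(self, source: str, target: str) -> bool:
        return Block(source, target) in self.blocks

    def to_document(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "goal": self.goal_label,
            "clusters": [
                {"label": c.label, "kind": c.kind, "elements": list(c.elements)}
                for c in self.clusters
            ],
            "alternatives": list(self.alternatives),
            "blocks": [{"source": b.source, "target": b.target} for b in self.blocks],
            "cluster_weights": dict(self.cluster_weights)
            if self.cluster_weights
            else None,
        }


def load_network(source: str | Path | Mapping) -> DecisionNetwork:
    """Load and validate a decision network from a YAML/JSON document.

    ``source`` may be a path to a ``.yaml``/``.yml``/``.json`` file or an
    already-parsed mapping.  Element ordering is preserved exactly as listed.
    """
    if isinstance(source, (str, Path)):
        doc = yaml.safe_load(Path(source).read_text())
    else:
        doc = dict(source)
    if not isinstance(doc, Mapping):
        raise SchemaError("network document must be a mapping")
    try:
        clusters = [
            Cluster(str(c["label"]), str(c.get("kind", "criterion")),
                    [str(e) for e in c["elements"]])
            for c in doc["clusters"]
        ]
        alternatives = [str(a) for a in doc.get("alternatives", [])]
        blocks = [
            Block(str(b["source"]), str(b["target"])) for b in doc.get("blocks", [])
        ]
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed network document: {exc!r}") from exc
    weights = doc.get("cluster_weights")
    if weights is not None:
        weights = {str(k): float(v) for k, v in weights.items()}
    return DecisionNetwork(
        goal_label=str(doc.get("goal", "goal")),
        clusters=clusters,
        alternatives=alternatives,
        blocks=blocks,
        cluster_weights=weights,
    )


def save_network(network: DecisionNetwork, path: str | Path) -> None:
    path = Path(path)
    doc = network.to_document()
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Judgment sets
# ---------------------------------------------------------------------------


@dataclass
class JudgmentSet:
    """All matrices elicited from one participant (or a consolidated group).

    ``anp_matrices`` maps a context label — a cluster label for
    within-cluster importance comparisons, or an element label for
    alternative comparisons with respect to that element — to a
    :class:`ComparisonMatrix`.  ``dematel_matrices`` maps a cluster label to
    that cluster's :class:`InfluenceMatrix`.
    """

    participant_id: str
    anp_matrices: dict[str, ComparisonMatrix] = field(default_factory=dict)
    dematel_matrices: dict[str, InfluenceMatrix] = field(default_factory=dict)

    def copy(self) -> "JudgmentSet":
        return JudgmentSet(
            self.participant_id,
            {k: m.copy() for k, m in self.anp_matrices.items()},
            {k: m.copy() for k, m in self.dematel_matrices.items()},
        )


def check_judgments_cover(network: DecisionNetwork, judgments: JudgmentSet,
                          method: str) -> None:
    """Raise :class:`PipelineError`-compatible errors for missing contexts."""
    from .errors import PipelineError

    missing: list[str] = []
    for c in network.clusters:
        if len(c.elements) > 1 and c.label not in judgments.anp_matrices:
            missing.append(f"ANP within-cluster matrix for {c.label!r}")
    for e in network.subcriteria():
        if len(network.alternatives) > 1 and e not in judgments.anp_matrices:
            missing.append(f"ANP alternatives matrix for {e!r}")
    if method.lower() == "danp":
        for c in network.clusters:
            if len(c.elements) > 1 and c.label not in judgments.dematel_matrices:
                missing.append(f"DEMATEL influence matrix for {c.label!r}")
    if missing:
        raise PipelineError("missing judgment matrices: " + "; ".join(missing))


def aggregate_judgments(
    judgment_sets: Sequence[JudgmentSet],
    anp_scheme: str = "geometric",
    dematel_scheme: str = "arithmetic",
    participant_id: str = "group",
) -> JudgmentSet:
    """Merge per-participant judgment sets into one consolidated set.

    The default schemes are the element-wise geometric mean for reciprocal
    comparison matrices — the standard aggregation of individual judgments,
    which keeps the result reciprocal — and the element-wise arithmetic mean
    for influence matrices, which keeps 0-4 scores on their bounded scale
    (real-valued results are allowed).  Aggregation is permutation-invariant
    over participants.
    """
    if not judgment_sets:
        raise AggregationError("no judgment sets to aggregate")
    if anp_scheme not in ("geometric", "arithmetic"):
        raise AggregationError(f"unknown ANP aggregation scheme {anp_scheme!r}")
    if dematel_scheme not in ("geometric", "arithmetic"):
        raise AggregationError(f"unknown DEMATEL aggregation scheme {dematel_scheme!r}")

    ref = judgment_sets[0]
    anp_ctx = set(ref.anp_matrices)
    dem_ctx = set(ref.dematel_matrices)
    for js in judgment_sets[1:]:
        if set(js.anp_matrices) != anp_ctx or set(js.dematel_matrices) != dem_ctx:
            off = (set(js.anp_matrices) ^ anp_ctx) | (set(js.dematel_matrices) ^ dem_ctx)
            raise AggregationError(
                f"participant {js.participant_id!r} covers different contexts: "
                f"{sorted(off)}"
            )

    def _mean(stack: np.ndarray, scheme: str) -> np.ndarray:
        if scheme == "geometric":
            if np.any(stack <= 0):
                raise AggregationError(
                    "geometric aggregation requires strictly positive entries"
                )
            return np.exp(np.log(stack).mean(axis=0))
        return stack.mean(axis=0)

    anp_out: dict[str, ComparisonMatrix] = {}
    for ctx in ref.anp_matrices:
        mats = [js.anp_matrices[ctx] for js in judgment_sets]
        shapes = {m.values.shape for m in mats}
        if len(shapes) != 1:
            raise AggregationError(f"dimension mismatch in ANP context {ctx!r}")
        agg = _mean(np.stack([m.values for m in mats]), anp_scheme)
        if anp_scheme == "geometric":
            # exact reciprocity: rebuild lower triangle from the upper one
            iu = np.triu_indices(agg.shape[0], k=1)
            agg[(iu[1], iu[0])] = 1.0 / agg[iu]
            np.fill_diagonal(agg, 1.0)
        anp_out[ctx] = ComparisonMatrix(list(mats[0].labels), agg, mats[0].context)

    dem_out: dict[str, InfluenceMatrix] = {}
    for ctx in ref.dematel_matrices:
        mats = [js.dematel_matrices[ctx] for js in judgment_sets]
        shapes = {m.values.shape for m in mats}
        if len(shapes) != 1:
            raise AggregationError(f"dimension mismatch in DEMATEL context {ctx!r}")
        agg = _mean(np.stack([m.values for m in mats]), dematel_scheme)
        np.fill_diagonal(agg, 0.0)
        dem_out[ctx] = InfluenceMatrix(list(mats[0].labels), agg)

    return JudgmentSet(participant_id, anp_out, dem_out)


# ---------------------------------------------------------------------------
# Matrix CSV I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return ";" if first.count(";") >= first.count(",") and ";" in first else ","


def read_matrix_csv(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a square labelled matrix from CSV.

    First row: optional corner cell then column labels; following rows:
    row label then values.  ``.`` or ``,`` decimals and ``p/q`` fractions
    are accepted; ``;``-delimited files (the usual companion of decimal
    commas) are detected automatically.
    """
    text = Path(path).read_text()
    delim = _sniff_delimiter(text)
    rows = [r for r in csv.reader(text.splitlines(), delimiter=delim) if r]
    if len(rows) < 2:
        raise ValidationError(f"{path}: not a labelled matrix")
    header = [h.strip() for h in rows[0]]
    col_labels = header[1:]
    body = rows[1:]
    labels = [r[0].strip() for r in body]
    if col_labels != labels:
        raise ValidationError(
            f"{path}: row labels {labels} do not match column labels {col_labels}"
        )
    n = len(labels)
    values = np.empty((n, n))
    for i, r in enumerate(body):
        if len(r[1:]) != n:
            raise ValidationError(f"{path}: row {labels[i]!r} has {len(r) - 1} cells, expected {n}")
        for j, cell in enumerate(r[1:]):
            values[i, j] = parse_cell(cell)
    return labels, values


def write_matrix_csv(path: str | Path, labels: Sequence[str],
                     values: np.ndarray) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(labels))
        for lbl, row in zip(labels, np.asarray(values)):
            w.writerow([lbl] + [repr(float(v)) for v in row])


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9_.-]+", "_", label)


def save_judgments(judgment_sets: Sequence[JudgmentSet], directory: str | Path) -> None:
    """Write judgment sets as one sub-directory of CSV matrices per participant."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for js in judgment_sets:
        pdir = directory / _safe_name(js.participant_id)
        pdir.mkdir(exist_ok=True)
        index = {"participant_id": js.participant_id, "anp": {}, "dematel": {}}
        for ctx, m in js.anp_matrices.items():
            fname = f"anp_{_safe_name(ctx)}.csv"
            write_matrix_csv(pdir / fname, m.labels, m.values)
            index["anp"][ctx] = fname
        for ctx, m in js.dematel_matrices.items():
            fname = f"dematel_{_safe_name(ctx)}.csv"
            write_matrix_csv(pdir / fname, m.labels, m.values)
            index["dematel"][ctx] = fname
        (pdir / "index.json").write_text(json.dumps(index, indent=2))


def load_judgments(directory: str | Path) -> list[JudgmentSet]:
    """Load judgment sets written by :func:`save_judgments`."""
    directory = Path(directory)
    sets: list[JudgmentSet] = []
    for pdir in sorted(p for p in directory.iterdir() if p.is_dir()):
        idx_path = pdir / "index.json"
        if not idx_path.exists():
            continue
        index = json.loads(idx_path.read_text())
        anp = {}
        for ctx, fname in index["anp"].items():
            labels, values = read_matrix_csv(pdir / fname)
            anp[ctx] = ComparisonMatrix(labels, values, context=ctx)
        dem = {}
        for ctx, fname in index["dematel"].items():
            labels, values = read_matrix_csv(pdir / fname)
            dem[ctx] = InfluenceMatrix(labels, values)
        sets.append(JudgmentSet(index["participant_id"], anp, dem))
    if not sets:
        raise ValidationError(f"no judgment sets found under {directory}")
    return sets


# ---------------------------------------------------------------------------
# Weight table and result output
# ---------------------------------------------------------------------------


@dataclass
class WeightTable:
    """Element local/relative/global weights plus alternative scores.

    ``elements`` holds one row per network element with its cluster, local
    weight (LW, within-cluster priority), cluster relative weight (RW) and
    global weight (GW = LW x RW; NaN for strategy elements, which do not
    enter alternative scoring).  ``alternatives`` holds one row per project
    alternative with its composed score.  ``mode`` records the block
    normalization convention ("unit" or "paper").
    """

    elements: pd.DataFrame  # columns: cluster, element, LW, RW, GW
    alternatives: pd.DataFrame  # columns: alternative, score
    mode: str = "unit"

    def element_weight(self, element: str, column: str = "GW") -> float:
        row = self.elements[self.elements["element"] == element]
        if row.empty:
            raise KeyError(element)
        return float(row.iloc[0][column])

    def alternative_scores(self) -> dict[str, float]:
        return dict(zip(self.alternatives["alternative"], self.alternatives["score"]))

    def equals(self, other: "WeightTable") -> bool:
        return (
            self.mode == other.mode
            and self.elements.equals(other.elements)
            and self.alternatives.equals(other.alternatives)
        )


def _write_df(df: pd.DataFrame, path: Path) -> None:
    # repr-precision floats so a read-back reproduces values bit-exactly
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(df.columns)
        for _, row in df.iterrows():
            w.writerow([repr(float(v)) if isinstance(v, float) else v for v in row])


def write_results(result, destination: str | Path) -> list[Path]:
    """Write a pipeline result bundle to ``destination``.

    Emits ``weights.csv`` and ``alternatives.csv`` (the weight table),
    ``ranking.csv``, ``consistency.csv``, ``roles.csv`` when influence
    analysis was run, and a ``manifest.json`` describing inputs, options and
    versions.  Values are written at full precision so that
    :func:`read_weight_table` reproduces them bit-exactly.
    """
    wt: WeightTable | None = getattr(result, "weight_table", None)
    if isinstance(result, WeightTable):
        wt = result
    if wt is None or wt.elements.empty:
        raise DanpError("empty result bundle: nothing to write")
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    p = destination / "weights.csv"
    _write_df(wt.elements, p)
    written.append(p)
    p = destination / "alternatives.csv"
    _write_df(wt.alternatives, p)
    written.append(p)
    (destination / "mode.json").write_text(json.dumps({"mode": wt.mode}))
    written.append(destination / "mode.json")

    ranking = getattr(result, "ranking", None)
    if ranking is not None:
        p = destination / "ranking.csv"
        df = pd.DataFrame(
            {
                "position": range(1, len(ranking.order) + 1),
                "alternative": ranking.order,
                "score": [ranking.scores[a] for a in ranking.order],
            }
        )
        _write_df(df, p)
        written.append(p)

    reports = getattr(result, "consistency", None)
    if reports:
        p = destination / "consistency.csv"
        df = pd.DataFrame(
            [
                {
                    "context": ctx,
                    "n": r.n,
                    "lambda_max": r.lambda_max,
                    "CI": r.CI,
                    "RI": r.RI,
                    "CR": r.CR,
                    "acceptable": r.acceptable,
                }
                for ctx, r in reports.items()
            ]
        )
        _write_df(df, p)
        written.append(p)

    dematel = getattr(result, "dematel", None)
    if dematel:
        from .dematel_core import role_table

        p = destination / "roles.csv"
        frames = []
        for cluster, res in dematel.items():
            df = role_table(res)
            df.insert(0, "cluster", cluster)
            frames.append(df)
        _write_df(pd.concat(frames, ignore_index=True), p)
        written.append(p)

    manifest = dict(getattr(result, "manifest", {}) or {})
    p = destination / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, default=str))
    written.append(p)
    return written


def read_weight_table(directination: str | Path) -> WeightTable:
    """Load a weight table written by :func:`write_results` (bit-exact)."""
    d = Path(directination)
    elements = pd.read_csv(d / "weights.csv", float_precision="round_trip")
    alternatives = pd.read_csv(d / "alternatives.csv", float_precision="round_trip")
    mode = "unit"
    mode_path = d / "mode.json"
    if mode_path.exists():
        mode = json.loads(mode_path.read_text()).get("mode", "unit")
    return WeightTable(elements=elements, alternatives=alternatives, mode=mode)
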