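"""Cell clustering and marker-logic lineage annotation.

Cells are grouped by agglomerative hierarchical clustering on 1 - Pearson
correlation with the ward.D2 criterion (squared-distance Lance-Williams
update), embedded in 2-D with t-SNE for visualisation, and labelled by an
ordered list of boolean marker rules: each rule demands a set of genes "on"
(above theta_on), "off" (at or below theta_off), "low" (in between), and
optionally at least one gene of an any-on set; the first rule whose
conditions all hold wins.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import Sc3kitError, ZeroVarianceCellError
from .quant import ExpressionMatrix

logger = logging.getLogger(__name__)

UNCLASSIFIED = "UNCLASSIFIED"

ON, LOW, OFF = "on", "low", "off"


@dataclass(frozen=True)
class Thresholds:
    """Expression levels separating (+) / (low) / (-) on the log2(RPM+1) scale.

    on: value > theta_on; off: value <= theta_off; low: in between.
    """

    theta_on: float = 4.0
    theta_off: float = 2.0

    def __post_init__(self) -> None:
        if self.theta_off >= self.theta_on:
            raise ValueError("theta_off must be < theta_on")

    def state(self, value: float) -> str:
        if value > self.theta_on:
            return ON
        if value <= self.theta_off:
            return OFF
        return LOW


@dataclass(frozen=True)
class MarkerRule:
    """Boolean on/low/off requirements over named genes defining one lineage."""

    label: str
    requires_on: frozenset[str] = frozenset()
    requires_off: frozenset[str] = frozenset()
    requires_low: frozenset[str] = frozenset()
    requires_any_on: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        sets = [self.requires_on, self.requires_off, self.requires_low,
                self.requires_any_on]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError(f"rule {self.label!r}: gene sets must be pairwise disjoint")

    @property
    def genes(self) -> frozenset[str]:
        return self.requires_on | self.requires_off | self.requires_low | self.requires_any_on


def default_rules() -> list[MarkerRule]:
    """The nine built-in lineage rules, in priority order."""
    specs = [
        ("ePGC", dict(requires_on={"PRDM1", "TFAP2C", "SOX17"}, requires_off={"SOX2"})),
        ("lPGC", dict(requires_on={"POU5F1", "NANOG", "TFAP2C"}, requires_off={"SOX2"})),
        ("Post-EPI", dict(requires_on={"POU5F1", "NANOG", "SOX2", "PRDM14"},
                          requires_off={"T", "GATA4"})),
        ("Pre-EPI", dict(requires_on={"NANOG", "SOX2"},
                         requires_off={"GATA6", "TFAP2C"})),
        ("Hypoblast", dict(requires_on={"SOX17", "GATA4", "GATA6"},
                           requires_off={"NANOG"})),
        ("TE", dict(requires_on={"TFAP2C", "GATA3", "GATA6"}, requires_off={"NANOG"})),
        ("Gastrulating", dict(requires_on={"POU5F1"},
                              requires_low={"NANOG", "PRDM14"},
                              requires_any_on={"T", "GATA4", "GATA6"})),
        ("VE/YE", dict(requires_low={"POU5F1"}, requires_on={"FOXA1"})),
        ("EXMC", dict(requires_low={"POU5F1"}, requires_on={"COL6A1"})),
    ]
    return [
        MarkerRule(label=label, priority=i,
                   **{k: frozenset(v) for k, v in kw.items()})
        for i, (label, kw) in enumerate(specs)
    ]


def rules_from_json(path) -> list[MarkerRule]:
    """Load rules from a JSON list of objects with label / on / off / low / any_on."""
    raw = json.loads(open(path).read())
    rules = []
    for i, obj in enumerate(raw):
        rules.append(MarkerRule(
            label=obj["label"],
            requires_on=frozenset(obj.get("on", [])),
            requires_off=frozenset(obj.get("off", [])),
            requires_low=frozenset(obj.get("low", [])),
            requires_any_on=frozenset(obj.get("any_on", [])),
            priority=obj.get("priority", i),
        ))
    return rules


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def pearson_distance(logm: ExpressionMatrix) -> pd.DataFrame:
    """Cell x cell matrix of 1 - Pearson correlation (across genes)."""
    vals = logm.values.to_numpy(dtype=float)
    if vals.shape[0] < 2 or vals.shape[1] < 2:
        raise Sc3kitError("need at least 2 genes and 2 cells")
    sd = vals.std(axis=0)
    for j in np.flatnonzero(sd == 0):
        raise ZeroVarianceCellError(
            f"cell {logm.values.columns[j]!r} has zero variance across genes"
        )
    corr = np.corrcoef(vals, rowvar=False)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    cells = logm.values.columns
    return pd.DataFrame(d, index=cells, columns=cells)


@dataclass
class Dendrogram:
    """Merge history of an agglomerative clustering (scipy linkage layout)."""

    linkage: np.ndarray        # (n-1, 4): children, height, size
    leaf_ids: list[str]

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")
        if self.linkage.shape[0] != len(self.leaf_ids) - 1:
            raise ValueError("a dendrogram over n leaves needs n-1 merges")

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        n = len(self.leaf_ids)

        def node(i: int) -> str:
            if i < n:
                return self.leaf_ids[i].replace(" ", "_")
            a, b, h, _ = self.linkage[i - n]
            return f"({node(int(a))},{node(int(b))}):{h:.6g}"

        return node(2 * n - 2) + ";"


def uhc_ward(d: pd.DataFrame) -> Dendrogram:
    """Hierarchical clustering of a precomputed dissimilarity under ward.D2.

    The Lance-Williams recursion runs on squared dissimilarities, matching
    R's ``hclust(..., method="ward.D2")`` on the same distance matrix.
    """
    dm = d.to_numpy(dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise Sc3kitError("distance matrix must be square and symmetric")
    condensed = squareform(dm, checks=False)
    linkage = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(linkage=linkage, leaf_ids=list(d.index))


def cut_clusters(dend: Dendrogram, k: int) -> pd.Series:
    """Partition the leaves into k groups by removing the k-1 highest merges."""
    n = len(dend.leaf_ids)
    if not 1 <= k <= n:
        raise Sc3kitError(f"k must be in [1, {n}], got {k}")
    labels = hierarchy.cut_tree(dend.linkage, n_clusters=k).ravel()
    return pd.Series(labels, index=dend.leaf_ids, name="cluster")


def tsne_embed(
    logm: ExpressionMatrix, seed: int, perplexity: float = 30.0
) -> pd.DataFrame:
    """Seeded 2-D t-SNE of cells; requires at least 3 x perplexity cells."""
    from sklearn.manifold import TSNE

    n_cells = logm.values.shape[1]
    if n_cells < 3 * perplexity:
        raise Sc3kitError(
            f"t-SNE needs >= {int(3 * perplexity)} cells for perplexity "
            f"{perplexity}; got {n_cells}"
        )
    emb = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init="pca"
    ).fit_transform(logm.values.to_numpy(dtype=float).T)
    return pd.DataFrame(emb, index=logm.values.columns, columns=["tsne1", "tsne2"])


# ---------------------------------------------------------------------------
# Marker-rule classification
# ---------------------------------------------------------------------------

@dataclass
class RuleTrace:
    """Evaluation record of every rule condition for one cell."""

    label: str
    conditions: dict[str, bool] = field(default_factory=dict)
    matched: bool = False


def _rule_matches(
    rule: MarkerRule, states: Mapping[str, str]
) -> RuleTrace:
    trace = RuleTrace(label=rule.label)
    ok = True
    for gene in sorted(rule.requires_on):
        hit = states.get(gene) == ON
        trace.conditions[f"{gene}=on"] = hit
        ok = ok and hit
    for gene in sorted(rule.requires_off):
        hit = states.get(gene) == OFF
        trace.conditions[f"{gene}=off"] = hit
        ok = ok and hit
    for gene in sorted(rule.requires_low):
        hit = states.get(gene) == LOW
        trace.conditions[f"{gene}=low"] = hit
        ok = ok and hit
    if rule.requires_any_on:
        hit = any(states.get(g) == ON for g in rule.requires_any_on)
        trace.conditions["any_on(" + ",".join(sorted(rule.requires_any_on)) + ")"] = hit
        ok = ok and hit
    trace.matched = ok
    return trace


def classify_cells(
    logm: ExpressionMatrix,
    rules: Sequence[MarkerRule] | None = None,
    thresholds: Thresholds | None = None,
) -> tuple[pd.Series, dict[str, list[RuleTrace]]]:
    """Assign each cell the first (lowest-priority-number) matching rule label.

    Rules referencing genes absent from the matrix are skipped with a warning.
    Returns (labels indexed by cell, per-cell rule traces).
    """
    rules = list(rules) if rules is not None else default_rules()
    thresholds = thresholds or Thresholds()
    rules.sort(key=lambda r: r.priority)

    present = set(logm.values.index)
    usable = []
    for rule in rules:
        missing = rule.genes - present
        if missing:
            logger.warning("rule %r skipped: missing gene(s) %s",
                           rule.label, sorted(missing))
        else:
            usable.append(rule)

    labels = {}
    traces: dict[str, list[RuleTrace]] = {}
    for cell in logm.values.columns:
        col = logm.values[cell]
        states = {g: thresholds.state(col.at[g])
                  for rule in usable for g in rule.genes}
        cell_traces = []
        label = UNCLASSIFIED
        for rule in usable:
            tr = _rule_matches(rule, states)
            cell_traces.append(tr)
            if tr.matched:
                label = rule.label
                break
        labels[cell] = label
        traces[cell] = cell_traces
    return pd.Series(labels, name="label"), traces
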