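"""Diagnostic layer: the published fixed decision tree, a simplified CHAID
induction algorithm, and ROC/AUC evaluation for AD-vs-bvFTD discrimination.

The fixed tree is the published classifier and is shipped verbatim so that
replication never depends on the tree fitter:

* root: ACE-III total, "> 70" vs "<= 70" (70 itself takes the lower branch);
* ACE-III > 70: >= 1 within-search error (sum of trials 1 and 2) at the
  6-box set size => AD, else bvFTD;
* ACE-III <= 70: >= 2 between-search errors (sum of trials 1 and 2) at the
  4-box set size => AD, else bvFTD.

The CHAID fitter is a documented simplification of chi-square automatic
interaction detection: continuous predictors are binned, adjacent bins are
merged while a 2x2 chi-square test finds them indistinguishable, and the
best predictor's Bonferroni-adjusted p-value decides the split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, rankdata

from .task_core import DomainError

AD, BVFTD = "AD", "bvFTD"

#: fixed published cut-offs (root ACE-III; 6-box within sum; 4-box between sum)
ACE_CUTOFF = 70
WS6_CUTOFF = 1
BS4_CUTOFF = 2


# ---------------------------------------------------------------------------
# fixed published tree
# ---------------------------------------------------------------------------


def classify_published_tree(ace_total: float, ws6_sum: int, bs4_sum: int) -> str:
    """Apply the published ACE-III + Box Task error decision tree."""
    if not (0 <= ace_total <= 100):
        raise DomainError(f"ACE-III total must be in [0, 100], got {ace_total}")
    if ws6_sum < 0 or bs4_sum < 0:
        raise DomainError("error counts must be non-negative")
    if ace_total > ACE_CUTOFF:
        return AD if ws6_sum >= WS6_CUTOFF else BVFTD
    return AD if bs4_sum >= BS4_CUTOFF else BVFTD


def classify_table(df: pd.DataFrame) -> pd.Series:
    """Vectorised fixed-tree labels for a table with columns
    ``ace_total``, ``ws6_sum``, ``bs4_sum``."""
    return df.apply(
        lambda r: classify_published_tree(r["ace_total"], r["ws6_sum"], r["bs4_sum"]), axis=1
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EvaluationResult:
    classes: tuple[str, str]
    confusion: np.ndarray  # rows = true class, cols = predicted
    per_class_percent_correct: dict[str, float]
    overall_percent_correct: float
    risk_estimate: float
    risk_se: float
    n: int


def evaluate_classifier(predictions: Sequence[str], labels: Sequence[str]) -> EvaluationResult:
    """Confusion matrix, per-class and overall percent correct, and the
    misclassification risk r with standard error sqrt(r(1-r)/n)."""
    predictions = list(predictions)
    labels = list(labels)
    if not labels:
        raise DomainError("empty input")
    if len(predictions) != len(labels):
        raise DomainError("predictions and labels differ in length")
    classes = tuple(sorted(set(labels) | set(predictions)))
    if len(classes) > 2:
        raise DomainError(f"expected two classes, got {classes}")
    idx = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(labels, predictions):
        conf[idx[t], idx[p]] += 1
    n = len(labels)
    correct = int(np.trace(conf))
    per_class = {
        c: float(100.0 * conf[i, i] / conf[i].sum()) if conf[i].sum() else float("nan")
        for c, i in idx.items()
    }
    overall = 100.0 * correct / n
    risk = 1.0 - correct / n
    return EvaluationResult(
        classes=classes,
        confusion=conf,
        per_class_percent_correct=per_class,
        overall_percent_correct=overall,
        risk_estimate=risk,
        risk_se=math.sqrt(risk * (1.0 - risk) / n),
        n=n,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    auc: float
    points: list[tuple[float, float]]  # (FPR, TPR) from (0,0) to (1,1)
    larger_indicates_positive: bool
    positive_label: str


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    larger_indicates_positive: bool = True,
    positive_label: str = AD,
) -> RocResult:
    """AUC as the Mann-Whitney probability (ties count 0.5) plus the full
    ROC curve at midpoint thresholds.

    With ``larger_indicates_positive=False`` the scores are negated first,
    so an AUC above 0.5 always means discrimination in the stated direction
    (used for cognitive scores where *lower* values are more AD-like).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive_label else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DomainError("both classes must be present")
    s = scores if larger_indicates_positive else -scores

    ranks = rankdata(s)  # average ranks handle ties exactly
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    # curve at midpoints between consecutive distinct scores plus sentinels
    uniq = np.unique(s)
    thresholds = np.concatenate(([np.inf], (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else [], [-np.inf]))
    points = []
    for thr in sorted(thresholds, reverse=True):
        pred_pos = s >= thr
        tpr = float(pred_pos[y == 1].mean())
        fpr = float(pred_pos[y == 0].mean())
        points.append((fpr, tpr))
    points = sorted(set(points))
    return RocResult(
        auc=float(auc),
        points=points,
        larger_indicates_positive=larger_indicates_positive,
        positive_label=positive_label,
    )


# ---------------------------------------------------------------------------
# simplified CHAID
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChaidParams:
    alpha_merge: float = 0.05
    alpha_split: float = 0.05
    min_node_size: int = 10
    max_depth: int = 3
    forced_first: str | None = None
    binning: int = 20  # max candidate cut-points for continuous predictors

    def __post_init__(self) -> None:
        if not (0 < self.alpha_merge <= 1 and 0 < self.alpha_split <= 1):
            raise DomainError("alpha levels must be in (0, 1]")
        if self.min_node_size < 2:
            raise DomainError("min_node_size must be >= 2")
        if self.max_depth < 1:
            raise DomainError("max_depth must be >= 1")


@dataclass
class TreeNode:
    n: int
    class_counts: dict[str, int]
    label: str
    depth: int
    predictor: str | None = None
    #: upper edges of the first r-1 children; child i holds values
    #: (thresholds[i-1], thresholds[i]] on the predictor
    thresholds: list[float] = field(default_factory=list)
    adjusted_p: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def predict_row(self, row: Mapping) -> str:
        if self.is_leaf:
            return self.label
        x = float(row[self.predictor])
        for i, thr in enumerate(self.thresholds):
            if x <= thr:
                return self.children[i].predict_row(row)
        return self.children[-1].predict_row(row)

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "class_counts": self.class_counts,
            "label": self.label,
        }
        if not self.is_leaf:
            d.update(
                predictor=self.predictor,
                thresholds=self.thresholds,
                adjusted_p=self.adjusted_p,
                children=[c.to_dict() for c in self.children],
            )
        return d

    def render(self, indent: int = 0) -> str:
        pad = "  " * indent
        head = f"{pad}n={self.n} counts={self.class_counts} -> {self.label}"
        if self.is_leaf:
            return head
        lines = [head + f"  split on {self.predictor} (adj p={self.adjusted_p:.3g})"]
        bounds = [-math.inf] + list(self.thresholds) + [math.inf]
        for i, child in enumerate(self.children):
            lines.append(f"{pad}  [{bounds[i]:g} < {self.predictor} <= {bounds[i + 1]:g}]")
            lines.append(child.render(indent + 2))
        return "\n".join(lines)


def _majority_label(counts: dict[str, int]) -> str:
    # tie-break toward AD: the clinically costlier miss
    best = max(counts.values()) if counts else 0
    tied = sorted(c for c, v in counts.items() if v == best)
    return AD if AD in tied else (tied[0] if tied else AD)


def _chi2_p(table: np.ndarray) -> float:
    """p-value of the label-independence chi-square; degenerate tables
    (a zero row/column) carry no evidence and return p = 1."""
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0
    return float(chi2_contingency(table, correction=False)[1])


def _candidate_bins(x: np.ndarray, binning: int) -> np.ndarray:
    """Category upper-edges: unique values when few, else quantile cuts."""
    uniq = np.unique(x)
    if len(uniq) <= binning:
        return uniq
    qs = np.quantile(x, np.linspace(0.0, 1.0, binning + 1)[1:-1])
    edges = np.unique(qs)
    return np.append(edges, uniq[-1])


def _best_split_for_predictor(
    x: np.ndarray, y: np.ndarray, classes: list[str], params: ChaidParams
) -> tuple[float, list[float]] | None:
    """Merge adjacent bins CHAID-style; return (Bonferroni-adjusted p,
    thresholds between the surviving categories) or None if unsplittable."""
    edges = _candidate_bins(x, params.binning)
    cat = np.searchsorted(edges, x)  # x <= edges[i] -> category i
    counts = []
    kept_edges = []
    for i in range(len(edges)):
        mask = cat == i
        if mask.any():
            counts.append([int(((y == c) & mask).sum()) for c in classes])
            kept_edges.append(float(edges[i]))
    table = np.array(counts, dtype=int)
    c0 = len(table)
    if c0 < 2:
        return None

    # iteratively merge the most-similar adjacent pair while p > alpha_merge
    while len(table) > 2:
        pairs = [_chi2_p(table[i : i + 2]) for i in range(len(table) - 1)]
        i = int(np.argmax(pairs))
        if pairs[i] <= params.alpha_merge:
            break
        table = np.vstack([table[:i], table[i] + table[i + 1], table[i + 2 :]])
        kept_edges = kept_edges[:i] + kept_edges[i + 1 :]

    # absorb categories too small to stand as children
    while len(table) > 1 and table.sum(axis=1).min() < params.min_node_size:
        i = int(np.argmin(table.sum(axis=1)))
        j = i - 1 if i == len(table) - 1 else i + 1
        lo, hi = min(i, j), max(i, j)
        table = np.vstack([table[:lo], table[lo] + table[hi], table[hi + 1 :]])
        kept_edges = kept_edges[:lo] + kept_edges[lo + 1 :]

    r = len(table)
    if r < 2:
        return None
    p = _chi2_p(table)
    bonferroni = math.comb(c0 - 1, r - 1)
    adj_p = min(1.0, p * bonferroni)
    # thresholds separating the r children: upper edge of each non-final child
    return adj_p, kept_edges[: r - 1]


def fit_chaid(
    features: pd.DataFrame,
    labels: Sequence[str],
    params: ChaidParams | None = None,
) -> TreeNode:
    """Recursive CHAID partitioning of ``features`` (numeric columns only)
    against two-class ``labels``.  ``params.forced_first`` names a predictor
    that is split first at the root regardless of the split test (the
    published analysis forced the ACE-III total in first)."""
    params = params or ChaidParams()
    y = np.asarray([str(l) for l in labels])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise DomainError("need >= 2 classes to fit a tree")
    if len(features) != len(y):
        raise DomainError("features and labels differ in length")
    if len(y) < 2 * params.min_node_size:
        raise DomainError(f"need n >= {2 * params.min_node_size} rows")
    if params.forced_first is not None and params.forced_first not in features.columns:
        raise DomainError(f"forced_first predictor '{params.forced_first}' not in features")

    X = features.reset_index(drop=True)

    def build(idx: np.ndarray, depth: int, forced: str | None) -> TreeNode:
        sub_y = y[idx]
        counts = {str(c): int((sub_y == c).sum()) for c in classes}
        node = TreeNode(n=len(idx), class_counts=counts, label=_majority_label(counts), depth=depth)
        if depth >= params.max_depth or len(idx) < 2 * params.min_node_size or len(set(sub_y)) < 2:
            return node

        candidates: list[tuple[float, str, list[float]]] = []
        for col in X.columns:
            x = X[col].to_numpy(dtype=float)[idx]
            if np.all(x == x[0]):
                continue  # degenerate predictor in this node
            res = _best_split_for_predictor(x, sub_y, classes, params)
            if res is not None:
                candidates.append((res[0], col, res[1]))
        if not candidates:
            return node

        if forced is not None:
            chosen = [c for c in candidates if c[1] == forced]
            if not chosen:
                return node
            adj_p, col, thresholds = chosen[0]
        else:
            candidates.sort(key=lambda c: (c[0], c[1]))
            adj_p, col, thresholds = candidates[0]
            if adj_p > params.alpha_split:
                return node

        node.predictor = col
        node.thresholds = [float(t) for t in thresholds]
        node.adjusted_p = adj_p
        xcol = X[col].to_numpy(dtype=float)
        bounds = [-np.inf] + node.thresholds + [np.inf]
        for i in range(len(bounds) - 1):
            child_idx = idx[(xcol[idx] > bounds[i]) & (xcol[idx] <= bounds[i + 1])]
            node.children.append(build(child_idx, depth + 1, None))
        return node

    return build(np.arange(len(y)), 0, params.forced_first)


def predict_tree(tree: TreeNode, features: pd.DataFrame) -> list[str]:
    return [tree.predict_row(row) for _, row in features.iterrows()]


def binary_threshold(node: TreeNode) -> float:
    """For a binary split, the boundary value: rows with predictor <= the
    returned value go to the first child."""
    if node.is_leaf or len(node.children) != 2:
        raise DomainError("node is not a binary split")
    return node.thresholds[0]
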