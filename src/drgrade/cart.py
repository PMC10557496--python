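"""From-scratch CART: Gini impurity, binary axis-aligned splits, rule export.

The grading rule set is itself the product of a classification tree trained
on labeled feature tables, so the tree learner is first-class here: it
re-derives threshold rules (with leaf confidences) from data rather than
consuming them.  Splits are exhaustive over midpoints of consecutive
distinct feature values; ties break toward the lowest feature index, then
the lowest threshold, making training deterministic for a fixed table.

Confidences attached to extracted rules are training-set leaf fractions:
100 x (majority-class count) / (leaf size).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .quantify import FEATURE_NAMES, FeatureVector
from .rules import (COUNT_FEATURES, SEVERITY_LABELS, Predicate, Rule,
                    RuleSet)

N_CLASSES = 5


@dataclass
class LabeledTable:
    """Feature vectors with severity labels, for training and evaluation."""

    rows: list[tuple[FeatureVector, int]]
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self):
        for _, y in self.rows:
            if not 0 <= int(y) < N_CLASSES:
                raise ValueError(f"label {y} outside 0..{N_CLASSES - 1}")

    def __len__(self) -> int:
        return len(self.rows)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.array([fv.as_array() for fv, _ in self.rows], dtype=float)
        y = np.array([y for _, y in self.rows], dtype=np.int64)
        return X, y

    @classmethod
    def from_arrays(cls, X: np.ndarray, y: Sequence[int]) -> "LabeledTable":
        return cls(rows=[(FeatureVector.from_array(row), int(lab))
                         for row, lab in zip(np.asarray(X, dtype=float), y)])

    @classmethod
    def concat(cls, tables: Sequence["LabeledTable"]) -> "LabeledTable":
        rows: list[tuple[FeatureVector, int]] = []
        for t in tables:
            rows.extend(t.rows)
        return cls(rows=rows)


@dataclass
class TreeNode:
    """Internal node (feature/threshold, two children) or leaf (class counts).

    Split semantics: value <= threshold routes left.
    """

    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    class_counts: Optional[tuple[int, ...]] = None

    @property
    def is_leaf(self) -> bool:
        return self.class_counts is not None

    def __post_init__(self):
        if self.class_counts is not None:
            if sum(self.class_counts) <= 0:
                raise ValueError("leaf class counts must sum to > 0")
        elif self.left is None or self.right is None:
            raise ValueError("internal node needs both children")

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class_counts": list(self.class_counts)}
        return {"feature": self.feature, "threshold": self.threshold,
                "left": self.left.to_dict(), "right": self.right.to_dict()}

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "class_counts" in d:
            return cls(class_counts=tuple(int(c) for c in d["class_counts"]))
        return cls(feature=d["feature"], threshold=float(d["threshold"]),
                   left=cls.from_dict(d["left"]),
                   right=cls.from_dict(d["right"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def load_tree(path: str | Path) -> TreeNode:
    return TreeNode.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class CartConfig:
    max_depth: int = 12
    min_samples_leaf: int = 1
    min_impurity_decrease: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")


def gini(class_counts: Sequence[int]) -> float:
    """Gini impurity 1 - sum p_k^2; 0 for a pure node, 0.8 for uniform-5."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative class count")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero class counts have no impurity")
    p = counts / total
    return float(1.0 - np.sum(p * p))


def _class_counts(y: np.ndarray) -> np.ndarray:
    return np.bincount(y, minlength=N_CLASSES)


def best_split(table_or_X, y: Optional[np.ndarray] = None,
               candidate_features: Optional[Sequence[int]] = None,
               min_samples_leaf: int = 1,
               ) -> Optional[tuple[int, float, float]]:
    """Exhaustive best Gini split of a table.

    Returns ``(feature_index, threshold, impurity_decrease)`` for the split
    maximizing the weighted Gini decrease over midpoints of consecutive
    distinct sorted values of each candidate feature, or ``None`` when no
    candidate reduces impurity.  Ties break toward the lowest feature index,
    then the lowest threshold.
    """
    if isinstance(table_or_X, LabeledTable):
        X, y = table_or_X.to_arrays()
    else:
        X = np.asarray(table_or_X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
    n = len(y)
    if n < 2:
        return None
    parent = gini(_class_counts(y))
    features = range(X.shape[1]) if candidate_features is None \
        else candidate_features

    best: Optional[tuple[int, float, float]] = None
    for f in features:
        col = X[:, f]
        order = np.argsort(col, kind="stable")
        v, yo = col[order], y[order]
        # one-hot cumulative class counts for every left-prefix
        onehot = np.zeros((n, N_CLASSES))
        onehot[np.arange(n), yo] = 1.0
        left = np.cumsum(onehot, axis=0)          # counts after i+1 rows
        total = left[-1]
        # candidate cut after row i requires v[i] < v[i+1]
        cuts = np.nonzero(v[:-1] < v[1:])[0]
        if cuts.size == 0:
            continue
        nl = cuts + 1.0
        nr = n - nl
        ok = (nl >= min_samples_leaf) & (nr >= min_samples_leaf)
        cuts, nl, nr = cuts[ok], nl[ok], nr[ok]
        if cuts.size == 0:
            continue
        lc = left[cuts]
        rc = total[None, :] - lc
        gl = 1.0 - np.sum((lc / nl[:, None]) ** 2, axis=1)
        gr = 1.0 - np.sum((rc / nr[:, None]) ** 2, axis=1)
        dec = parent - (nl * gl + nr * gr) / n
        k = int(np.argmax(dec))  # first max -> lowest threshold on ties
        if dec[k] <= 0:
            continue
        thr = (v[cuts[k]] + v[cuts[k] + 1]) / 2.0
        if best is None or dec[k] > best[2] + 1e-15:
            best = (f, float(thr), float(dec[k]))
    return best


def build_tree(table: LabeledTable, config: CartConfig = CartConfig()
               ) -> TreeNode:
    """Recursive partitioning until purity, depth or leaf-size limits."""
    if len(table) == 0:
        raise ValueError("cannot build a tree from an empty table")
    X, y = table.to_arrays()

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        counts = _class_counts(y[idx])
        if (depth >= config.max_depth
                or gini(counts) == 0.0
                or len(idx) < 2 * config.min_samples_leaf):
            return TreeNode(class_counts=tuple(int(c) for c in counts))
        split = best_split(X[idx], y[idx],
                           min_samples_leaf=config.min_samples_leaf)
        if split is None or split[2] < config.min_impurity_decrease:
            return TreeNode(class_counts=tuple(int(c) for c in counts))
        f, thr, _ = split
        mask = X[idx, f] <= thr
        return TreeNode(feature=FEATURE_NAMES[f], threshold=thr,
                        left=grow(idx[mask], depth + 1),
                        right=grow(idx[~mask], depth + 1))

    return grow(np.arange(len(y)), 0)


def predict(tree: TreeNode, features: FeatureVector) -> int:
    """Severity predicted by tree traversal; leaf ties go to the lower level."""
    node = tree
    while not node.is_leaf:
        v = features[node.feature]
        node = node.left if v <= node.threshold else node.right
    return int(np.argmax(node.class_counts))


def predict_table(tree: TreeNode, table: LabeledTable) -> np.ndarray:
    return np.array([predict(tree, fv) for fv, _ in table.rows])


def accuracy(tree: TreeNode, table: LabeledTable) -> float:
    _, y = table.to_arrays()
    return float(np.mean(predict_table(tree, table) == y))


def extract_rules(tree: TreeNode, fallback_policy: str = "error") -> RuleSet:
    """One conjunctive rule per leaf, bounds merged per feature.

    Redundant same-feature predicates on a root-to-leaf path collapse into
    the tightest lower/upper bounds; count-feature paths with both bounds
    finite are rendered as integer ranges.  Because the leaves partition the
    feature space, the resulting rule set is exhaustive and mutually
    exclusive, so the fallback policy is never exercised.
    """
    rules: list[Rule] = []

    def walk(node: TreeNode, bounds: dict[str, list[float]]) -> None:
        if node.is_leaf:
            preds: list[Predicate] = []
            for feat, (lo, hi) in bounds.items():
                is_count = feat in COUNT_FEATURES
                if is_count and lo > -np.inf and hi < np.inf:
                    preds.append(Predicate(feat, "in_int_range",
                                           (int(np.floor(lo)) + 1,
                                            int(np.floor(hi)))))
                    continue
                if lo > -np.inf:
                    preds.append(Predicate(feat, "gt", lo))
                if hi < np.inf:
                    preds.append(Predicate(feat, "le", hi))
            counts = node.class_counts
            sev = int(np.argmax(counts))
            conf = 100.0 * max(counts) / sum(counts)
            rules.append(Rule(rule_id=f"leaf_{len(rules):03d}",
                              predicates=tuple(preds), severity=sev,
                              label=SEVERITY_LABELS[sev], confidence=conf))
            return
        lo, hi = bounds.get(node.feature, [-np.inf, np.inf])
        left_bounds = dict(bounds)
        left_bounds[node.feature] = [lo, min(hi, node.threshold)]
        walk(node.left, left_bounds)
        right_bounds = dict(bounds)
        right_bounds[node.feature] = [max(lo, node.threshold), hi]
        walk(node.right, right_bounds)

    walk(tree, {})
    return RuleSet(rules=rules, fallback_policy=fallback_policy)
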