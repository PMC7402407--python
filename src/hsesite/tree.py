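"""Binary CART decision tree with Gini impurity and exhaustive best-first splits.

The classifier behind the site predictor is deliberately simple: a binary
decision tree grown by exhaustively searching, at every node, all features
and all thresholds (midpoints between consecutive distinct sorted values)
for the split that maximally decreases the weighted Gini impurity. Growth
stops at pure nodes, nodes smaller than ``min_samples_split`` (default 2),
nodes at ``max_depth`` (unlimited by default), or when every feature is
constant within the node. Leaves store their class counts; the prediction score of a sample is
the positive-class fraction of the leaf it lands in.

The tree is implemented from scratch so the split mechanics are directly
testable against hand-enumerated candidates; with the "best" splitter the
whole procedure is deterministic (ties resolved by lowest feature index,
then smallest threshold) and refits are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class TreeParams:
    """criterion/splitter are fixed to gini/best; min_samples_split is the
    smallest node that may still be split; seed is reserved for stochastic
    extensions (feature subsampling) — the default splitter ignores it."""

    criterion: str = "gini"
    splitter: str = "best"
    min_samples_split: int = 2
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.criterion != "gini":
            raise ValueError("only the gini criterion is implemented")
        if self.splitter != "best":
            raise ValueError("only the 'best' splitter is implemented")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.max_depth is not None and self.max_depth < 0:
            raise ValueError("max_depth must be non-negative")


def gini_impurity(class_counts: tuple[int, int]) -> float:
    """Gini impurity 1 − p₀² − p₁² of a node with the given class counts."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0:
        raise ValueError("class counts must be non-negative")
    total = n0 + n1
    if total == 0:
        raise ValueError("empty node has no impurity")
    p0, p1 = n0 / total, n1 / total
    return 1.0 - p0 * p0 - p1 * p1


def best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float, float] | None:
    """Exhaustive best split of (X, y): (feature, threshold, gain) or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values of each feature; the split sends ``x <= threshold`` left. Gain is
    the decrease from parent impurity to the size-weighted child impurity
    (never negative, since Gini is concave). Ties: lowest feature index,
    then smallest threshold. None when the node is already pure or every
    feature is constant; a zero-gain split on an impure node is still
    returned — parity-structured data (XOR) only become separable after a
    split that does not itself reduce impurity.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    parent = gini_impurity((n0, n1))
    if parent == 0.0:
        return None
    best: tuple[int, float, float] | None = None
    for f in range(X.shape[1]):
        x = X[:, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cum1 = np.cumsum(y[order])
        cut = np.flatnonzero(xs[:-1] < xs[1:])  # split after sorted index i
        if len(cut) == 0:
            continue
        nl = cut + 1
        l1 = cum1[cut]
        l0 = nl - l1
        nr = n - nl
        r1 = n1 - l1
        r0 = n0 - l0
        gl = 1.0 - (l0 / nl) ** 2 - (l1 / nl) ** 2
        gr = 1.0 - (r0 / nr) ** 2 - (r1 / nr) ** 2
        gains = parent - (nl * gl + nr * gr) / n
        j = int(np.argmax(gains))  # first max -> smallest threshold in a tie
        if best is None or gains[j] > best[2]:
            threshold = (xs[cut[j]] + xs[cut[j] + 1]) / 2.0
            best = (f, float(threshold), float(gains[j]))
    return best


@dataclass
class TreeModel:
    """A fitted tree: nested node dicts plus the training feature width.

    Internal nodes: {"feature", "threshold", "left", "right"}; leaves:
    {"n0", "n1", "score"} where score = n1 / (n0 + n1).
    """

    root: dict
    n_features: int
    params: TreeParams = TreeParams()

    def depth(self) -> int:
        def _d(node: dict) -> int:
            if "score" in node:
                return 0
            return 1 + max(_d(node["left"]), _d(node["right"]))

        return _d(self.root)

    def save(self, path: str | Path) -> None:
        payload = {
            "n_features": self.n_features,
            "params": {
                "criterion": self.params.criterion,
                "splitter": self.params.splitter,
                "min_samples_split": self.params.min_samples_split,
                "max_depth": self.params.max_depth,
                "seed": self.params.seed,
            },
            "root": self.root,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            root=payload["root"],
            n_features=int(payload["n_features"]),
            params=TreeParams(**payload["params"]),
        )


def fit(X: np.ndarray, y: np.ndarray, params: TreeParams = TreeParams()) -> TreeModel:
    """Grow a CART tree on binary-labeled data.

    Deterministic given the input order and parameters; raises on
    non-binary labels or an empty dataset.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D and aligned with y")
    if len(y) == 0:
        raise ValueError("cannot fit on an empty dataset")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")

    root: dict = {}
    stack: list[tuple[dict, np.ndarray, int]] = [(root, np.arange(len(y)), 0)]
    while stack:
        node, idx, depth = stack.pop()
        sub_y = y[idx]
        n1 = int(sub_y.sum())
        n0 = len(idx) - n1
        stop = (
            n0 == 0
            or n1 == 0
            or len(idx) < params.min_samples_split
            or (params.max_depth is not None and depth >= params.max_depth)
        )
        split = None if stop else best_split(X[idx], sub_y)
        if split is None:
            node["n0"] = n0
            node["n1"] = n1
            node["score"] = n1 / (n0 + n1)
            continue
        f, threshold, _gain = split
        left_mask = X[idx, f] <= threshold
        node["feature"] = f
        node["threshold"] = threshold
        node["left"] = {}
        node["right"] = {}
        stack.append((node["left"], idx[left_mask], depth + 1))
        stack.append((node["right"], idx[~left_mask], depth + 1))
    return TreeModel(root=root, n_features=X.shape[1], params=params)


def predict_score(model: TreeModel, X: np.ndarray) -> np.ndarray:
    """Route samples to leaves and return the leaf positive-class fractions."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else '?'}"
        )
    scores = np.empty(len(X), dtype=float)
    stack: list[tuple[dict, np.ndarray]] = [(model.root, np.arange(len(X)))]
    while stack:
        node, idx = stack.pop()
        if len(idx) == 0:
            continue
        if "score" in node:
            scores[idx] = node["score"]
            continue
        left = X[idx, node["feature"]] <= node["threshold"]
        stack.append((node["left"], idx[left]))
        stack.append((node["right"], idx[~left]))
    return scores


def predict_label(model: TreeModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard labels from scores: score >= threshold predicts positive."""
    return (predict_score(model, X) >= threshold).astype(int)
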