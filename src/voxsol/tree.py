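"""Regression trees with pluggable split policies.

One tree-growing routine serves all three ensemble flavours; the policy
decides which features are candidates at a node and how cut-points are
proposed:

===============  =====================  ==========================
method           candidate features     cut-points per feature
===============  =====================  ==========================
Bagging          all                    exhaustive (all midpoints)
Random Forest    random subset (mtry)   exhaustive (all midpoints)
Extra Trees      random subset (mtry)   one, uniform in (min, max)
===============  =====================  ==========================

The split criterion is the CART regression standard: maximise the reduction
in sum of squared errors, SSE(parent) - SSE(left) - SSE(right).  Rows route
left iff value <= threshold; exhaustive thresholds are midpoints between
adjacent distinct sorted values, so predictions are invariant to monotone
jitter below the data resolution.

Recursion stops when the node cannot yield two children of at least
``min_node_size`` rows, when the targets are constant, or when no candidate
split has positive gain.  There is no depth limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "CandidateFeatureRule",
    "CutpointRule",
    "SplitPolicy",
    "TreeNode",
    "best_split_exhaustive",
    "fit_tree",
    "predict_tree",
    "tree_feature_sse",
]


class CandidateFeatureRule(Enum):
    ALL = "all"
    RANDOM_SUBSET = "random_subset"


class CutpointRule(Enum):
    EXHAUSTIVE = "exhaustive"
    ONE_RANDOM_PER_FEATURE = "one_random_per_feature"


@dataclass(frozen=True)
class SplitPolicy:
    """How a node chooses its split."""

    candidate_feature_rule: CandidateFeatureRule = CandidateFeatureRule.ALL
    cutpoint_rule: CutpointRule = CutpointRule.EXHAUSTIVE
    mtry: int | None = None  # required for RANDOM_SUBSET

    def validate(self, n_features: int) -> None:
        if self.candidate_feature_rule is CandidateFeatureRule.RANDOM_SUBSET:
            if self.mtry is None or not 1 <= self.mtry <= n_features:
                raise ValueError(
                    f"mtry must be in [1, {n_features}]; got {self.mtry}"
                )


@dataclass
class TreeNode:
    """Either a leaf (prediction = mean target of its training rows) or an
    internal node splitting on ``feature <= threshold``."""

    prediction: float | None = None
    n_rows: int = 0
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_leaves(self) -> int:
        if self.is_leaf:
            return 1
        return self.left.n_leaves() + self.right.n_leaves()

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"leaf": self.prediction, "n": self.n_rows}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "n": self.n_rows,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "leaf" in d:
            return cls(prediction=float(d["leaf"]), n_rows=int(d["n"]))
        return cls(
            n_rows=int(d["n"]),
            feature=int(d["feature"]),
            threshold=float(d["threshold"]),
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


def best_split_exhaustive(x: np.ndarray, y: np.ndarray):
    """Best single-feature split by SSE reduction, or None.

    Scans every midpoint between adjacent distinct sorted values of *x* and
    returns ``(threshold, sse_reduction)`` maximising
    SSE(parent) - SSE(left) - SSE(right); None when *x* is constant or no
    split has positive gain (e.g. constant *y*).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        return None
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    valid = xs[:-1] < xs[1:]  # a threshold exists between positions k-1, k
    if not valid.any():
        return None
    csum = np.cumsum(ys)[:-1]
    k = np.arange(1, n)
    total = csum[-1] + ys[-1]
    with np.errstate(invalid="ignore"):
        red = csum**2 / k + (total - csum) ** 2 / (n - k) - total**2 / n
    red[~valid] = -np.inf
    best = int(np.argmax(red))
    if red[best] <= 0:
        return None
    threshold = 0.5 * (xs[best] + xs[best + 1])
    return float(threshold), float(red[best])


def _best_split_matrix(x: np.ndarray, y: np.ndarray, min_child: int):
    """Vectorised exhaustive split search over the columns of *x*.

    Returns ``(col, threshold, reduction)`` for the best valid split with
    both children >= *min_child* rows and positive gain, else None.  The
    first maximum in (position, column-major) order wins, which is
    deterministic for a fixed candidate-column order.
    """
    n, m = x.shape
    if n < 2 * min_child:
        return None
    order = np.argsort(x, axis=0, kind="stable")
    xs = np.take_along_axis(x, order, axis=0)
    ys = np.take_along_axis(np.broadcast_to(y[:, None], (n, m)), order, axis=0)
    csum = np.cumsum(ys, axis=0)[:-1]
    total = float(y.sum())
    k = np.arange(1, n, dtype=float)[:, None]
    with np.errstate(invalid="ignore"):
        red = csum**2 / k + (total - csum) ** 2 / (n - k) - total**2 / n
    invalid = xs[:-1] >= xs[1:]
    red[invalid] = -np.inf
    if min_child > 1:
        red[: min_child - 1] = -np.inf
        red[n - min_child :] = -np.inf
    flat = int(np.argmax(red))
    r, c = divmod(flat, m)
    if not np.isfinite(red[r, c]) or red[r, c] <= 0:
        return None
    threshold = 0.5 * (xs[r, c] + xs[r + 1, c])
    return c, float(threshold), float(red[r, c])


def _sse_reduction_at(x: np.ndarray, y: np.ndarray, threshold: float) -> float:
    left = x <= threshold
    n_l = int(left.sum())
    n = x.size
    if n_l == 0 or n_l == n:
        return -np.inf
    s_l = float(y[left].sum())
    s = float(y.sum())
    return s_l**2 / n_l + (s - s_l) ** 2 / (n - n_l) - s**2 / n


def _random_cut_split(x: np.ndarray, y: np.ndarray, rng: np.random.Generator,
                      min_child: int):
    """One uniform random cut-point per candidate column; keep the best.

    Cuts are drawn strictly inside (min, max) of the node's values, so both
    children are non-empty by construction.
    """
    n, m = x.shape
    if n < 2 * min_child:
        return None
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    # one draw per column, consumed in column order for reproducibility
    u = rng.random(m)
    best = None
    for c in range(m):
        if hi[c] <= lo[c]:
            continue
        cut = lo[c] + u[c] * (hi[c] - lo[c])
        if not lo[c] < cut < hi[c]:
            continue
        n_left = int((x[:, c] <= cut).sum())
        if n_left < min_child or n - n_left < min_child:
            continue
        red = _sse_reduction_at(x[:, c], y, cut)
        if red > 0 and (best is None or red > best[2]):
            best = (c, float(cut), float(red))
    return best


def fit_tree(
    x: np.ndarray,
    y: np.ndarray,
    policy: SplitPolicy | None = None,
    min_node_size: int = 5,
    rng: np.random.Generator | None = None,
) -> TreeNode:
    """Grow a regression tree on the rows of *x* (n x p) against *y*.

    Deterministic for a given rng state.  ``min_node_size`` bounds the size
    of every leaf; a node is only split when both children would have at
    least that many rows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0 or x.shape[1] == 0:
        raise ValueError("empty table")
    if x.shape[0] != y.shape[0]:
        raise ValueError("row count of x must match y")
    policy = policy or SplitPolicy()
    policy.validate(x.shape[1])
    if min_node_size < 1:
        raise ValueError("min_node_size must be >= 1")
    rng = rng or np.random.default_rng(0)
    return _grow(x, y, policy, min_node_size, rng)


def _grow(x, y, policy, min_node_size, rng) -> TreeNode:
    n, p = x.shape
    node = TreeNode(prediction=float(y.mean()), n_rows=n)
    if n < 2 * min_node_size or np.all(y == y[0]):
        return node

    if policy.candidate_feature_rule is CandidateFeatureRule.RANDOM_SUBSET:
        cols = np.sort(rng.choice(p, size=policy.mtry, replace=False))
    else:
        cols = np.arange(p)

    if policy.cutpoint_rule is CutpointRule.EXHAUSTIVE:
        found = _best_split_matrix(x[:, cols], y, min_node_size)
    else:
        found = _random_cut_split(x[:, cols], y, rng, min_node_size)
    if found is None:
        return node

    c, threshold, _red = found
    feature = int(cols[c])
    mask = x[:, feature] <= threshold
    node.feature = feature
    node.threshold = threshold
    node.left = _grow(x[mask], y[mask], policy, min_node_size, rng)
    node.right = _grow(x[~mask], y[~mask], policy, min_node_size, rng)
    return node


def predict_tree(node: TreeNode, row: np.ndarray) -> float:
    """Route *row* down the tree (left iff value <= threshold) to a leaf mean."""
    row = np.asarray(row, dtype=float)
    while not node.is_leaf:
        if node.feature >= row.size:
            raise ValueError(f"row lacks feature index {node.feature}")
        node = node.left if row[node.feature] <= node.threshold else node.right
    return node.prediction


def predict_tree_matrix(node: TreeNode, x: np.ndarray) -> np.ndarray:
    """Vectorised prediction for every row of *x*."""
    x = np.asarray(x, dtype=float)
    out = np.empty(x.shape[0])
    _predict_into(node, x, np.arange(x.shape[0]), out)
    return out


def _predict_into(node, x, idx, out):
    if node.is_leaf:
        out[idx] = node.prediction
        return
    mask = x[idx, node.feature] <= node.threshold
    _predict_into(node.left, x, idx[mask], out)
    _predict_into(node.right, x, idx[~mask], out)


def tree_feature_sse(node: TreeNode, x: np.ndarray, y: np.ndarray) -> dict[int, float]:
    """Total SSE reduction attributed to each feature across the tree's nodes.

    Recomputes the reduction of each realised split from the training rows
    that reach the node ("node purity" importance contribution).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scores: dict[int, float] = {}
    _accumulate_sse(node, x, y, np.arange(x.shape[0]), scores)
    return scores


def _accumulate_sse(node, x, y, idx, scores):
    if node.is_leaf or idx.size == 0:
        return
    red = _sse_reduction_at(x[idx, node.feature], y[idx], node.threshold)
    if np.isfinite(red):
        scores[node.feature] = scores.get(node.feature, 0.0) + max(red, 0.0)
    mask = x[idx, node.feature] <= node.threshold
    _accumulate_sse(node.left, x, y, idx[mask], scores)
    _accumulate_sse(node.right, x, y, idx[~mask], scores)
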