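"""Bagging, Random Forest and Extra Trees over the shared tree core.

The three ensemble methods are configurations of one fitting routine:

* **Bagging** — bootstrap resample per tree, all features, exhaustive cuts;
  100 trees by default.
* **Random Forest** — bootstrap resample per tree, a random mtry-subset of
  features per node, exhaustive cuts; 1000 trees by default.
* **Extra Trees** — the full training sample per tree (no bootstrap), a
  random mtry-subset per node, one uniform random cut per candidate feature;
  500 trees by default.

Every bootstrap sample draws N of the N training rows with replacement.
Predictions are the unweighted mean of tree predictions, so each prediction
lies within the training target range.  Per-tree random streams are derived
from the master seed by tree index, making the fitted ensemble independent
of tree fitting order.

The statsmodels-style surface is ``TreeEnsemble(x, y, config).fit()``
returning a :class:`TreeEnsembleResults` with predictions, out-of-bag error
and feature importances; :func:`fit_ensemble` / :func:`predict_ensemble` are
the equivalent functional entry points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from .data import DescriptorTable
from .tree import (
    CandidateFeatureRule,
    CutpointRule,
    SplitPolicy,
    TreeNode,
    fit_tree,
    predict_tree_matrix,
    tree_feature_sse,
)

__all__ = [
    "EnsembleMethod",
    "EnsembleConfig",
    "TrainedEnsemble",
    "TreeEnsemble",
    "TreeEnsembleResults",
    "OOBResult",
    "fit_ensemble",
    "predict_ensemble",
    "oob_error",
    "feature_importance",
]


class EnsembleMethod(Enum):
    BAGGING = "bagging"
    RANDOM_FOREST = "random_forest"
    EXTRA_TREES = "extra_trees"


#: default forest sizes per method
DEFAULT_N_TREES = {
    EnsembleMethod.BAGGING: 100,
    EnsembleMethod.RANDOM_FOREST: 1000,
    EnsembleMethod.EXTRA_TREES: 500,
}


@dataclass(frozen=True)
class EnsembleConfig:
    method: EnsembleMethod
    n_trees: int | None = None
    mtry: int | None = None
    min_node_size: int = 5
    seed: int = 0

    def resolved(self, n_features: int) -> "EnsembleConfig":
        """Fill method-dependent defaults for a given feature count.

        mtry defaults follow the regression conventions of the canonical
        implementations: floor(p/3) for Random Forest, ceil(p/3) for Extra
        Trees (minimum 1); Bagging always uses all features.
        """
        n_trees = self.n_trees if self.n_trees is not None else DEFAULT_N_TREES[self.method]
        mtry = self.mtry
        if self.method is EnsembleMethod.BAGGING:
            mtry = n_features
        elif mtry is None:
            if self.method is EnsembleMethod.RANDOM_FOREST:
                mtry = max(1, n_features // 3)
            else:
                mtry = max(1, -(-n_features // 3))
        return replace(self, n_trees=n_trees, mtry=mtry)

    @property
    def bootstrap(self) -> bool:
        return self.method is not EnsembleMethod.EXTRA_TREES

    def policy(self, n_features: int) -> SplitPolicy:
        if self.method is EnsembleMethod.BAGGING:
            return SplitPolicy(CandidateFeatureRule.ALL, CutpointRule.EXHAUSTIVE)
        if self.method is EnsembleMethod.RANDOM_FOREST:
            return SplitPolicy(
                CandidateFeatureRule.RANDOM_SUBSET, CutpointRule.EXHAUSTIVE, self.mtry
            )
        return SplitPolicy(
            CandidateFeatureRule.RANDOM_SUBSET,
            CutpointRule.ONE_RANDOM_PER_FEATURE,
            self.mtry,
        )


def _tree_rng(seed: int, tree_index: int) -> np.random.Generator:
    # independent per-tree PCG64 stream; reproducible under any fit order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(tree_index,)))


@dataclass
class TrainedEnsemble:
    """A fitted forest: trees, per-tree bootstrap indices, config, features."""

    config: EnsembleConfig
    trees: list[TreeNode]
    bootstrap_indices: list[np.ndarray] | None
    feature_names: list[str]
    y_train_min: float
    y_train_max: float

    def to_dict(self) -> dict:
        return {
            "method": self.config.method.value,
            "n_trees": self.config.n_trees,
            "mtry": self.config.mtry,
            "min_node_size": self.config.min_node_size,
            "seed": self.config.seed,
            "feature_names": self.feature_names,
            "y_train_min": self.y_train_min,
            "y_train_max": self.y_train_max,
            "bootstrap_indices": (
                None
                if self.bootstrap_indices is None
                else [idx.tolist() for idx in self.bootstrap_indices]
            ),
            "trees": [t.to_dict() for t in self.trees],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedEnsemble":
        cfg = EnsembleConfig(
            method=EnsembleMethod(d["method"]),
            n_trees=d["n_trees"],
            mtry=d["mtry"],
            min_node_size=d["min_node_size"],
            seed=d["seed"],
        )
        boot = d["bootstrap_indices"]
        return cls(
            config=cfg,
            trees=[TreeNode.from_dict(t) for t in d["trees"]],
            bootstrap_indices=None if boot is None else [np.array(b) for b in boot],
            feature_names=list(d["feature_names"]),
            y_train_min=float(d["y_train_min"]),
            y_train_max=float(d["y_train_max"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path) -> "TrainedEnsemble":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_matrix(table, feature_names=None):
    if isinstance(table, DescriptorTable):
        if feature_names is not None:
            missing = [f for f in feature_names if f not in set(table.feature_names)]
            if missing:
                raise ValueError(f"table lacks feature {missing[0]!r}")
            return table.frame[feature_names].to_numpy()
        return table.values, table.feature_names
    x = np.asarray(table, dtype=float)
    if feature_names is not None:
        if x.shape[1] != len(feature_names):
            raise ValueError(
                f"expected {len(feature_names)} features, got {x.shape[1]}"
            )
        return x
    return x, [f"f{i}" for i in range(x.shape[1])]


def fit_ensemble(table, y, config: EnsembleConfig) -> TrainedEnsemble:
    """Fit a tree ensemble on the (complete, unscaled) descriptor table."""
    x, names = _as_matrix(table)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    cfg = config.resolved(p)
    if cfg.n_trees < 1:
        raise ValueError(f"n_trees must be >= 1; got {cfg.n_trees}")
    if cfg.mtry > p:
        raise ValueError(f"mtry {cfg.mtry} exceeds feature count {p}")
    policy = cfg.policy(p)

    trees: list[TreeNode] = []
    boots: list[np.ndarray] | None = [] if cfg.bootstrap else None
    for t in range(cfg.n_trees):
        rng = _tree_rng(cfg.seed, t)
        if cfg.bootstrap:
            idx = rng.integers(0, n, size=n)
            boots.append(idx)
            xt, yt = x[idx], y[idx]
        else:
            xt, yt = x, y
        trees.append(fit_tree(xt, yt, policy, cfg.min_node_size, rng))
    return TrainedEnsemble(
        config=cfg,
        trees=trees,
        bootstrap_indices=boots,
        feature_names=list(names),
        y_train_min=float(y.min()),
        y_train_max=float(y.max()),
    )


def predict_ensemble(model: TrainedEnsemble, table) -> np.ndarray:
    """Per-row unweighted mean of the tree predictions."""
    x = _as_matrix(table, model.feature_names)
    preds = np.zeros(x.shape[0])
    for tree in model.trees:
        preds += predict_tree_matrix(tree, x)
    return preds / len(model.trees)


@dataclass
class OOBResult:
    rmse: float  # NaN when no row is out-of-bag
    n_oob: int
    n_skipped: int
    predictions: np.ndarray | None = None


def oob_error(model: TrainedEnsemble, table, y) -> OOBResult:
    """Out-of-bag RMSE: each training row predicted only by the trees whose
    bootstrap sample excluded it.  Rows never out-of-bag are skipped and
    counted.  Only defined for bootstrap methods."""
    if model.bootstrap_indices is None:
        raise ValueError("out-of-bag error is undefined without bootstrap sampling")
    x = _as_matrix(table, model.feature_names)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=int)
    for tree, idx in zip(model.trees, model.bootstrap_indices):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        oob = ~in_bag
        if not oob.any():
            continue
        sums[oob] += predict_tree_matrix(tree, x[oob])
        counts[oob] += 1
    covered = counts > 0
    n_oob = int(covered.sum())
    preds = np.full(n, np.nan)
    if n_oob:
        preds[covered] = sums[covered] / counts[covered]
        rmse = float(np.sqrt(np.mean((preds[covered] - y[covered]) ** 2)))
    else:
        rmse = float("nan")
    return OOBResult(rmse=rmse, n_oob=n_oob, n_skipped=n - n_oob, predictions=preds)


def _trees_features(model: TrainedEnsemble) -> list[set[int]]:
    used = []
    for tree in model.trees:
        s: set[int] = set()
        stack = [tree]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                s.add(node.feature)
                stack.extend((node.left, node.right))
        used.append(s)
    return used


def feature_importance(
    model: TrainedEnsemble, table, y, seed: int = 0
) -> "pd.DataFrame":
    """Permutation and node-purity importance per descriptor.

    * permutation: mean increase in a tree's out-of-bag MSE after permuting
      the feature's values among that tree's out-of-bag rows (bootstrap
      methods; NaN otherwise);
    * purity: total SSE reduction attributed to the feature across all
      nodes of all trees.
    Features a tree never splits on contribute exactly zero to both scores
    for that tree.
    """
    import pandas as pd

    x = _as_matrix(table, model.feature_names)
    y = np.asarray(y, dtype=float)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    used = _trees_features(model)

    # purity is accumulated over each tree's own training rows
    purity = np.zeros(p)
    for t, tree in enumerate(model.trees):
        if model.bootstrap_indices is not None:
            idx = model.bootstrap_indices[t]
            xt, yt = x[idx], y[idx]
        else:
            xt, yt = x, y
        for feat, score in tree_feature_sse(tree, xt, yt).items():
            purity[feat] += score

    permutation = np.full(p, np.nan)
    if model.bootstrap_indices is not None:
        permutation = np.zeros(p)
        contrib = np.zeros(p, dtype=int)
        for t, tree in enumerate(model.trees):
            in_bag = np.zeros(n, dtype=bool)
            in_bag[model.bootstrap_indices[t]] = True
            oob = np.where(~in_bag)[0]
            if oob.size == 0:
                continue
            base = predict_tree_matrix(tree, x[oob])
            base_mse = np.mean((base - y[oob]) ** 2)
            for feat in range(p):
                contrib[feat] += 1
                if feat not in used[t]:
                    continue  # permuting an unused feature leaves the tree unchanged
                perm = rng.permutation(oob.size)
                xp = x[oob].copy()
                xp[:, feat] = xp[perm, feat]
                mse = np.mean((predict_tree_matrix(tree, xp) - y[oob]) ** 2)
                permutation[feat] += mse - base_mse
            del base
        with np.errstate(invalid="ignore"):
            permutation = np.where(contrib > 0, permutation / np.maximum(contrib, 1), np.nan)

    return pd.DataFrame(
        {"permutation": permutation, "purity": purity},
        index=pd.Index(model.feature_names, name="feature"),
    )


# ---------------------------------------------------------------------------
# Model / Results surface


class TreeEnsemble:
    """Tree-ensemble regression model for logS prediction.

    Parameters
    ----------
    table
        Complete numeric descriptor table (``DescriptorTable`` or array),
        conventionally the unpruned, unscaled representation.
    y
        Training logS values aligned with the table rows (or None when the
        table is a ``DescriptorTable`` and *target* is given).
    config
        Method and hyperparameters; see :class:`EnsembleConfig`.
    """

    def __init__(self, table, y, config: EnsembleConfig):
        self.table = table
        self.y = np.asarray(y, dtype=float)
        self.config = config

    @classmethod
    def from_dataframe(cls, frame, target_column: str, config: EnsembleConfig):
        y = frame[target_column].to_numpy(dtype=float)
        x = DescriptorTable(frame.drop(columns=[target_column]))
        return cls(x, y, config)

    def fit(self) -> "TreeEnsembleResults":
        trained = fit_ensemble(self.table, self.y, self.config)
        return TreeEnsembleResults(self, trained)


class TreeEnsembleResults:
    """Fitted ensemble with prediction, OOB diagnostics and importances."""

    def __init__(self, model: TreeEnsemble, trained: TrainedEnsemble):
        self.model = model
        self.trained = trained

    def predict(self, table) -> np.ndarray:
        return predict_ensemble(self.trained, table)

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.table)

    def oob(self) -> OOBResult:
        return oob_error(self.trained, self.model.table, self.model.y)

    def importances(self, seed: int = 0):
        return feature_importance(self.trained, self.model.table, self.model.y, seed)

    def summary(self) -> str:
        cfg = self.trained.config
        lines = [
            "Tree ensemble regression results",
            "=" * 40,
            f"method:        {cfg.method.value}",
            f"n_trees:       {cfg.n_trees}",
            f"mtry:          {cfg.mtry}",
            f"min_node_size: {cfg.min_node_size}",
            f"bootstrap:     {cfg.bootstrap}",
            f"seed:          {cfg.seed}",
            f"n_train:       {len(self.model.y)}",
            f"n_features:    {len(self.trained.feature_names)}",
        ]
        if cfg.bootstrap:
            res = self.oob()
            lines.append(f"OOB RMSE:      {res.rmse:.3f} (n_oob={res.n_oob})")
        return "\n".join(lines)
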