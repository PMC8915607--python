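"""k-nearest-neighbour solubility regression on scaled descriptors.

Four variants: Euclidean or Manhattan distance, each either unweighted
(simple mean of the k nearest training logS values) or exponentially
weighted towards closer neighbours, w_j = exp(-d_j / h).  The bandwidth h
defaults to the mean distance to the query's k neighbours, which makes the
weights scale-free; as h grows the weighted mean converges to the
unweighted one.

Distances are only meaningful on descriptors passed through the full
cleaning pipeline (correlation-pruned and min-max scaled to [0, 1]), so
every dimension contributes comparably.

The neighbour count k is chosen by leave-one-out cross-validation over the
training set (the held-out compound is excluded from its own neighbour
list), scanning k = 2..8 by default and breaking RMSE ties toward the
smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .data import DescriptorTable

__all__ = [
    "Metric",
    "Weighting",
    "KnnConfig",
    "knn_predict",
    "knn_predict_batch",
    "select_k_loocv",
    "KNNRegressor",
    "KNNResults",
]


class Metric(Enum):
    EUCLIDEAN = "euclidean"
    MANHATTAN = "manhattan"


class Weighting(Enum):
    UNWEIGHTED = "unweighted"
    EXPONENTIAL = "exponential"


@dataclass(frozen=True)
class KnnConfig:
    metric: Metric = Metric.EUCLIDEAN
    weighting: Weighting = Weighting.UNWEIGHTED
    k: int = 4
    bandwidth: float | None = None  # None: mean distance to the k neighbours

    def __post_init__(self):
        if self.k < 1:
            raise ValueError(f"k must be >= 1; got {self.k}")


def _as_array(table) -> np.ndarray:
    if isinstance(table, DescriptorTable):
        return table.values
    return np.atleast_2d(np.asarray(table, dtype=float))


def _distances(queries: np.ndarray, train: np.ndarray, metric: Metric) -> np.ndarray:
    name = "euclidean" if metric is Metric.EUCLIDEAN else "cityblock"
    return cdist(queries, train, metric=name)


def _aggregate(d_row: np.ndarray, y: np.ndarray, config: KnnConfig) -> float:
    """Combine neighbour targets for one query given its training distances.

    Neighbours tied with the k-th distance are all included, and the
    (possibly weighted) mean runs over the expanded set — deterministic
    regardless of training order.
    """
    n = d_row.size
    if config.k > n:
        raise ValueError(f"k={config.k} exceeds {n} training compounds")
    order = np.argsort(d_row, kind="stable")
    kth = d_row[order[config.k - 1]]
    take = order[: config.k]
    extra = order[config.k :][d_row[order[config.k :]] == kth]
    idx = np.concatenate([take, extra]) if extra.size else take
    d_sel, y_sel = d_row[idx], y[idx]
    if config.weighting is Weighting.UNWEIGHTED:
        return float(y_sel.mean())
    h = config.bandwidth if config.bandwidth is not None else float(d_sel.mean())
    if h == 0.0:  # all selected neighbours coincide with the query
        return float(y_sel.mean())
    w = np.exp(-d_sel / h)
    return float(np.sum(w * y_sel) / np.sum(w))


def knn_predict(query_row, train_table, y, config: KnnConfig) -> float:
    """Predict logS for a single query compound."""
    train = _as_array(train_table)
    q = np.asarray(query_row, dtype=float).reshape(1, -1)
    y = np.asarray(y, dtype=float)
    d = _distances(q, train, config.metric)[0]
    return _aggregate(d, y, config)


def knn_predict_batch(query_table, train_table, y, config: KnnConfig) -> np.ndarray:
    """Vectorised prediction for every row of *query_table*."""
    train = _as_array(train_table)
    queries = _as_array(query_table)
    y = np.asarray(y, dtype=float)
    d = _distances(queries, train, config.metric)
    return np.array([_aggregate(row, y, config) for row in d])


def loocv_rmse(train_table, y, config: KnnConfig) -> float:
    """Leave-one-out RMSE over the training set for a fixed configuration."""
    train = _as_array(train_table)
    y = np.asarray(y, dtype=float)
    n = train.shape[0]
    if config.k > n - 1:
        raise ValueError(f"k={config.k} needs at least {config.k + 1} training rows")
    d = _distances(train, train, config.metric)
    errs = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        errs[i] = _aggregate(d[i, mask], y[mask], config) - y[i]
        mask[i] = True
    return float(np.sqrt(np.mean(errs**2)))


def select_k_loocv(
    train_table,
    y,
    metric: Metric,
    weighting: Weighting,
    k_range=range(2, 9),
    bandwidth: float | None = None,
) -> tuple[int, dict[int, float]]:
    """Choose k minimising LOOCV RMSE; ties go to the smaller k.

    Returns the selected k and the per-k RMSE table.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks:
        raise ValueError("k_range is empty")
    table_rmse: dict[int, float] = {}
    for k in ks:
        cfg = KnnConfig(metric=metric, weighting=weighting, k=k, bandwidth=bandwidth)
        table_rmse[k] = loocv_rmse(train_table, y, cfg)
    best = min(ks, key=lambda k: (table_rmse[k], k))
    return best, table_rmse


class KNNRegressor:
    """kNN solubility model; ``fit()`` runs the LOOCV selection of k.

    Expects descriptors already passed through the cleaning pipeline
    (pruned, scaled); the class does not re-scale.
    """

    def __init__(
        self,
        table,
        y,
        config: KnnConfig = KnnConfig(),
        k_range=range(2, 9),
    ):
        self.table = table
        self.y = np.asarray(y, dtype=float)
        self.config = config
        self.k_range = k_range

    def fit(self, select_k: bool = True) -> "KNNResults":
        if select_k:
            k_star, rmse_by_k = select_k_loocv(
                self.table,
                self.y,
                self.config.metric,
                self.config.weighting,
                self.k_range,
                self.config.bandwidth,
            )
            cfg = replace(self.config, k=k_star)
        else:
            cfg = self.config
            rmse_by_k = {cfg.k: loocv_rmse(self.table, self.y, cfg)}
        return KNNResults(self, cfg, rmse_by_k)


class KNNResults:
    def __init__(self, model: KNNRegressor, config: KnnConfig, loocv_rmse_by_k):
        self.model = model
        self.config = config
        self.loocv_rmse_by_k = dict(loocv_rmse_by_k)

    @property
    def k(self) -> int:
        return self.config.k

    @property
    def loocv_rmse(self) -> float:
        return self.loocv_rmse_by_k[self.config.k]

    def predict(self, table) -> np.ndarray:
        return knn_predict_batch(table, self.model.table, self.model.y, self.config)

    def summary(self) -> str:
        lines = [
            "kNN regression results",
            "=" * 40,
            f"metric:    {self.config.metric.value}",
            f"weighting: {self.config.weighting.value}",
            f"selected k: {self.config.k}",
            "LOOCV RMSE by k:",
        ]
        for k in sorted(self.loocv_rmse_by_k):
            marker = " *" if k == self.config.k else ""
            lines.append(f"  k={k}: {self.loocv_rmse_by_k[k]:.3f}{marker}")
        return "\n".join(lines)
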