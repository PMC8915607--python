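"""Leakage-safe descriptor curation.

The cleaning pipeline applied to raw descriptor exports, in fixed order:

1. drop any descriptor with an undefined (missing) value for any compound;
2. drop zero-variance descriptors (variance computed on training rows only,
   when a split is supplied);
3. optionally prune correlated pairs: whenever two descriptors have
   |Pearson r| > 0.8 over the training rows, keep the one whose |r| with the
   logS target is larger;
4. min-max scale each descriptor to [0, 1] using training-set bounds only,
   so validation/test values never leak into model construction (they may
   legitimately fall outside [0, 1] and are not clipped).

Tree ensembles are robust to redundant descriptors and consume the unpruned,
unscaled table; steps 3-4 serve the distance- and kernel-based models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import DescriptorTable, SolubilitySet

__all__ = [
    "ScalingBounds",
    "PruneAudit",
    "drop_incomplete_features",
    "drop_zero_variance",
    "correlation_prune",
    "fit_scaler",
    "apply_scaler",
    "unscale",
    "FeaturePipeline",
]


class PipelineError(ValueError):
    pass


@dataclass(frozen=True)
class ScalingBounds:
    """Per-feature training-set minimum and maximum for min-max scaling."""

    minima: pd.Series
    maxima: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.minima.index)


@dataclass
class PrunedPair:
    kept: str
    dropped: str
    r_between: float
    r_kept_target: float
    r_dropped_target: float
    tie: bool = False


@dataclass
class PruneAudit:
    """Ordered record of correlation-prune decisions."""

    pairs: list[PrunedPair] = field(default_factory=list)

    @property
    def dropped_features(self) -> list[str]:
        return [p.dropped for p in self.pairs]

    def __len__(self) -> int:
        return len(self.pairs)


def _train_rows(table: DescriptorTable, train_ids) -> pd.DataFrame:
    if train_ids is None:
        return table.frame
    return table.frame.loc[list(train_ids)]


def drop_incomplete_features(table: DescriptorTable) -> tuple[DescriptorTable, list[str]]:
    """Remove every descriptor with a missing value for any compound.

    Returns the reduced table and the removed feature names.  Raises if no
    usable descriptor survives.
    """
    missing = table.frame.isna().any(axis=0)
    removed = list(table.frame.columns[missing])
    kept = [f for f in table.feature_names if f not in set(removed)]
    if not kept:
        raise PipelineError("all descriptors have undefined values; nothing usable")
    return table.select_features(kept), removed


def drop_zero_variance(
    table: DescriptorTable, train_ids=None
) -> tuple[DescriptorTable, list[str]]:
    """Remove descriptors with zero sample variance.

    Variance is computed over the training rows when ``train_ids`` is given,
    so a feature constant on the test rows but varying in training survives.
    """
    sub = _train_rows(table, train_ids)
    if sub.isna().to_numpy().any():
        raise PipelineError("zero-variance filter requires a complete table")
    # max == min is an exact zero-variance test, immune to the rounding a
    # naive variance of a constant column can accumulate
    spread = sub.max(axis=0) - sub.min(axis=0)
    removed = list(spread.index[spread.to_numpy() == 0.0])
    kept = [f for f in table.feature_names if f not in set(removed)]
    return table.select_features(kept), removed


def _pearson_matrix(values: np.ndarray) -> np.ndarray:
    # np.corrcoef on columns; constant columns must be removed beforehand
    return np.corrcoef(values, rowvar=False)


def correlation_prune(
    table: DescriptorTable,
    target: SolubilitySet,
    threshold: float = 0.8,
    train_ids=None,
) -> tuple[DescriptorTable, PruneAudit]:
    """Prune one member of every descriptor pair with |Pearson r| > threshold.

    The survivor of each pair is the descriptor with the larger absolute
    Pearson correlation with the logS target over the training rows (ties
    keep the lexicographically first name and are flagged in the audit).
    Pairs are processed greedily in descending |r| (ties broken by the
    lexicographic feature-name pair) so the result does not depend on input
    column order; pairs whose loser was already dropped are skipped.
    """
    if not 0.0 < threshold <= 1.0:
        raise PipelineError(f"threshold must be in (0, 1]; got {threshold}")
    sub = _train_rows(table, train_ids)
    names = list(sub.columns)
    x = sub.to_numpy()
    if np.isnan(x).any():
        raise PipelineError("correlation pruning requires a complete table")
    y = target.series.loc[sub.index].to_numpy()

    corr = _pearson_matrix(x)
    with np.errstate(invalid="ignore"):
        sx = x.std(axis=0, ddof=0)
        if (sx == 0).any():
            raise PipelineError("constant feature present; run drop_zero_variance first")
        r_target = ((x - x.mean(0)) * (y - y.mean())[:, None]).mean(0) / (sx * y.std(ddof=0))
    abs_rt = np.abs(r_target)

    p = len(names)
    candidates = [
        (abs(corr[i, j]), names[i], names[j], i, j)
        for i, j in itertools.combinations(range(p), 2)
        if abs(corr[i, j]) > threshold
    ]
    # descending |r|, lexicographic name pair for deterministic tie order
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))

    dropped: set[str] = set()
    audit = PruneAudit()
    for r_ij, ni, nj, i, j in candidates:
        if ni in dropped or nj in dropped:
            continue
        tie = bool(np.isclose(abs_rt[i], abs_rt[j]))
        if tie:
            keep, drop = sorted((ni, nj))
        elif abs_rt[i] > abs_rt[j]:
            keep, drop = ni, nj
        else:
            keep, drop = nj, ni
        k_idx, d_idx = names.index(keep), names.index(drop)
        audit.pairs.append(
            PrunedPair(keep, drop, float(r_ij), float(abs_rt[k_idx]), float(abs_rt[d_idx]), tie)
        )
        dropped.add(drop)

    kept = [f for f in table.feature_names if f not in dropped]
    return table.select_features(kept), audit


def fit_scaler(table: DescriptorTable, train_ids=None) -> ScalingBounds:
    """Compute per-feature min/max over the training rows only.

    A feature with MAX == MIN signals that the zero-variance filter was
    skipped and raises.
    """
    sub = _train_rows(table, train_ids)
    if sub.isna().to_numpy().any():
        raise PipelineError("scaler requires a complete table")
    lo, hi = sub.min(axis=0), sub.max(axis=0)
    flat = lo.index[(hi - lo).to_numpy() == 0.0]
    if len(flat):
        raise PipelineError(
            f"feature {flat[0]!r} is constant over the training rows; "
            "apply the zero-variance filter first"
        )
    return ScalingBounds(minima=lo.astype(float), maxima=hi.astype(float))


def apply_scaler(table: DescriptorTable, bounds: ScalingBounds) -> DescriptorTable:
    """Affine map value -> (value - MIN) / (MAX - MIN), per feature.

    Training values land in [0, 1]; validation/test values may fall outside
    and are deliberately not clipped.
    """
    missing = [f for f in table.feature_names if f not in set(bounds.feature_names)]
    if missing:
        raise PipelineError(f"no scaling bounds for feature {missing[0]!r}")
    lo = bounds.minima[table.feature_names]
    hi = bounds.maxima[table.feature_names]
    scaled = (table.frame - lo) / (hi - lo)
    return DescriptorTable(scaled, dict(table.provenance))


def unscale(table: DescriptorTable, bounds: ScalingBounds) -> DescriptorTable:
    """Inverse of :func:`apply_scaler`."""
    lo = bounds.minima[table.feature_names]
    hi = bounds.maxima[table.feature_names]
    return DescriptorTable(table.frame * (hi - lo) + lo, dict(table.provenance))


@dataclass
class FeaturePipeline:
    """Fitted cleaning pipeline: incomplete -> zero-variance -> prune -> scale.

    ``fit`` learns everything from the training rows; ``transform`` applies
    the learned feature selection and scaling to any table sharing the raw
    feature space (the leakage-safe path for validation/test descriptors).
    """

    threshold: float = 0.8
    prune: bool = True
    scale: bool = True

    removed_incomplete: list[str] = field(default_factory=list)
    removed_zero_variance: list[str] = field(default_factory=list)
    audit: PruneAudit | None = None
    bounds: ScalingBounds | None = None
    kept_features: list[str] | None = None

    def fit(
        self,
        table: DescriptorTable,
        target: SolubilitySet | None = None,
        train_ids=None,
    ) -> "FeaturePipeline":
        work, self.removed_incomplete = drop_incomplete_features(table)
        work, self.removed_zero_variance = drop_zero_variance(work, train_ids)
        if self.prune:
            if target is None:
                raise PipelineError("correlation pruning requires the logS target")
            work, self.audit = correlation_prune(work, target, self.threshold, train_ids)
        if self.scale:
            self.bounds = fit_scaler(work, train_ids)
        self.kept_features = work.feature_names
        return self

    def transform(self, table: DescriptorTable) -> DescriptorTable:
        if self.kept_features is None:
            raise PipelineError("pipeline not fitted")
        work = table.select_features(
            [f for f in self.kept_features if f in set(table.feature_names)]
        )
        if work.feature_names != self.kept_features:
            missing = set(self.kept_features) - set(work.feature_names)
            raise PipelineError(f"table lacks fitted feature {sorted(missing)[0]!r}")
        if self.scale:
            work = apply_scaler(work, self.bounds)
        return work

    def fit_transform(
        self,
        table: DescriptorTable,
        target: SolubilitySet | None = None,
        train_ids=None,
    ) -> DescriptorTable:
        return self.fit(table, target, train_ids).transform(table)
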