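"""Vox Machinarum: median-of-models consensus prediction.

A "wisdom of crowds" combination: for each compound, take the median of an
odd number m of individual model predictions.  Crowd membership and size
are chosen on an internal validation set — models are ranked by their
individual validation RMSE (ties broken by AAE, then name), candidate crowd
sizes m in {3, 5, 7, 9} are scored as the validation RMSE of the top-m
median, and the smallest-RMSE size wins (ties to smaller m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import evaluate

__all__ = [
    "PredictionPanel",
    "ConsensusModel",
    "vox_predict",
    "select_consensus",
    "median_membership_census",
    "VoxMachinarum",
    "ConsensusResults",
]

logger = logging.getLogger(__name__)

DEFAULT_SIZES = (3, 5, 7, 9)


@dataclass
class PredictionPanel:
    """Complete compounds x models matrix of logS predictions."""

    frame: pd.DataFrame  # index: compound ids, columns: model names

    def __post_init__(self):
        if self.frame.columns.has_duplicates:
            raise ValueError("model names must be unique")
        if self.frame.isna().to_numpy().any():
            raise ValueError("panel must be complete: every model predicts every compound")
        self.frame = self.frame.astype(float)

    @classmethod
    def from_dict(cls, predictions: dict[str, dict | pd.Series]) -> "PredictionPanel":
        return cls(pd.DataFrame(predictions))

    @property
    def model_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)


@dataclass(frozen=True)
class ConsensusModel:
    """Chosen crowd: ordered member names plus the median combination rule."""

    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) % 2 == 0:
            raise ValueError("crowd size must be odd")

    @property
    def m(self) -> int:
        return len(self.members)


def vox_predict(panel: PredictionPanel, members) -> pd.Series:
    """Per-compound median over an odd set of member models.

    The output is bracketed by the member predictions:
    min <= median <= max for every compound.
    """
    members = list(members)
    if len(members) % 2 == 0:
        raise ValueError(f"crowd size must be odd; got {len(members)}")
    missing = [m for m in members if m not in set(panel.model_names)]
    if missing:
        raise ValueError(f"model {missing[0]!r} not in panel")
    sub = panel.frame[members]
    return pd.Series(np.median(sub.to_numpy(), axis=1), index=sub.index, name="vox")


def rank_models(panel: PredictionPanel, truth) -> pd.DataFrame:
    """Rank panel models by validation RMSE (ties: AAE, then name)."""
    truth = pd.Series(truth).astype(float)
    rows = []
    for name in panel.model_names:
        rep = evaluate(panel.frame[name], truth)
        rows.append({"model": name, "rmse": rep.rmse, "aae": rep.aae})
    ranking = pd.DataFrame(rows).sort_values(
        by=["rmse", "aae", "model"], kind="stable"
    )
    return ranking.reset_index(drop=True)


def select_consensus(
    validation_panel: PredictionPanel,
    validation_truth,
    sizes=DEFAULT_SIZES,
) -> tuple[ConsensusModel, dict[int, float]]:
    """Choose the crowd on the validation set.

    Members for each candidate size m are the top-m models by individual
    validation RMSE; each candidate crowd is scored by the validation RMSE
    of its median prediction.  Smallest RMSE wins; ties go to the smaller m.
    Candidate sizes larger than the available panel are dropped with a
    warning.
    """
    truth = pd.Series(validation_truth).astype(float)
    ranking = rank_models(validation_panel, truth)
    n_models = len(ranking)
    usable = sorted(m for m in sizes if m <= n_models)
    dropped = sorted(set(sizes) - set(usable))
    if dropped:
        logger.warning(
            "panel has only %d models; dropping crowd sizes %s", n_models, dropped
        )
    if not usable:
        raise ValueError(f"panel has {n_models} models; none of the sizes {sizes} fit")
    rmse_by_size: dict[int, float] = {}
    for m in usable:
        members = tuple(ranking["model"].iloc[:m])
        med = vox_predict(validation_panel, members)
        rmse_by_size[m] = evaluate(med, truth).rmse
    best = min(usable, key=lambda m: (rmse_by_size[m], m))
    chosen = ConsensusModel(tuple(ranking["model"].iloc[:best]))
    return chosen, rmse_by_size


def median_membership_census(
    panel: PredictionPanel, members, reference_member: str
) -> int:
    """Count compounds where the reference model's prediction is the crowd
    median (ties count for the reference if it attains the median value).
    Defined for three-member crowds."""
    members = list(members)
    if len(members) != 3:
        raise ValueError("census is defined for three-member crowds")
    if reference_member not in members:
        raise ValueError(f"{reference_member!r} is not a crowd member")
    sub = panel.frame[members].to_numpy()
    med = np.median(sub, axis=1)
    ref = panel.frame[reference_member].to_numpy()
    return int(np.sum(ref == med))


class VoxMachinarum:
    """Consensus model over a validation panel; ``fit()`` runs selection."""

    def __init__(self, validation_panel: PredictionPanel, validation_truth, sizes=DEFAULT_SIZES):
        self.panel = validation_panel
        self.truth = pd.Series(validation_truth).astype(float)
        self.sizes = tuple(sizes)

    def fit(self) -> "ConsensusResults":
        chosen, rmse_by_size = select_consensus(self.panel, self.truth, self.sizes)
        return ConsensusResults(self, chosen, rmse_by_size)


class ConsensusResults:
    def __init__(self, model: VoxMachinarum, chosen: ConsensusModel, rmse_by_size):
        self.model = model
        self.consensus = chosen
        self.validation_rmse_by_size = dict(rmse_by_size)

    @property
    def members(self) -> tuple[str, ...]:
        return self.consensus.members

    @property
    def m(self) -> int:
        return self.consensus.m

    def predict(self, panel: PredictionPanel) -> pd.Series:
        return vox_predict(panel, self.members)

    def summary(self) -> str:
        lines = [
            "Vox Machinarum consensus results",
            "=" * 40,
            "validation RMSE by crowd size:",
        ]
        for m in sorted(self.validation_rmse_by_size):
            marker = " *" if m == self.m else ""
            lines.append(f"  m={m}: {self.validation_rmse_by_size[m]:.3f}{marker}")
        lines.append(f"members: {', '.join(self.members)}")
        return "\n".join(lines)
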