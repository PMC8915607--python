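"""Domain containers and CSV I/O for descriptor matrices and solubility data.

The package works with three plain containers:

``DescriptorTable``
    a compounds-by-features numeric matrix of molecular descriptors
    (e.g. CDK descriptor exports), missing values allowed until cleaned;
``SolubilitySet``
    one intrinsic aqueous solubility value (logS, log10 mol/L) per compound,
    with a free-text source label;
``DatasetSplit``
    disjoint train / validation / test identifier sets.

CSV dialects follow RFC 4180 with a header row; missing descriptor cells may
be empty or ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DescriptorTable",
    "SolubilitySet",
    "DatasetSplit",
    "read_descriptor_csv",
    "write_descriptor_csv",
    "read_solubility_csv",
    "write_solubility_csv",
    "remove_overlap",
    "split_train_validation",
]

#: tokens accepted as "missing" in descriptor CSV cells
MISSING_TOKENS = ("", "NA")


class DataError(ValueError):
    """Raised for malformed input tables (duplicate ids, non-numeric cells...)."""


@dataclass
class DescriptorTable:
    """Compound x feature matrix of numeric molecular descriptors.

    Parameters
    ----------
    frame
        DataFrame indexed by unique compound identifiers, one numeric column
        per descriptor.  NaN marks a missing value (permitted before the
        cleaning pipeline has run).
    provenance
        Optional per-feature free-text tag (e.g. the computing toolkit).
    """

    frame: pd.DataFrame
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.frame.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise DataError(f"duplicate compound id: {dup!r}")
        if self.frame.columns.has_duplicates:
            dup = self.frame.columns[self.frame.columns.duplicated()][0]
            raise DataError(f"duplicate feature name: {dup!r}")
        self.frame = self.frame.astype(float)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()

    @property
    def n_compounds(self) -> int:
        return self.frame.shape[0]

    @property
    def n_features(self) -> int:
        return self.frame.shape[1]

    def n_missing(self) -> int:
        return int(self.frame.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing() == 0

    def select_rows(self, ids) -> "DescriptorTable":
        return DescriptorTable(self.frame.loc[list(ids)], dict(self.provenance))

    def select_features(self, names) -> "DescriptorTable":
        return DescriptorTable(
            self.frame[list(names)],
            {k: v for k, v in self.provenance.items() if k in set(names)},
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DescriptorTable({self.n_compounds} compounds x "
            f"{self.n_features} features, {self.n_missing()} missing)"
        )


@dataclass
class SolubilitySet:
    """Mapping compound id -> intrinsic solubility logS (log10 mol/L)."""

    series: pd.Series
    source_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.series.index.has_duplicates:
            dup = self.series.index[self.series.index.duplicated()][0]
            raise DataError(f"duplicate compound id: {dup!r}")
        self.series = self.series.astype(float)
        bad = self.series.index[~np.isfinite(self.series.to_numpy())]
        if len(bad):
            raise DataError(f"non-finite logS for compound {bad[0]!r}")

    @classmethod
    def from_dict(cls, values: dict, source: str | None = None) -> "SolubilitySet":
        labels = {k: source for k in values} if source else {}
        return cls(pd.Series(values, dtype=float), labels)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.series.index)

    def __len__(self) -> int:
        return len(self.series)

    def __getitem__(self, compound_id) -> float:
        return float(self.series[compound_id])

    def subset(self, ids) -> "SolubilitySet":
        ids = list(ids)
        return SolubilitySet(
            self.series.loc[ids],
            {k: v for k, v in self.source_labels.items() if k in set(ids)},
        )

    def align_with(self, table: DescriptorTable) -> np.ndarray:
        """Target vector ordered like the table's compounds."""
        return self.series.loc[table.compound_ids].to_numpy()


@dataclass(frozen=True)
class DatasetSplit:
    """Pairwise-disjoint train / validation / test identifier sets."""

    train_ids: tuple
    validation_ids: tuple
    test_ids: tuple = ()

    def __post_init__(self) -> None:
        tr, va, te = set(self.train_ids), set(self.validation_ids), set(self.test_ids)
        if tr & va or tr & te or va & te:
            raise DataError("split sets are not pairwise disjoint")


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_cell(raw: str, row_id, column: str) -> float:
    text = raw.strip()
    if text in MISSING_TOKENS:
        return np.nan
    try:
        return float(text)
    except ValueError:
        raise DataError(
            f"non-numeric cell {raw!r} at row {row_id!r}, column {column!r}"
        ) from None


def read_descriptor_csv(path) -> DescriptorTable:
    """Read a descriptor CSV (first column = compound id, rest numeric).

    Empty cells and ``NA`` are recorded as missing, never as zero.  Duplicate
    compound ids and non-numeric cells raise :class:`DataError` naming the
    offending id / cell.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 1:
        raise DataError(f"{path}: no columns")
    id_col = raw.columns[0]
    ids = raw[id_col].str.strip()
    if ids.duplicated().any():
        raise DataError(f"duplicate compound id: {ids[ids.duplicated()].iloc[0]!r}")
    data = {}
    for col in raw.columns[1:]:
        data[col] = [
            _parse_cell(v, ids.iloc[i], col) for i, v in enumerate(raw[col])
        ]
    frame = pd.DataFrame(data, index=pd.Index(ids, name=id_col), dtype=float)
    return DescriptorTable(frame)


def write_descriptor_csv(table: DescriptorTable, path, float_format: str = "%.12g") -> None:
    """Write a descriptor CSV; missing values become empty cells."""
    table.frame.to_csv(path, float_format=float_format, na_rep="")


def read_solubility_csv(path) -> SolubilitySet:
    """Read a target CSV ``compound_id,logS[,source]``."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise DataError(f"{path}: expected at least compound_id and logS columns")
    ids = raw.iloc[:, 0].str.strip()
    if ids.duplicated().any():
        raise DataError(f"duplicate compound id: {ids[ids.duplicated()].iloc[0]!r}")
    values = pd.Series(
        [_parse_cell(v, ids.iloc[i], raw.columns[1]) for i, v in enumerate(raw.iloc[:, 1])],
        index=pd.Index(ids, name=raw.columns[0]),
        dtype=float,
    )
    labels = {}
    if raw.shape[1] >= 3:
        labels = dict(zip(ids, raw.iloc[:, 2].str.strip()))
    return SolubilitySet(values, labels)


def write_solubility_csv(sset: SolubilitySet, path, float_format: str = "%.12g") -> None:
    frame = pd.DataFrame(
        {
            "logS": sset.series,
            "source": [sset.source_labels.get(i, "") for i in sset.compound_ids],
        }
    )
    frame.index.name = "compound_id"
    frame.to_csv(path, float_format=float_format)


# ---------------------------------------------------------------------------
# Pool curation


def _normalize_id(identifier) -> str:
    return re.sub(r"\s+", " ", str(identifier)).strip().casefold()


def remove_overlap(pool: SolubilitySet, test_ids) -> tuple[SolubilitySet, list]:
    """Drop from *pool* every compound also present in *test_ids*.

    Identifiers are compared case-insensitively after whitespace
    normalization, so a training pool can be checked against externally
    published test-set listings.  Returns the reduced pool and the list of
    removed pool ids (empty intersection is valid).  Idempotent.
    """
    test_norm = {_normalize_id(t) for t in test_ids}
    removed = [i for i in pool.compound_ids if _normalize_id(i) in test_norm]
    kept = [i for i in pool.compound_ids if _normalize_id(i) not in test_norm]
    return pool.subset(kept), removed


def split_train_validation(pool: SolubilitySet, n_validation: int, seed: int) -> DatasetSplit:
    """Seeded uniform random partition of *pool* into train and validation.

    The validation compounds are sampled without replacement; the remainder
    train.  Deterministic for a given seed.
    """
    n = len(pool)
    if not 0 < n_validation < n:
        raise DataError(
            f"n_validation must be in (0, {n}); got {n_validation}"
        )
    rng = np.random.default_rng(seed)
    ids = np.array(pool.compound_ids, dtype=object)
    val_idx = rng.choice(n, size=n_validation, replace=False)
    val_mask = np.zeros(n, dtype=bool)
    val_mask[val_idx] = True
    return DatasetSplit(
        train_ids=tuple(ids[~val_mask]),
        validation_ids=tuple(ids[val_mask]),
    )
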