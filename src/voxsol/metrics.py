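"""Evaluation statistics for solubility predictions.

Metric conventions, matching the reporting style standard in logS
benchmarking exercises:

* RMSE — root mean squared error, in logS units;
* AAE — average absolute error;
* R² — the square of the Pearson correlation coefficient between predicted
  and observed values (not the coefficient of determination), so it is
  always in [0, 1];
* SD — standard deviation of the observed values with denominator N (no
  Bessel correction), for consistency with the definition of RMSE;
* RMSE/SD — below 1 means the model beats predicting the dataset mean;
* within-threshold counts at 0.5 and 1.0 logS units, reported as
  ``count (pct%)`` with percentages rounded half-up to integers.

The boundary comparator for the within-threshold counts is configurable:
``closed`` (default) counts |error| <= threshold, ``strict`` counts
|error| < threshold.  The four-way error buckets used for colouring
prediction scatter plots are half-open as conventionally captioned:
under 0.5, 0.5 to 1.0, 1.0 to 2.0 (closed), over 2.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdMode",
    "EvalReport",
    "ErrorBucket",
    "evaluate",
    "bucket_errors",
    "compare_solubility_sets",
    "value_range",
    "report_table",
]


class ThresholdMode(Enum):
    CLOSED = "closed"  # |err| <= threshold
    STRICT = "strict"  # |err| < threshold


class ErrorBucket(Enum):
    UNDER_05 = "under_05"
    FROM_05_TO_10 = "from_05_to_10"
    FROM_10_TO_20 = "from_10_to_20"
    OVER_20 = "over_20"


def round_half_up_percent(count: int, n: int) -> int:
    """Integer percentage, .5 rounding away from zero toward the larger int."""
    return int(math.floor(100.0 * count / n + 0.5))


@dataclass(frozen=True)
class EvalReport:
    """Metric bundle for one predictor on one dataset."""

    rmse: float
    aae: float
    r2: float  # NaN when observed values are constant
    sd: float
    rmse_over_sd: float
    n_within_05: int
    n_within_10: int
    n: int
    threshold_mode: ThresholdMode = ThresholdMode.CLOSED

    @property
    def pct_within_05(self) -> int:
        return round_half_up_percent(self.n_within_05, self.n)

    @property
    def pct_within_10(self) -> int:
        return round_half_up_percent(self.n_within_10, self.n)


def _paired(predictions, observed):
    if isinstance(predictions, pd.Series) and isinstance(observed, pd.Series):
        common = predictions.index.intersection(observed.index)
        return predictions.loc[common].to_numpy(float), observed.loc[common].to_numpy(float)
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    return p, o


def _count_within(err: np.ndarray, threshold: float, mode: ThresholdMode) -> int:
    if mode is ThresholdMode.CLOSED:
        return int(np.sum(err <= threshold))
    return int(np.sum(err < threshold))


def evaluate(
    predictions, observed, threshold_mode: ThresholdMode = ThresholdMode.CLOSED
) -> EvalReport:
    """Compute the full metric bundle over paired predicted/observed logS.

    Requires at least two pairs.  With constant observed values R² is
    undefined and reported as NaN, never as zero.
    """
    p, o = _paired(predictions, observed)
    n = p.size
    if n < 2:
        raise ValueError("need at least two paired values")
    err = np.abs(p - o)
    rmse = float(np.sqrt(np.mean((p - o) ** 2)))
    aae = float(np.mean(err))
    sd = float(np.std(o))  # denominator N
    if np.all(o == o[0]) or np.all(p == p[0]):
        r2 = float("nan")
    else:
        r2 = float(stats.pearsonr(p, o).statistic ** 2)
    return EvalReport(
        rmse=rmse,
        aae=aae,
        r2=r2,
        sd=sd,
        rmse_over_sd=rmse / sd if sd > 0 else float("nan"),
        n_within_05=_count_within(err, 0.5, threshold_mode),
        n_within_10=_count_within(err, 1.0, threshold_mode),
        n=n,
        threshold_mode=threshold_mode,
    )


def bucket_errors(predictions, observed) -> list[ErrorBucket]:
    """Per-compound error category for figure colouring.

    |err| < 0.5 -> under_05; 0.5 <= |err| < 1.0 -> from_05_to_10;
    1.0 <= |err| <= 2.0 -> from_10_to_20; > 2.0 -> over_20.
    """
    p, o = _paired(predictions, observed)
    out = []
    for e in np.abs(p - o):
        if e < 0.5:
            out.append(ErrorBucket.UNDER_05)
        elif e < 1.0:
            out.append(ErrorBucket.FROM_05_TO_10)
        elif e <= 2.0:
            out.append(ErrorBucket.FROM_10_TO_20)
        else:
            out.append(ErrorBucket.OVER_20)
    return out


@dataclass(frozen=True)
class SetComparison:
    report: EvalReport
    n_differing_over_1: int
    common_ids: tuple


def compare_solubility_sets(
    set_a, set_b, threshold_mode: ThresholdMode = ThresholdMode.CLOSED
) -> SetComparison:
    """Compare two solubility compilations over their common compounds.

    Set A plays the role of predictions, set B of the gold standard; the
    metric bundle is computed over the id intersection, along with the
    count of compounds whose two values differ by more than one logS unit.
    """
    a = set_a.series if hasattr(set_a, "series") else pd.Series(set_a, dtype=float)
    b = set_b.series if hasattr(set_b, "series") else pd.Series(set_b, dtype=float)
    common = [i for i in a.index if i in set(b.index)]
    if not common:
        raise ValueError("the two sets share no compounds")
    pa, pb = a.loc[common].to_numpy(float), b.loc[common].to_numpy(float)
    report = evaluate(pa, pb, threshold_mode)
    n_over = int(np.sum(np.abs(pa - pb) > 1.0))
    return SetComparison(report=report, n_differing_over_1=n_over, common_ids=tuple(common))


def value_range(values) -> float:
    """max - min of a collection of logS determinations for one compound."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values for a range")
    return float(v.max() - v.min())


def report_table(reports: dict[str, EvalReport], rounding: int = 3) -> pd.DataFrame:
    """Tabulate named reports, one row per predictor.

    Metrics are rounded for display; within-threshold columns render as
    ``count (pct%)``.  ``DataFrame.to_csv`` / ``to_string`` give the CSV and
    aligned-text forms.
    """
    if not reports:
        raise ValueError("need at least one report")
    rows = []
    for name, rep in reports.items():
        rows.append(
            {
                "Method": name,
                "RMSE": round(rep.rmse, rounding),
                "RMSE/SD": round(rep.rmse_over_sd, rounding),
                "AAE": round(rep.aae, rounding),
                "R2": round(rep.r2, rounding) if not math.isnan(rep.r2) else float("nan"),
                "Err<0.5": f"{rep.n_within_05} ({rep.pct_within_05}%)",
                "Err<1.0": f"{rep.n_within_10} ({rep.pct_within_10}%)",
            }
        )
    return pd.DataFrame(rows).set_index("Method")
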