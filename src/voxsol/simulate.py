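"""Seeded synthetic descriptor/solubility datasets and tiny worked fixtures.

The generator emulates the statistical shape of a druglike descriptor
export at desk scale — on the order of 100-200 compounds by ~170 numeric
features — with the pathologies the cleaning pipeline must handle planted
deliberately:

* columns that are missing for every compound (removed by the
  incomplete-feature filter);
* zero-variance columns;
* blocks of strongly correlated features, built as affine copies of a block
  seed plus small jitter, so correlation pruning has known targets;
* a logS response that is a fixed, documented nonlinear function g of a
  small informative feature subset, plus Gaussian noise whose standard
  deviation mirrors inter-laboratory reproducibility: presets 0.17
  ("tight", carefully curated data) and 0.62 ("loose").

With informative features f1..f5 drawn uniform on [0, 1] (before the
per-feature affine shift onto descriptor-like ranges), the response is

    logS = -6 + 2*f1 - 3*f2 + 2*f3*f4 + 1.5*[f5 > 0.5] + eps,
    eps ~ Normal(0, noise_sd^2)

evaluated on the unshifted uniform variates, so the signal variance is
independent of the cosmetic descriptor ranges.  All randomness flows
through one numpy PCG64 generator seeded from ``spec.seed``; the draw order
is fixed, so datasets are bit-reproducible for a given seed across
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DescriptorTable, SolubilitySet

__all__ = [
    "GeneratorSpec",
    "SyntheticDataset",
    "generate",
    "make_fixtures",
    "NOISE_TIGHT",
    "NOISE_LOOSE",
]

#: inter-laboratory reproducibility presets (logS units)
NOISE_TIGHT = 0.17
NOISE_LOOSE = 0.62

N_INFORMATIVE = 5


@dataclass(frozen=True)
class GeneratorSpec:
    """Shape and noise parameters of a synthetic dataset."""

    n_compounds: int = 150
    n_features: int = 173
    n_correlated_blocks: int = 6
    block_size: int = 4  # features per correlated block, incl. the seed feature
    block_jitter: float = 0.02  # jitter SD on block copies, relative to their spread
    n_missing_columns: int = 2
    n_zero_variance_columns: int = 2
    noise_sd: float = NOISE_TIGHT
    seed: int = 0

    def __post_init__(self):
        base = (
            N_INFORMATIVE
            + self.n_correlated_blocks * self.block_size
            + self.n_missing_columns
            + self.n_zero_variance_columns
        )
        if self.n_features < base:
            raise ValueError(
                f"n_features={self.n_features} too small for the planted "
                f"structure (needs >= {base})"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    table: DescriptorTable
    solubility: SolubilitySet
    informative_features: list[str]
    correlated_blocks: list[list[str]]  # first entry of each block is the seed feature
    missing_columns: list[str]
    zero_variance_columns: list[str]
    description: str


def _response(u_inf: np.ndarray) -> np.ndarray:
    f1, f2, f3, f4, f5 = (u_inf[:, i] for i in range(N_INFORMATIVE))
    return -6.0 + 2.0 * f1 - 3.0 * f2 + 2.0 * f3 * f4 + 1.5 * (f5 > 0.5)


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Draw one synthetic descriptor table + logS set for *spec*.

    Deterministic per seed.  Degenerate constant targets (no informative
    signal and no noise) are rejected.
    """
    if spec.noise_sd == 0 and N_INFORMATIVE == 0:  # pragma: no cover - guarded shape
        raise ValueError("degenerate spec: constant target")
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_compounds, spec.n_features

    u = rng.random((n, p))  # uniform latent variates, one column per feature
    u_inf = u[:, :N_INFORMATIVE]
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else np.zeros(n)
    logs = _response(u_inf) + noise

    names = [f"D{j:03d}" for j in range(p)]
    x = np.empty((n, p))
    # cosmetic per-feature affine shift onto descriptor-like ranges
    scales = 10.0 ** rng.integers(-1, 3, size=p)
    offsets = rng.normal(0.0, 5.0, size=p)
    for j in range(p):
        x[:, j] = u[:, j] * scales[j] + offsets[j]

    # plant correlated blocks: affine copies of a block-seed column + jitter
    blocks: list[list[str]] = []
    col = N_INFORMATIVE
    for _b in range(spec.n_correlated_blocks):
        seed_col = col
        block = [names[seed_col]]
        for rep in range(1, spec.block_size):
            j = seed_col + rep
            slope = rng.uniform(0.5, 2.0) * (1 if rng.random() < 0.5 else -1)
            copy = slope * x[:, seed_col]
            # jitter relative to the copy's spread keeps |r| near 1 regardless
            # of the cosmetic descriptor range
            x[:, j] = copy + rng.normal(0, spec.block_jitter * copy.std(), size=n)
            block.append(names[j])
        blocks.append(block)
        col += spec.block_size

    # plant all-missing and zero-variance columns at the tail
    missing_cols = names[p - spec.n_missing_columns - spec.n_zero_variance_columns :
                         p - spec.n_zero_variance_columns]
    zero_var_cols = names[p - spec.n_zero_variance_columns :] if spec.n_zero_variance_columns else []
    for name in zero_var_cols:
        x[:, names.index(name)] = rng.normal(0, 3)  # one constant per column
    frame = pd.DataFrame(x, columns=names,
                         index=pd.Index([f"CPD{i:04d}" for i in range(n)], name="compound_id"))
    for name in missing_cols:
        frame[name] = np.nan

    table = DescriptorTable(frame, {name: "synthetic" for name in names})
    sol = SolubilitySet(
        pd.Series(logs, index=frame.index), {i: "synthetic" for i in frame.index}
    )
    return SyntheticDataset(
        table=table,
        solubility=sol,
        informative_features=names[:N_INFORMATIVE],
        correlated_blocks=blocks,
        missing_columns=list(missing_cols),
        zero_variance_columns=list(zero_var_cols),
        description=(
            "logS = -6 + 2*f1 - 3*f2 + 2*f3*f4 + 1.5*[f5>0.5] + "
            f"Normal(0, {spec.noise_sd}^2) on uniform latent features"
        ),
    )


# ---------------------------------------------------------------------------
# Worked fixtures: published logS determinations with wide literature spreads


def make_fixtures() -> dict:
    """Tiny named datasets for worked examples and tests.

    ``literature_spreads`` lists, per compound, the published logS
    determinations discussed in the literature-versus-curated comparison
    (each value labelled with a citation key); ``curated_averages`` carries the
    curated averages reported for three of the loose-set compounds.
    """
    spreads = {
        "griseofulvin": [(-3.25, "ref47"), (-4.83, "ref31")],
        "haloperidol": [(-4.43, "ref47"), (-5.26, "ref48"), (-5.14, "ref49"), (-5.77, "ref50")],
        "cisapride": [(-3.40, "ref48"), (-4.70, "ref48")],
        "amiodarone": [(-2.95, "ref48"), (-7.17, "ref48"), (-8.17, "ref23")],
        "clofazimine": [(-3.70, "ref48"), (-4.68, "ref48"), (-5.68, "ref48"), (-5.80, "ref47")],
        "saquinavir": [(-4.27, "ref48"), (-4.09, "ref48"), (-2.48, "ref48")],
        "tamoxifen": [(-8.49, "ref31"), (0.87, "ref48")],
        "bisoprolol": [(-7.77, "ref48"), (2.09, "curated")],
    }
    curated = {"amiodarone": -10.40, "clofazimine": -9.05, "saquinavir": -5.92}

    literature_first = SolubilitySet(
        pd.Series({k: v[0][0] for k, v in spreads.items()}),
        {k: v[0][1] for k, v in spreads.items()},
    )
    return {
        "literature_spreads": spreads,
        "curated_averages": curated,
        "literature_first_choice": literature_first,
    }
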