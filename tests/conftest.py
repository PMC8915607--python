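import numpy as np
import pandas as pd
import pytest

from voxsol import DescriptorTable, SolubilitySet
from voxsol.simulate import GeneratorSpec, generate


@pytest.fixture
def small_table():
    """Six compounds, three hand-picked features with a missing cell."""
    frame = pd.DataFrame(
        {
            "alpha": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0],
            "beta": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
            "gamma": [0.2, np.nan, 0.9, 0.1, 0.5, 0.7],
        },
        index=pd.Index([f"c{i}" for i in range(6)], name="compound_id"),
    )
    return DescriptorTable(frame)


@pytest.fixture
def small_target():
    return SolubilitySet.from_dict(
        {f"c{i}": v for i, v in enumerate([-2.0, -2.5, -3.0, -3.5, -4.0, -4.5])},
        source="toy",
    )


@pytest.fixture
def bench_small():
    """Compact synthetic dataset for ensemble/kNN behaviour tests."""
    spec = GeneratorSpec(
        n_compounds=80,
        n_features=40,
        n_correlated_blocks=2,
        block_size=3,
        n_missing_columns=1,
        n_zero_variance_columns=1,
        noise_sd=0.17,
        seed=7,
    )
    return generate(spec)
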