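import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from berryplast.core_data import ExpressionMatrix, SampleDescriptor
from berryplast.synthetic import SyntheticSpec, generate_dataset


def build_matrix(values, sample_names, gene_ids=None, scale="log2"):
    """ExpressionMatrix from an array and encoded sample names."""
    from berryplast.core_data import parse_sample_name

    values = np.asarray(values, dtype=float)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(values.shape[0])]
    descs = [parse_sample_name(n) for n in sample_names]
    df = pd.DataFrame(values, index=gene_ids, columns=sample_names)
    return ExpressionMatrix(df, descs, scale)


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-design synthetic dataset (11 x 3 x 3, 2000 genes)."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced synthetic dataset for fast pipeline unit tests."""
    spec = SyntheticSpec(
        n_vineyards=6,
        class_counts={
            "constitutive": 60, "marker_up": 40, "marker_down": 40,
            "plastic": 60, "year_effect": 0, "bimodal_low": 80, "background": 220,
        },
        seed=5,
    )
    return generate_dataset(spec)


@pytest.fixture
def six_sample_names():
    return ["AM081A", "AM081B", "AM081C", "CS081A", "CS081B", "CS081C"]
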