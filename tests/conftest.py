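import numpy as np
import pandas as pd
import pytest

from flavoromics import FeatureTable, SynthConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """Default-scale synthetic study (3 groups x 3 replicates), fixed seed."""
    return generate_study(SynthConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_table():
    """6-sample, 5-feature complete table with two groups and an IS channel."""
    r = np.random.default_rng(3)
    values = pd.DataFrame(
        r.lognormal(mean=10, sigma=0.3, size=(6, 5)),
        index=[f"s{i}" for i in range(6)],
        columns=[f"f{i}" for i in range(4)] + ["IS"],
    )
    return FeatureTable(
        values=values,
        group_labels=pd.Series(["A"] * 3 + ["B"] * 3, index=values.index),
        internal_standard_id="IS",
    )
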