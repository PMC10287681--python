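import pandas as pd
import pytest

from soilnet.otutable import OtuTable
from soilnet.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        n_mesocosms_per_soil=10,
        n_prok_otus=60,
        n_fungal_otus=60,
        n_prok_clusters=4,
        n_fungal_clusters=4,
        depth_mean=3000,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One small synthetic dataset shared across read-only tests."""
    return generate_dataset(small_config)


@pytest.fixture()
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        {
            "o1": [10, 20, 0, 5],
            "o2": [5, 5, 5, 5],
            "o3": [0, 0, 50, 40],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    habitat = pd.Series(
        ["natural", "natural", "abandoned", "abandoned"],
        index=counts.index,
    )
    return OtuTable(counts, habitat, "prokaryote")
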