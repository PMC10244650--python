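import numpy as np
import pytest

from umint import (
    SimulationConfig,
    UMINTConfig,
    preprocess_dataset,
    simulate,
)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-cell, 3-cluster paired dataset (RNA-like 200 features, ADT-like 15)."""
    return simulate(SimulationConfig(
        n_cells=300, n_clusters=3, modality_dims=(200, 15), seed=11,
    ))


@pytest.fixture(scope="session")
def small_processed(small_sim):
    """The same dataset after the rna/adt preprocessing recipes."""
    labels = dict(zip(small_sim.data.cell_ids, small_sim.true_labels))
    data, _ = preprocess_dataset(
        small_sim.data.modalities, ["rna", "adt"], labels=labels, n_top=200,
    )
    return data


@pytest.fixture()
def tiny_config():
    """A deliberately small network for fast unit tests."""
    return UMINTConfig(hidden_widths=[8, 4], bottleneck_width=5,
                       epochs=5, batch_size=32, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
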