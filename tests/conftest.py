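import numpy as np
import pytest

from expfusion.model import ExplosionConsequenceModel
from expfusion.simulate import (
    ScenarioGrid,
    SurrogateConfig,
    chemicals_to_frame,
    dataset_to_frame,
    generate_dataset,
    make_synthetic_chemicals,
)

TINY_HP = {
    "model_dim": 16,
    "n_heads": 2,
    "n_layers": 1,
    "ff_dim": 32,
    "epochs": 2,
    "batch_size": 64,
    "C": 1.0,
    "epsilon": 0.01,
    "gamma": 3e-4,
}


@pytest.fixture(scope="session")
def tiny_grid():
    return ScenarioGrid(
        temperatures=(0.0, 50.0),
        pressures=(100.0, 1000.0),
        leak_sizes=(10.0, 50.0),
        quantities=(10.0, 100.0),
    )


@pytest.fixture(scope="session")
def tiny_tables(tiny_grid):
    chems = make_synthetic_chemicals(8, seed=11)
    records = generate_dataset(chems, tiny_grid, SurrogateConfig())
    return chemicals_to_frame(chems), dataset_to_frame(records)


@pytest.fixture(scope="session")
def tiny_model(tiny_tables):
    chemicals, dataset = tiny_tables
    return ExplosionConsequenceModel(chemicals, dataset, split_seed=3, n_augment=2)


@pytest.fixture(scope="session")
def tiny_results(tiny_model):
    return tiny_model.fit(variant="full", hyperparams=TINY_HP, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
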