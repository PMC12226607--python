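import numpy as np
import pytest

from replayseg import ClassRegistry, build_dataset, make_incremental_splits
from replayseg.incremental import TrainConfig, run_initial_step
from replayseg.scenes import SceneSpec


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast scene spec for unit tests (the benchmark uses defaults)."""
    return SceneSpec(height=16, width=16, images_per_class=10,
                     blob_radius=(2.0, 5.0))


@pytest.fixture(scope="session")
def tiny_registry():
    return ClassRegistry([{1, 2, 3}, {4, 5}])


@pytest.fixture(scope="session")
def tiny_dataset(tiny_spec):
    items, manifest = build_dataset(tiny_spec, rng_seed=11)
    return items, manifest


@pytest.fixture(scope="session")
def tiny_splits(tiny_dataset, tiny_registry):
    items, manifest = tiny_dataset
    steps = make_incremental_splits(manifest, tiny_registry)
    train = {t: [items[r] for r in df[df["split"] == "train"]["row"]]
             for t, df in steps.items()}
    test = [items[r] for df in steps.values()
            for r in df[df["split"] == "test"]["row"]]
    return train, test


@pytest.fixture(scope="session")
def tiny_config():
    """Cheap protocol config for contract tests; no diffusion training."""
    return TrainConfig(epochs_initial=3, epochs_per_step=2, width=8,
                       train_diffusion=False, use_replay=False, seed=5)


@pytest.fixture(scope="session")
def tiny_state0(tiny_splits, tiny_registry, tiny_config):
    train, _ = tiny_splits
    return run_initial_step(train[0], tiny_registry, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
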