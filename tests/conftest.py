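import numpy as np
import pytest

from subloc import synth
from subloc.features import extract_feature_table


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four easy classes, 4 proteins each, fold-balanced; shared read-only."""
    spec = synth.DatasetSpec(
        classes=("cytoplasm", "nucleus", "cell_periphery", "vacuole"),
        cells_per_protein=8,
        proteins_per_class=4,
        fold_fractions=(0.5, 0.25, 0.25),
        seed=7,
    )
    return synth.generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_dataset):
    table, rejects = extract_feature_table(tiny_dataset)
    assert not rejects
    return table


@pytest.fixture(scope="session")
def trained_tiny_network(tiny_dataset):
    """A quickly trained small-architecture network on the 4-class set."""
    from subloc import network as net

    config = net.NetworkConfig(
        conv_widths=(4, 4, 8, 8, 8, 8, 8, 8),
        fc_widths=(24, 24, 4),
        n_classes=4,
        dropout_rate=0.0,
    )
    network = net.build_network(config, seed=3)
    tcfg = net.TrainConfig(epochs=4, batch_size=16, initial_lr=0.15, seed=3,
                           lr_halving_interval=10_000)
    return net.train(network, tiny_dataset, tcfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
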