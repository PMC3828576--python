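import numpy as np
import pytest

from idrmap import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down genome: 6 Mb / 12 windows, 240 genes, 60 pairs."""
    return SimulationConfig(
        chrom_length_bp=6_000_000,
        n_genes=240,
        n_pairs=60,
        mean_protein_length=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return simulate(small_config)


@pytest.fixture(scope="session")
def small_bundle_dir(small_bundle, tmp_path_factory):
    d = tmp_path_factory.mktemp("bundle")
    small_bundle.write(d)
    return d


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
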