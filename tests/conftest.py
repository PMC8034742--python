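import pytest

from forestroutes import synthetic


@pytest.fixture(scope="session")
def world():
    return synthetic.gen_world(seed=1)


@pytest.fixture(scope="session")
def species_small(world):
    return synthetic.gen_species(world, n=40, seed=3)


@pytest.fixture()
def dataset_dir(tmp_path, world, species_small):
    """Synthetic dataset written in the ingest interchange formats."""
    synthetic.write_dataset(world, species_small, tmp_path)
    return tmp_path
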