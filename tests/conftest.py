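import numpy as np
import pytest

from mvfuse.dataset_io import load_dataset, load_manifest, stratified_split
from mvfuse.synthetic_specimens import GeneratorConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory):
    """Small generated dataset: 2 subfamilies x 2 species x 8 specimens."""
    out = tmp_path_factory.mktemp("tiny_dataset")
    cfg = GeneratorConfig(n_species_per_subfamily=2, n_specimens_per_species=8,
                          image_size=64, missing_view_rate=0.15, seed=7)
    generate_dataset(cfg, out)
    return out


@pytest.fixture(scope="session")
def tiny_dataset(tiny_dataset_dir):
    return load_dataset(tiny_dataset_dir / "manifest.csv", input_size=32)


@pytest.fixture(scope="session")
def tiny_records(tiny_dataset_dir):
    return load_manifest(tiny_dataset_dir / "manifest.csv")


@pytest.fixture(scope="session")
def tiny_split(tiny_records):
    return stratified_split(tiny_records, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
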