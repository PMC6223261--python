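import numpy as np
import pytest

from plpmine.catalog_stats import load_catalog
from plpmine.synthetic_data import SimulationParams, make_dataset


@pytest.fixture(scope="session")
def catalog():
    """The packaged published PLP catalog."""
    return load_catalog()


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small seeded synthetic dataset shared by mining/pipeline tests."""
    out = tmp_path_factory.mktemp("ds")
    params = SimulationParams(seed=5, n_plps=8, n_decoy_transcripts=8)
    fasta, mgf, truth = make_dataset(params, out)
    return {"params": params, "fasta": fasta, "mgf": mgf, "truth": truth, "dir": out}


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
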