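import numpy as np
import pytest

from dabiddi.molecular_features import parse_smiles
from dabiddi.synthetic_data import SimReportConfig, gen_molecules, gen_reports

ASPIRIN = "CC(=O)OC1=CC=CC=C1C(=O)O"


@pytest.fixture(scope="session")
def aspirin_graph():
    return parse_smiles(ASPIRIN, "aspirin")


@pytest.fixture(scope="session")
def molecule_set():
    return gen_molecules(30, seed=11)


@pytest.fixture(scope="session")
def small_corpus():
    """A modest simulated report corpus shared across bayes tests."""
    cfg = SimReportConfig(n_drugs=8, n_reports=5000, n_aes=4, seed=21)
    reports, truth = gen_reports(cfg)
    return cfg, reports, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
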