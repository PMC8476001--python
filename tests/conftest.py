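import numpy as np
import pytest

from tcrmodels import simulate
from tcrmodels.io import ClonotypeRecord, ClonotypeTable


@pytest.fixture
def simple_table():
    return ClonotypeTable(
        [
            ClonotypeRecord("CASSF", 3, v_gene="V1"),
            ClonotypeRecord("CASSF", 2, v_gene="V2"),
            ClonotypeRecord("CASSLGF", 1, v_gene="V3"),
        ],
        sample_id="s1",
        timepoint="day0",
    )


@pytest.fixture(scope="session")
def anchored_seqs():
    """Mixed-length anchored CDR3s spanning the default length range."""
    cfg = simulate.SimulationConfig(n_clones=600, seed=11)
    clones, _ = simulate.generate_repertoire(cfg)
    return clones


@pytest.fixture(scope="session")
def tiny_rbm():
    """A 3-site, 2-state, 1-hidden toy model with fixed parameters."""
    from tcrmodels.rbm import DReLUParams, RBMModel

    rng = np.random.default_rng(42)
    model = RBMModel(
        g=rng.normal(size=(3, 2)) * 0.5,
        W=rng.normal(size=(3, 1, 2)) * 0.8,
        hidden=DReLUParams(
            np.array([0.9]), np.array([1.4]), np.array([0.3]), np.array([-0.2])
        ),
        n_sites=3,
        n_states=2,
    )
    return model
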