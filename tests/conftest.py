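import numpy as np
import pytest

from dosefm.data import Dataset, Measurement
from dosefm.simulate import SimulationConfig, generate_dataset


TOY_CSV = """NSC1,CONC1,NSC2,CONC2,CELLNAME,PERCENTGROWTH
101,1e-7,205,1e-6,MCF7,45.0
101,1e-7,205,5e-6,MCF7,30.0
101,5e-7,205,1e-6,MCF7,25.0
101,5e-7,205,5e-6,MCF7,10.0
101,1e-7,,,MCF7,80.0
205,1e-6,,,MCF7,60.0
"""


@pytest.fixture
def toy_file(tmp_path):
    """6-row screen: a 2x2 combination grid plus two monotherapy rows."""
    path = tmp_path / "toy.csv"
    path.write_text(TOY_CSV)
    return path


@pytest.fixture
def toy_dataset():
    """Hand-built dataset: one pair in one cell line, complete 2x2 grid."""
    ms = [
        Measurement("101", 1e-07, "205", 1e-06, "MCF7", 45.0),
        Measurement("101", 1e-07, "205", 5e-06, "MCF7", 30.0),
        Measurement("101", 5e-07, "205", 1e-06, "MCF7", 25.0),
        Measurement("101", 5e-07, "205", 5e-06, "MCF7", 10.0),
        Measurement("101", 1e-07, None, None, "MCF7", 80.0),
        Measurement("101", 5e-07, None, None, "MCF7", 55.0),
        Measurement("205", 1e-06, None, None, "MCF7", 60.0),
        Measurement("205", 5e-06, None, None, "MCF7", 40.0),
    ]
    return Dataset.from_measurements(ms)


@pytest.fixture(scope="session")
def small_sim():
    """A small noiseless-friendly screen shared across tests.

    8 drugs, 12 pairs, 3 cell lines, 2x2 grids: large enough for fold
    construction under every scenario, small enough to encode fast.
    """
    config = SimulationConfig(n_drugs=8, n_cell_lines=3, grid_size=2,
                              pair_fraction=12 / 28, noise_sd=2.0, seed=42)
    return generate_dataset(config)


@pytest.fixture(scope="session")
def default_sim():
    """The generator's default study conditions (seeded)."""
    return generate_dataset(SimulationConfig(seed=7))
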