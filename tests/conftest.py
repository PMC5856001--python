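import numpy as np
import pytest

from dsbpred import Genome, make_shape_table
from dsbpred.simulate import MarkSpec, SimulationConfig, simulate_dataset

JASPAR_TEXT = """\
>MA0001.1 ALPHA
A  [ 10  0  0 10 ]
C  [  0 10  0  0 ]
G  [  0  0 10  0 ]
T  [  0  0  0  0 ]
>MA0002.1 BETA
A  [ 12  2  0  0  3 14 ]
C  [  1  0 14  0  2  0 ]
G  [  0 12  0  0  9  0 ]
T  [  1  0  0 14  0  0 ]
"""


@pytest.fixture(scope="session")
def jaspar_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("motifs") / "motifs.jaspar"
    path.write_text(JASPAR_TEXT)
    return path


@pytest.fixture(scope="session")
def shape_table():
    return make_shape_table(seed=0)


@pytest.fixture(scope="session")
def flat_genome():
    """A 20-kb single-chromosome genome of uniform sequence for geometry tests."""
    return Genome.from_dict({"chr1": "A" * 20_000})


@pytest.fixture(scope="session")
def sim():
    """A small simulated dataset shared across tests: genome, ground truth."""
    cfg = SimulationConfig(
        seed=11, n_chroms=1, chrom_length=600_000, n_dsb=300
    )
    genome, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "genome": genome, "truth": truth}


@pytest.fixture(scope="session")
def null_sim():
    """Same generative process with uninformative marks (no class signal)."""
    cfg = SimulationConfig(
        seed=13,
        n_chroms=1,
        chrom_length=600_000,
        n_dsb=300,
        marks=[MarkSpec("null_mark", 0.3, 0.3)],
    )
    genome, truth = simulate_dataset(cfg)
    return {"cfg": cfg, "genome": genome, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(20_240)
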