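import numpy as np
import pytest

from bovimito import (MultiAlignment, RootedTree, SubstitutionModel,
                      simulate, study_emulator)
from bovimito.simulate import SimulationConfig


@pytest.fixture(scope="session")
def preset_run():
    """One wisent-trio preset simulation shared across tests."""
    cfg = study_emulator(seed=1)
    genomes, aln, truth = simulate(cfg)
    return cfg, genomes, aln, truth


@pytest.fixture(scope="session")
def jc_pair_50kb():
    """A two-taxon JC dataset long enough for tight distance checks."""
    tree = RootedTree.from_newick("(a:0.025,b:0.025);")
    cfg = SimulationConfig(tree=tree, model=SubstitutionModel.jc(),
                           genome_length=50000, seed=17)
    _, aln, truth = simulate(cfg)
    return aln, truth


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
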