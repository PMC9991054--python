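import numpy as np
import pytest

from somgnn.molgraph import (
    AtomRecord,
    BondRecord,
    EnzymeContext,
    FeatureConfig,
    MoleculeGraph,
    parse_molecule,
)
from somgnn.synthetic import SynthConfig, make_planted_dataset


def make_graph(elements, bonds, molecule_id="g"):
    """Build a MoleculeGraph from element symbols and (i, j, order) triples."""
    atoms = [AtomRecord(index=k, element=e, degree=0) for k, e in enumerate(elements)]
    recs = [BondRecord(i=min(i, j), j=max(i, j), order=o) for i, j, o in bonds]
    return MoleculeGraph(atoms=atoms, bonds=recs, molecule_id=molecule_id)


@pytest.fixture(scope="session")
def ethanol():
    return parse_molecule("CCO")


@pytest.fixture(scope="session")
def glycol():
    # O-C-C-O: the end-swapping symmetry maps one oxygen onto the other
    return make_graph(["O", "C", "C", "O"], [(0, 1, 1), (1, 2, 1), (2, 3, 1)])


@pytest.fixture(scope="session")
def small_feature_config():
    return FeatureConfig(
        element_vocab=["C", "N", "O"],
        envtype_vocab=["C|1|C1", "C|2|C1,C1"],
        ec2_vocab=["1.4", "2.1"],
    )


@pytest.fixture(scope="session")
def rule0_dataset():
    return make_planted_dataset(SynthConfig(n_molecules=120, rule_id="rule0", seed=11))


@pytest.fixture(scope="session")
def rule2_dataset():
    return make_planted_dataset(SynthConfig(n_molecules=120, rule_id="rule2", seed=11))


def split_examples(dataset, n_train, n_val, seed=3):
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    train = [dataset[i] for i in perm[:n_train]]
    val = [dataset[i] for i in perm[n_train:n_train + n_val]]
    test = [dataset[i] for i in perm[n_train + n_val:]]
    return train, val, test
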