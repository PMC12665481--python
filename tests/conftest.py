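import dendropy
import numpy as np
import pytest

from basaltbiome import datasets
from basaltbiome.ecology import AsvTable


@pytest.fixture(scope="session")
def records():
    return datasets.load_well_chemistry()


@pytest.fixture(scope="session")
def chem_frame():
    return datasets.load_chemistry_frame()


@pytest.fixture(scope="session")
def reactivity_ref():
    return datasets.load_reactivity_reference()


@pytest.fixture(scope="session")
def constants():
    return datasets.default_thermo_constants()


@pytest.fixture(scope="session")
def kinetics():
    return datasets.default_phase_kinetics()


@pytest.fixture
def four_leaf_tree():
    return dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);", schema="newick")


def random_community_fixture(seed: int, n_samples: int = 6, n_asvs: int = 12):
    """A random presence table + matching random tree, for metric axioms."""
    from basaltbiome.synthetic import generate_tree

    rng = np.random.default_rng(seed)
    tree = generate_tree(n_asvs, seed=seed)
    counts = rng.integers(0, 3, size=(n_samples, n_asvs))
    # guarantee no empty sample
    for i in range(n_samples):
        if counts[i].sum() == 0:
            counts[i, rng.integers(n_asvs)] = 1
    table = AsvTable(counts, [f"s{i}" for i in range(n_samples)],
                     [f"ASV_{j + 1}" for j in range(n_asvs)])
    return table, tree
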