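import numpy as np
import pytest

from optionvalue import (
    Phylogeny,
    SpeciesTable,
    SynthConfig,
    TreeEnsemble,
    simulate_attributes,
    simulate_ensemble,
    simulate_yule_tree,
)

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):2);"


@pytest.fixture
def toy_tree() -> Phylogeny:
    """Four-tip tree with hand-checkable PD/ED values."""
    return Phylogeny.from_newick(TOY_NEWICK)


@pytest.fixture
def toy_newick() -> str:
    return TOY_NEWICK


@pytest.fixture(scope="session")
def yule100() -> Phylogeny:
    """A fixed 100-tip pure-birth tree shared across tests."""
    return simulate_yule_tree(100, seed=11)


@pytest.fixture(scope="session")
def small_ensemble() -> TreeEnsemble:
    """Fixed 100-tip, 3-tree ensemble."""
    return simulate_ensemble(100, 3, seed=11)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    return SynthConfig(n_tips=100, n_trees=3, seed=11)


@pytest.fixture(scope="session")
def small_table(small_ensemble, small_config) -> SpeciesTable:
    return simulate_attributes(small_ensemble, small_config)


def random_yule(n_tips: int, seed) -> Phylogeny:
    return simulate_yule_tree(n_tips, 1.0, np.random.default_rng(seed))
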