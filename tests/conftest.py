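import numpy as np
import pandas as pd
import pytest

from ovensong import (SimulationConfig, make_bundle, parse_newick,
                      simulate_tree)


@pytest.fixture(scope="session")
def balanced_tree():
    """Four-tip ultrametric tree with hand-checkable covariances."""
    return parse_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def tree50():
    return simulate_tree(50, seed=1234)


@pytest.fixture(scope="session")
def small_bundle():
    """A 40-species synthetic study reused across tests (read-only)."""
    return make_bundle(SimulationConfig(seed=99, n_species=40,
                                        n_posterior_trees=4))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def species_table(small_bundle):
    """Merged species table (song means + predictors) for model fitting."""
    from ovensong import derive_song_features, encode_habitat, species_aggregate
    clean, _ = derive_song_features(small_bundle.songs)
    tab = species_aggregate(clean).join(small_bundle.predictors)
    return tab.join(encode_habitat(tab["habitat"]))


def star_tree(n, length=1.0):
    labels = [f"s{i:03d}" for i in range(n)]
    return parse_newick(
        "(" + ",".join(f"{l}:{length}" for l in labels) + ");"), labels
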