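import dendropy
import numpy as np
import pandas as pd
import pytest

from ecophylo import (
    EffectSpec,
    StudyDesign,
    generate_backbone,
    generate_study,
    graft_species,
    resolve_uncertainty,
)


def tree_from_newick(s: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=s, schema="newick",
                             suppress_internal_node_taxa=True)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the worked example tree."""
    return tree_from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_study():
    return generate_study(seed=101)


@pytest.fixture(scope="session")
def null_study():
    return generate_study(effects=EffectSpec.null(), seed=202)


@pytest.fixture(scope="session")
def default_backbone(default_study):
    return generate_backbone(default_study.genus_map, 140.0, seed=303)


@pytest.fixture(scope="session")
def default_polytomy(default_study, default_backbone):
    return graft_species(default_backbone, default_study.genus_map)


@pytest.fixture(scope="session")
def small_ensemble(default_polytomy):
    return resolve_uncertainty(default_polytomy, 8, seed=404)


@pytest.fixture
def toy_community():
    """6 units x 5 species with two clear habitat blocks."""
    W = pd.DataFrame(
        [[5, 3, 0, 0, 1],
         [4, 4, 1, 0, 0],
         [6, 2, 0, 1, 0],
         [0, 1, 5, 4, 3],
         [1, 0, 4, 5, 2],
         [0, 0, 6, 3, 4]],
        index=[f"u{i}" for i in range(6)],
        columns=list("abcde"),
    )
    return W
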