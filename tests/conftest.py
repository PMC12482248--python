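import random

import pytest

from svmfp.graphbuild import SubstructureGraph
from svmfp.matching import SubstructureInstance
from svmfp.vocabulary import (
    CARBON_BACKBONE,
    FUNCTIONAL_GROUP,
    Substructure,
    Vocabulary,
    default_vocabulary,
)

#: a drug-sized reference for analog-set tests (large enough that single
#: graph edits keep path-fingerprint similarity above the 0.90 filter)
REFERENCE_SMILES = (
    "CC(C)Cc1ccc(cc1)C(C)C(=O)NCCc1ccc(OC)c(OC)c1N(CC)C(=O)c1ccc(F)cc1OC"
)


@pytest.fixture(scope="session")
def full_vocab() -> Vocabulary:
    return default_vocabulary()


@pytest.fixture()
def tiny_vocab() -> Vocabulary:
    """Hydroxyl + primary amine + a generic 3-carbon chain + benzene."""
    return Vocabulary((
        Substructure(0, "hydroxyl", "[OX2H]", FUNCTIONAL_GROUP),
        Substructure(1, "primary-amine", "[NX3H2]", FUNCTIONAL_GROUP),
        Substructure(2, "chain-C3", "[C;!R]-[C;!R]-[C;!R]", CARBON_BACKBONE,
                     smiles="CCC"),
        Substructure(3, "benzene", "c1ccccc1", CARBON_BACKBONE,
                     smiles="c1ccccc1"),
    ))


def random_instance_graph(
    rng: random.Random,
    max_nodes: int = 12,
    n_classes: int = 20,
) -> SubstructureGraph:
    """A random substructure graph with class-consistent backbone flags."""
    k = rng.randint(0, max_nodes)
    backbone_class = [rng.random() < 0.4 for _ in range(n_classes)]
    nodes = []
    for _ in range(k):
        cls = rng.randrange(n_classes)
        nodes.append(SubstructureInstance(
            substructure_index=cls,
            atom_indices=frozenset(),
            score=1.0,
            is_backbone=backbone_class[cls],
        ))
    edges = {
        (i, j)
        for i in range(k)
        for j in range(i + 1, k)
        if rng.random() < 0.3
    }
    return SubstructureGraph(nodes=nodes, edges=edges)
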