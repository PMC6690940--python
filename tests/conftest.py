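import numpy as np
import pytest

from islandpe import (
    DatedTree,
    GenusAnnotations,
    OccurrenceRecord,
    build_incidence,
)

TOY_NEWICK = "((A:1,B:1):1,C:2);"

# (genus, island) presences used across the metric tests:
# I1 = {A}, I2 = {A, B, C}, I3 = {C}
TOY_PRESENCES = [("A", "I1"), ("A", "I2"), ("B", "I2"), ("C", "I2"), ("C", "I3")]


@pytest.fixture
def toy_tree() -> DatedTree:
    return DatedTree.from_newick_string(TOY_NEWICK)


@pytest.fixture
def toy_records() -> list[OccurrenceRecord]:
    return [OccurrenceRecord(g, i, 0.0, 0.0) for g, i in TOY_PRESENCES]


@pytest.fixture
def toy_incidence(toy_tree, toy_records):
    return build_incidence(toy_records, toy_tree)


@pytest.fixture
def toy_annotations() -> GenusAnnotations:
    """C occurs on continents; A and B are island-restricted."""
    return GenusAnnotations(continental={"A": False, "B": False, "C": True})


def random_world(rng: np.random.Generator, n_tips=8, n_islands=6):
    """Small random tree + incidence for property tests (every genus somewhere)."""
    from islandpe.synthetic import SyntheticScenario, generate_incidence, generate_tree

    seed = int(rng.integers(2**31))
    scn = SyntheticScenario(
        n_genera=n_tips, n_islands=n_islands, seed=seed, f_paleo=0.0, f_neo=0.0
    )
    tree = generate_tree(scn)
    inc, ann = generate_incidence(scn, tree)
    return tree, inc, ann
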