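import numpy as np
import pytest

from stratadate.reference import reference_species_tree
from stratadate.trees import SpeciesTree, enumerate_single_w


@pytest.fixture(scope="session")
def ref_tree():
    """The bundled dated 13-species reference topology (single-W)."""
    return reference_species_tree()


@pytest.fixture(scope="session")
def ref_tree_multi():
    return reference_species_tree(multi_w=True)


@pytest.fixture(scope="session")
def ref_scenarios(ref_tree):
    return enumerate_single_w(ref_tree)


@pytest.fixture(scope="session")
def small_tree():
    """A 5-tip dated ladder with the focal species F (ages 0.1..1)."""
    return SpeciesTree(
        "((((F:0.1,O1:0.1):0.15,O2:0.25):0.25,O3:0.5):0.5,O4:1.0);", "F"
    )


def random_nested_tree(rng, n_tips):
    """Random rooted binary topology as a nested tuple, with random
    ultrametric ages; returns (newick_with_lengths, tip_labels)."""
    labels = [f"t{i}" for i in range(n_tips)]
    items = [(lab, 0.0) for lab in labels]
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), 2, replace=False))
        (a, ha), (b, hb) = items[i], items[j]
        h = max(ha, hb) + float(rng.uniform(0.1, 1.0))
        merged = (f"({a}:{h - ha},{b}:{h - hb})", h)
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return items[0][0] + ";", labels


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
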