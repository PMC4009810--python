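import pytest

from phylorisk import ExtinctionModel, load_fixture, synthesize


@pytest.fixture(scope="session")
def fig1():
    return load_fixture("fig1")


@pytest.fixture(scope="session")
def caribbean():
    return load_fixture("caribbean")


@pytest.fixture(scope="session")
def nasuta_pichoni():
    return load_fixture("nasuta_pichoni")


@pytest.fixture(scope="session")
def batunai_abrotanoides():
    return load_fixture("batunai_abrotanoides")


@pytest.fixture(scope="session")
def caribbean_model(caribbean):
    """All three Caribbean species at the critically-endangered probability."""
    base = ExtinctionModel.from_metadata(caribbean.metadata)
    return base.revised({tip: 0.99 for tip in caribbean.metadata})


@pytest.fixture(scope="session")
def random_fixture_12():
    """Seeded 12-tip synthetic fixture for brute-force oracle suites."""
    return synthesize(12, seed=7)


# ---------------------------------------------------------------------------
# Independent oracles (path-walking, set algebra); kept free of the library's
# branch-intersection implementation so they can check it.


def root_path_branches(tree, tip_label):
    """Branches (child nodes) on the path from a tip to the root, by walking."""
    node = tree.tip(tip_label)
    path = []
    while node is not None:
        if node.parent is not None or node.length > 0:
            path.append(node)
        node = node.parent
    return path


def brute_force_pd(tree, tips):
    """PD as the summed length of the union of root-path edge sets."""
    edges = set()
    for tip in tips:
        edges.update(id(b) for b in root_path_branches(tree, tip))
    lookup = {id(b): b.length for b in tree.branches()}
    return sum(lookup[e] for e in edges)
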