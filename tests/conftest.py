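"""Shared fixtures and tree-generation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from leca_trace import fixtures as fx
from leca_trace.formats import parse_tree

# ---------------------------------------------------------------------------
# Tree generation helpers (independent of the package's tree machinery)
# ---------------------------------------------------------------------------


def nested_to_newick(t) -> str:
    def render(node) -> str:
        if isinstance(node, tuple):
            return "(" + ",".join(render(c) for c in node) + ")"
        return str(node)

    return render(t) + ";"


def _insert_everywhere(t, tip):
    yield (t, tip)
    if isinstance(t, tuple):
        a, b = t
        for na in _insert_everywhere(a, tip):
            yield (na, b)
        for nb in _insert_everywhere(b, tip):
            yield (a, nb)


def all_rooted_binary_trees(tips):
    """Every labelled rooted binary topology on the given tips.

    Built by sequential tip insertion; yields (2n-3)!! nested-tuple trees.
    """
    trees = [tips[0]]
    for tip in tips[1:]:
        trees = [nt for t in trees for nt in _insert_everywhere(t, tip)]
    return trees


def random_binary_newick(rng: np.random.Generator, n_tips: int, with_lengths: bool = False) -> str:
    """A uniformly random sequence of joins over ``n_tips`` labelled tips."""
    nodes = [f"t{i}" for i in range(n_tips)]
    if with_lengths:
        nodes = [f"{n}:{rng.uniform(0.1, 2.0):.3f}" for n in nodes]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        joined = f"({a},{b})"
        if with_lengths:
            joined += f":{rng.uniform(0.1, 2.0):.3f}"
        nodes.append(joined)
    return nodes[0] + ";"


def random_presence(rng: np.random.Generator, tips, p: float = 0.5) -> dict[str, int]:
    return {t: int(rng.random() < p) for t in tips}


# ---------------------------------------------------------------------------
# Packaged-fixture fixtures
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def taxon_map():
    return fx.load_taxon_map()


@pytest.fixture(scope="session")
def fig2_tree(taxon_map):
    return fx.load_reference_tree(taxon_map)


@pytest.fixture(scope="session")
def table1_profile():
    return fx.load_table1_profile()


@pytest.fixture(scope="session")
def table2_profile():
    return fx.load_table2_profile()


@pytest.fixture(scope="session")
def combined_profile():
    return fx.load_combined_profile()


@pytest.fixture(scope="session")
def inventory():
    return fx.load_inventory()


@pytest.fixture()
def small_tree():
    """The 4-tip example tree with an explicit root bipartition."""
    return parse_tree("((A,B)L,(C,D)R);", sides={"UNIKONT": ["L"], "BIKONT": ["R"]})
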