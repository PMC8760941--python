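import numpy as np
import pytest

from convloss.treeio import SpeciesConfig


@pytest.fixture
def config3():
    """Three parasite-host pairs, one nonhost, one reference."""
    return SpeciesConfig(
        roles={
            "P1": "parasite", "H1": "host",
            "P2": "parasite", "H2": "host",
            "P3": "parasite", "H3": "host",
            "N1": "nonhost",
            "REF": "reference",
        },
        lineages={"L1": ("P1", "H1"), "L2": ("P2", "H2"), "L3": ("P3", "H3")},
    )


@pytest.fixture
def config1():
    """Single parasite-host pair plus reference."""
    return SpeciesConfig(
        roles={"P1": "parasite", "H1": "host", "REF": "reference"},
        lineages={"L1": ("P1", "H1")},
    )


def random_newick(rng: np.random.Generator, leaf_names, with_supports=True):
    """Random rooted binary tree over the given leaves, as newick."""
    nodes = [f"{name}:0.1" for name in leaf_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        sup = f"{rng.uniform():.2f}" if with_supports else ""
        nodes.append(f"({a},{b}){sup}:0.1")
    nwk = nodes[0]
    # strip the root's support label and branch length: roots carry none
    return nwk[: nwk.rfind(")") + 1] + ";"
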