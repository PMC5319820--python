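import random

import pytest

from cophy import Tree, parse_newick, yule_tree


def caterpillar(labels) -> Tree:
    """Fully unbalanced (ladder) tree over ``labels`` in order."""
    labels = list(labels)
    s = f"({labels[0]},{labels[1]})"
    for lab in labels[2:]:
        s = f"({s},{lab})"
    return parse_newick(s + ";")


def random_binary_pair(n_tips: int, seed: int):
    """Two independent random binary trees over the same tip labels."""
    rng = random.Random(seed)
    t1 = yule_tree(n_tips, rng.randrange(2**31))
    t2 = yule_tree(n_tips, rng.randrange(2**31))
    return t1, t2


@pytest.fixture
def cat5():
    return caterpillar(["a", "b", "c", "d", "e"])
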