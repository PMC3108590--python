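import numpy as np
import pytest

import lexitree as lt


@pytest.fixture
def two_lexicons():
    a = lt.Lexicon("A", {"m1": ("ab",), "m2": ("cd",)})
    b = lt.Lexicon("B", {"m1": ("ab",), "m2": ("ce",)})
    return a, b


@pytest.fixture
def small_dataset():
    lexicons = (
        lt.Lexicon("A", {"m1": ("ab",), "m2": ("cd",)}),
        lt.Lexicon("B", {"m1": ("ab",), "m2": ("ce",)}),
        lt.Lexicon("C", {"m1": ("zz",), "m2": ("cd",)}),
    )
    return lt.LexicalDataset(("m1", "m2"), lexicons)


def random_tree_with_lengths(n, seed, lo=0.5, hi=2.0):
    """Random binary tree with positive branch lengths (additive-matrix source)."""
    tree = lt.random_binary_tree([f"t{i:02d}" for i in range(n)], seed)
    rng = np.random.default_rng(seed + 7)
    for node in tree.nodes():
        if node is not tree.root:
            node.length = float(rng.uniform(lo, hi))
    return tree
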