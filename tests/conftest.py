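import dendropy
import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


def coalescent_ultrametric_tree(n_tips: int, rng: np.random.Generator,
                                depth_scale: float = 10.0) -> dendropy.Tree:
    """Random ultrametric tree built by successive pairwise coalescence."""
    tns = dendropy.TaxonNamespace()
    live = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = tns.new_taxon(f"t{i}")
        nd._age = 0.0
        live.append(nd)
    t = 0.0
    while len(live) > 1:
        t += rng.exponential(depth_scale / n_tips)
        i, j = sorted(rng.choice(len(live), 2, replace=False))
        a, b = live[int(i)], live[int(j)]
        parent = dendropy.Node()
        parent._age = t
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = t - a._age
        b.edge.length = t - b._age
        live = [x for k, x in enumerate(live) if k not in (int(i), int(j))]
        live.append(parent)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = live[0]
    return tree


@pytest.fixture
def tree_factory():
    return coalescent_ultrametric_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
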