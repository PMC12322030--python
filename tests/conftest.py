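import numpy as np
import pytest

from orthodyn import CountModel, SimConfig, simulate_all


def small_config(seed: int = 3, **overrides) -> SimConfig:
    """Reduced study conditions shared across tests: 6 orders x 12 tips,
    ~250 families."""
    defaults = dict(
        seed=seed,
        n_orders=6,
        tips_per_order=12,
        block_sizes={"core": 120, "contracted_in_fel": 20, "lost_in_fel": 15,
                     "gained_in_fel": 10, "driver": 30, "orphan": 9,
                     "rare_species_specific": 40},
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def bundle():
    """One full synthetic dataset at the reduced scale."""
    return simulate_all(small_config(seed=3))


@pytest.fixture(scope="session")
def default_bundle():
    """One dataset at the full default study conditions (12 orders x 32
    tips, 1000 families); session-scoped because it is the expensive one."""
    return simulate_all(SimConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_bifurcating_tree(rng: np.random.Generator, n_tips: int):
    """Random bifurcating tree with strictly positive branch lengths
    (pure-birth shape, edges then jittered multiplicatively)."""
    import dendropy

    from orthodyn.simulate import _yule_clade

    tns = dendropy.TaxonNamespace()
    labels = [f"T{i}" for i in range(n_tips)]
    clade = _yule_clade(rng, n_tips, 1.0, labels, tns)
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = clade
    tree.is_rooted = True
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.edge.length * float(rng.uniform(0.5, 1.5)) \
                + 1e-3
    return tree


def noiseless_config(seed: int = 5) -> SimConfig:
    """Deterministic counts (noise disabled) for exact planted-block checks."""
    return small_config(seed=seed, count_model=CountModel(distribution="fixed"))
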