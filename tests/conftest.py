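import numpy as np
import pytest

from enrichdag.io import AnnotationCatalog, GeneSet, InteractionNetwork, OntologyDAG


@pytest.fixture
def path_graph():
    """a - b - c."""
    net = InteractionNetwork()
    net.add_edge("a", "b")
    net.add_edge("b", "c")
    return net


@pytest.fixture
def star_network():
    """Hub h with leaves l1..l5, plus 4 isolated-from-h extra genes.

    10 genes total; the hub's 5 leaves are exactly the genes annotated with
    term t, so the hub's neighborhood is maximally enriched.
    """
    net = InteractionNetwork()
    for i in range(1, 6):
        net.add_edge("h", f"l{i}")
    for i in range(1, 5):
        net.add_edge(f"x{i}", f"x{(i % 4) + 1}")
    return net


@pytest.fixture
def toy_catalog():
    cat = AnnotationCatalog()
    for g in ["l1", "l2", "l3", "l4"]:
        cat.add(g, "GO:T1", "BP")
    cat.add("x1", "GO:T1", "BP")
    for g in ["x2", "x3"]:
        cat.add(g, "hsa001", "KEGG")
    return cat


@pytest.fixture
def diamond_dag():
    """t -> {p1, p2} -> root."""
    dag = OntologyDAG()
    dag.parents = {"t": {"p1", "p2"}, "p1": {"root"}, "p2": {"root"}}
    dag.roots = {"root"}
    return dag


@pytest.fixture
def tiny_corpus():
    """Small synthetic corpus shared by pipeline-level tests."""
    from enrichdag.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(
        n_genes=150,
        n_go_terms=36,
        n_kegg_terms=6,
        n_positives=12,
        n_signal_terms=8,
        p0=0.05,
        p1=0.9,
        mean_degree=6,
        positive_module_extra_degree=6,
        seed=11,
    )
    return generate(cfg)


@pytest.fixture
def separable_blobs():
    """Two well-separated Gaussian blobs, 100 samples, fixed seed."""
    rng = np.random.default_rng(42)
    X = np.vstack([
        rng.normal(-3.0, 0.5, size=(50, 2)),
        rng.normal(3.0, 0.5, size=(50, 2)),
    ])
    y = np.array([0] * 50 + [1] * 50)
    return X, y
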