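"""Seeded generator of a synthetic network + annotation corpus.

Emulates the structure the real pipeline consumes — a sparse protein
interaction network, GO/KEGG-style annotation catalogs, a shallow ontology
and a positive gene list — with a *planted* signal: positive genes are
preferentially wired into a module of "carrier" genes, and the carriers are
annotated with a chosen set of signal terms at an elevated rate p1 while
every other gene-term pair is annotated at a base rate p0.  Positive genes'
neighborhoods therefore over-represent the signal terms, which is exactly
the effect the enrichment encoding is built to detect; setting p1 = p0
yields a null corpus with no planted effect.

Randomness is two-tier: graph wiring and annotation sampling draw from
separate child seeds of the master seed, so either tier can be ablated
without disturbing the other.  All outputs are byte-identical across runs
with the same config.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .io import AnnotationCatalog, GeneSet, InteractionNetwork, OntologyDAG

GO_ROOTS = {"BP": "GO:0008150", "CC": "GO:0005575", "MF": "GO:0003674"}


@dataclass
class SyntheticConfig:
    n_genes: int = 1000
    n_go_terms: int = 270
    n_kegg_terms: int = 30
    n_positives: int = 50
    n_signal_terms: int = 20
    p0: float = 0.05  # base annotation probability
    p1: float = 0.9  # signal-term probability on carrier genes
    mean_degree: float = 8.0
    positive_module_extra_degree: int = 10
    seed: int = 17

    def __post_init__(self) -> None:
        if not (0.0 < self.p0 <= self.p1 <= 1.0):
            raise ValueError(f"need 0 < p0 <= p1 <= 1, got p0={self.p0}, p1={self.p1}")
        if self.n_signal_terms > self.n_go_terms + self.n_kegg_terms:
            raise ValueError("more signal terms than terms")
        if not 0 < self.n_positives < self.n_genes:
            raise ValueError("need 0 < n_positives < n_genes")
        if self.mean_degree <= 0 or self.positive_module_extra_degree < 0:
            raise ValueError("degrees must be positive")


@dataclass
class SyntheticData:
    network: InteractionNetwork
    catalog: AnnotationCatalog
    dag: OntologyDAG
    positives: GeneSet
    negatives_universe: GeneSet
    signal_terms: list[str]
    carriers: list[str]
    config: SyntheticConfig


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:05d}" for i in range(n)]


def _term_ids(cfg: SyntheticConfig) -> tuple[list[str], list[str], dict[str, str]]:
    go = [f"GO:{7000000 + i}" for i in range(cfg.n_go_terms)]
    kegg = [f"hsa{10000 + i}" for i in range(cfg.n_kegg_terms)]
    ns = {}
    for i, t in enumerate(go):
        ns[t] = ("BP", "CC", "MF")[i % 3]
    for t in kegg:
        ns[t] = "KEGG"
    return go, kegg, ns


def _build_ontology(go_terms: list[str], ns_of: dict[str, str], rng: np.random.Generator) -> OntologyDAG:
    """Shallow 2-level DAG: 3 roots, 4 children per root, each GO term under
    one (occasionally two) children of its namespace root."""
    dag = OntologyDAG()
    dag.roots = set(GO_ROOTS.values())
    dag.namespace_of_root = {v: k for k, v in GO_ROOTS.items()}
    children: dict[str, list[str]] = {}
    for i_ns, (ns, root) in enumerate(GO_ROOTS.items()):
        kids = [f"GO:{8000000 + 10 * i_ns + j}" for j in range(4)]
        children[ns] = kids
        for kid in kids:
            dag.parents[kid] = {root}
    for t in go_terms:
        kids = children[ns_of[t]]
        primary = kids[int(rng.integers(len(kids)))]
        dag.parents[t] = {primary}
        if rng.random() < 0.1:  # sparse multiple inheritance
            other = kids[int(rng.integers(len(kids)))]
            dag.parents[t].add(other)
    return dag


def generate(cfg: SyntheticConfig) -> SyntheticData:
    """Build the full synthetic corpus deterministically from ``cfg.seed``."""
    ss = np.random.SeedSequence(cfg.seed)
    s_graph, s_wiring, s_annot, s_choice, s_onto = [
        np.random.default_rng(child) for child in ss.spawn(5)
    ]
    genes = _gene_ids(cfg.n_genes)
    go_terms, kegg_terms, ns_of = _term_ids(cfg)
    all_terms = go_terms + kegg_terms

    # tier 1: background graph + positive-module wiring
    p_edge = min(cfg.mean_degree / (cfg.n_genes - 1), 1.0)
    graph_seed = int(s_graph.integers(2**31))
    g = nx.fast_gnp_random_graph(cfg.n_genes, p_edge, seed=graph_seed)
    net = InteractionNetwork()
    for u, v in g.edges():
        net.add_edge(genes[u], genes[v], int(s_graph.integers(400, 1000)))

    pos_idx = s_choice.choice(cfg.n_genes, size=cfg.n_positives, replace=False)
    pos_set = {genes[i] for i in pos_idx}
    non_pos = [i for i in range(cfg.n_genes) if genes[i] not in pos_set]
    module_size = max(3 * cfg.positive_module_extra_degree, 1)
    carrier_idx = s_choice.choice(len(non_pos), size=min(module_size, len(non_pos)), replace=False)
    carriers = sorted(genes[non_pos[i]] for i in carrier_idx)
    for gi in sorted(pos_idx):
        extra = s_wiring.choice(len(carriers), size=min(cfg.positive_module_extra_degree, len(carriers)),
                                replace=False)
        for ci in extra:
            net.add_edge(genes[gi], carriers[ci], 900)

    # tier 2: annotations — base rate everywhere, elevated on carrier x signal
    signal_pick = s_choice.choice(len(all_terms), size=cfg.n_signal_terms, replace=False)
    signal_terms = sorted(all_terms[i] for i in signal_pick)
    prob = np.full((cfg.n_genes, len(all_terms)), cfg.p0)
    carrier_rows = [genes.index(c) for c in carriers]
    signal_cols = [all_terms.index(t) for t in signal_terms]
    prob[np.ix_(carrier_rows, signal_cols)] = cfg.p1
    hits = s_annot.random((cfg.n_genes, len(all_terms))) < prob
    # every term needs >= 1 annotated gene for a well-formed catalog
    for j in np.flatnonzero(~hits.any(axis=0)):
        hits[int(s_annot.integers(cfg.n_genes)), j] = True

    cat = AnnotationCatalog()
    for i, j in zip(*np.nonzero(hits)):
        cat.add(genes[i], all_terms[j], ns_of[all_terms[j]])

    dag = _build_ontology(go_terms, ns_of, s_onto)
    positives = GeneSet(sorted(pos_set), label="positive")
    negatives_universe = GeneSet([g_ for g_ in genes if g_ not in pos_set], label="unlabeled")
    return SyntheticData(net, cat, dag, positives, negatives_universe, signal_terms, carriers, cfg)


def write_fixture(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit the corpus as the same TSV dialects the loaders read, plus a
    manifest of every parameter and the planted ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = generate(cfg)
    paths = {
        "network": out / "network.tsv",
        "annotations": out / "annotations.tsv",
        "ontology": out / "ontology.tsv",
        "positives": out / "positives.txt",
        "manifest": out / "manifest.json",
    }
    with open(paths["network"], "w") as fh:
        for a, b, score in sorted(data.network.edges()):
            fh.write(f"{a}\t{b}\t{score}\n")
    with open(paths["annotations"], "w") as fh:
        for t in data.catalog.terms:
            for g in sorted(data.catalog.genes_of(t)):
                fh.write(f"{g}\t{t}\t{data.catalog.term_namespace[t]}\n")
    with open(paths["ontology"], "w") as fh:
        root_ns = data.dag.namespace_of_root
        for child in sorted(data.dag.parents):
            for parent in sorted(data.dag.parents[child]):
                ns = root_ns.get(parent)
                if ns is None:
                    grand = next(iter(data.dag.parents[parent]))
                    ns = root_ns[grand]
                fh.write(f"{child}\t{parent}\t{ns}\n")
    with open(paths["positives"], "w") as fh:
        for g in data.positives:
            fh.write(g + "\n")
    manifest = {
        "config": asdict(cfg),
        "signal_terms": data.signal_terms,
        "carriers": data.carriers,
        "n_edges": data.network.n_edges,
        "n_terms": len(data.catalog.terms),
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return paths
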