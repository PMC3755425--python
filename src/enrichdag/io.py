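"""Input parsing and core data containers.

The pipeline consumes four plain-text inputs:

* an undirected protein--protein interaction network as a TSV edge list
  (``gene_a<TAB>gene_b[<TAB>score]``, STRING-style integer confidence 0-999);
* an annotation catalog as a TSV of ``gene<TAB>term[<TAB>namespace]`` rows
  linking genes to GO terms or KEGG pathways;
* an optional ontology parent table ``child<TAB>parent<TAB>namespace``
  describing the GO directed acyclic graph;
* gene lists, one ID per line, ``#`` comments allowed.

Gene and term identifiers are opaque strings; no ID mapping is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

NAMESPACES = ("BP", "CC", "MF", "KEGG")


class ParseError(ValueError):
    """A malformed line in an input file; message carries the line number."""


class EmptyInputError(ValueError):
    """An input file produced no usable records."""


class CyclicOntologyError(ValueError):
    """The ontology parent table contains a cycle."""


class InteractionNetwork:
    """Undirected gene network with integer edge confidence scores.

    Backed by a :class:`networkx.Graph`; self-loops are never stored and an
    edge ``{a, b}`` is queryable from both endpoints.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def add_edge(self, a: str, b: str, score: int = 999) -> None:
        """Add edge keeping the maximum score over duplicates; drop self-loops."""
        if a == b:
            return
        if self._g.has_edge(a, b):
            self._g[a][b]["score"] = max(self._g[a][b]["score"], score)
        else:
            self._g.add_edge(a, b, score=score)

    def edge_score(self, a: str, b: str) -> int:
        return self._g[a][b]["score"]

    def edges(self) -> Iterable[tuple[str, str, int]]:
        for a, b, d in self._g.edges(data=True):
            yield a, b, d["score"]

    def neighbors(self, g: str) -> set[str]:
        """Direct neighbors of ``g``, excluding ``g`` itself.

        Returns the empty set when ``g`` is absent from the network or
        isolated, so callers never need to guard membership first.
        """
        if g not in self._g:
            return set()
        return set(self._g.neighbors(g)) - {g}

    def degree(self, g: str) -> int:
        return len(self.neighbors(g))


@dataclass
class AnnotationCatalog:
    """Bidirectional gene <-> term maps with per-term namespaces."""

    term_to_genes: dict[str, set[str]] = field(default_factory=dict)
    gene_to_terms: dict[str, set[str]] = field(default_factory=dict)
    term_namespace: dict[str, str] = field(default_factory=dict)

    def add(self, gene: str, term: str, namespace: str | None = None) -> None:
        if namespace is None:
            namespace = "BP" if term.upper().startswith("GO") else "KEGG"
        if namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {namespace!r}; expected one of {NAMESPACES}")
        prior = self.term_namespace.setdefault(term, namespace)
        if prior != namespace:
            raise ValueError(f"term {term!r} assigned conflicting namespaces {prior!r}/{namespace!r}")
        self.term_to_genes.setdefault(term, set()).add(gene)
        self.gene_to_terms.setdefault(gene, set()).add(term)

    @property
    def terms(self) -> list[str]:
        """Deterministic term order: GO namespaces first, then KEGG; sorted within."""
        order = {ns: i for i, ns in enumerate(NAMESPACES)}
        return sorted(self.term_to_genes, key=lambda t: (order[self.term_namespace[t]], t))

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_terms)

    def genes_of(self, term: str) -> set[str]:
        return self.term_to_genes.get(term, set())

    def terms_of(self, gene: str) -> set[str]:
        return self.gene_to_terms.get(gene, set())


@dataclass
class OntologyDAG:
    """Term -> parents map plus the namespace roots (terms with no parent)."""

    parents: dict[str, set[str]] = field(default_factory=dict)
    roots: set[str] = field(default_factory=set)
    namespace_of_root: dict[str, str] = field(default_factory=dict)

    def children_of_roots(self) -> dict[str, list[str]]:
        """Direct children of each root, the categories used for term reports."""
        out: dict[str, list[str]] = {r: [] for r in sorted(self.roots)}
        for child, ps in sorted(self.parents.items()):
            for p in ps:
                if p in self.roots:
                    out[p].append(child)
        return out


def ancestors(dag: OntologyDAG, t: str) -> set[str]:
    """All terms reachable from ``t`` by repeated parent steps, excluding ``t``.

    Raises ``KeyError`` for unknown terms and :class:`CyclicOntologyError`
    if the traversal revisits ``t``.
    """
    if t not in dag.parents and t not in dag.roots:
        raise KeyError(t)
    seen: set[str] = set()
    frontier = list(dag.parents.get(t, ()))
    while frontier:
        p = frontier.pop()
        if p == t:
            raise CyclicOntologyError(f"cycle through term {t!r}")
        if p in seen:
            continue
        seen.add(p)
        frontier.extend(dag.parents.get(p, ()))
    return seen


@dataclass
class GeneSet:
    """Ordered, duplicate-free gene list with a class label."""

    ids: list[str]
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({g for g in self.ids if self.ids.count(g) > 1})
            raise ValueError(f"duplicate gene IDs: {dupes}")
        if self.label not in ("positive", "negative", "unlabeled"):
            raise ValueError(f"bad label {self.label!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(self.ids)

    def as_set(self) -> set[str]:
        return set(self.ids)


def _rows(path: str | Path, min_cols: int):
    """Yield (line_number, fields) for non-empty, non-comment TSV lines."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < min_cols:
                raise ParseError(f"{path}:{lineno}: expected >={min_cols} tab-separated fields, got {len(fields)}")
            yield lineno, fields


def read_network(path: str | Path, min_score: int = 0) -> InteractionNetwork:
    """Load a TSV edge list, keeping edges with score >= ``min_score``.

    A missing third column means score 999 (maximal confidence).  Duplicate
    edges collapse to the maximum score before thresholding; self-loops are
    dropped.  An empty result raises :class:`EmptyInputError`.
    """
    best: dict[tuple[str, str], int] = {}
    for lineno, fields in _rows(path, 2):
        a, b = fields[0], fields[1]
        if len(fields) >= 3:
            try:
                score = int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer score {fields[2]!r}") from exc
        else:
            score = 999
        if a == b:
            continue
        key = (a, b) if a < b else (b, a)
        best[key] = max(best.get(key, score), score)
    net = InteractionNetwork()
    for (a, b), score in best.items():
        if score >= min_score:
            net.add_edge(a, b, score)
    if net.n_edges == 0:
        raise EmptyInputError(f"{path}: no edges with score >= {min_score}")
    return net


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, score in sorted(net.edges()):
            fh.write(f"{a}\t{b}\t{score}\n")


def read_annotations(path: str | Path, namespace_map: Mapping[str, str] | None = None) -> AnnotationCatalog:
    """Load a gene-term TSV into an :class:`AnnotationCatalog`.

    A third column, or ``namespace_map``, assigns namespaces; otherwise
    GO-prefixed terms default to BP and everything else to KEGG.
    """
    cat = AnnotationCatalog()
    n = 0
    for _lineno, fields in _rows(path, 2):
        gene, term = fields[0], fields[1]
        ns = fields[2] if len(fields) >= 3 else None
        if ns is None and namespace_map is not None:
            ns = namespace_map.get(term)
        cat.add(gene, term, ns)
        n += 1
    if n == 0:
        raise EmptyInputError(f"{path}: no annotation rows")
    return cat


def read_ontology(path: str | Path) -> OntologyDAG:
    """Load a child-parent TSV into an :class:`OntologyDAG`.

    Roots are the terms that appear only as parents; the third column
    records each row's namespace and labels the roots it reaches.
    """
    dag = OntologyDAG()
    child_ns: dict[str, str] = {}
    for _lineno, fields in _rows(path, 2):
        child, parent = fields[0], fields[1]
        dag.parents.setdefault(child, set()).add(parent)
        if len(fields) >= 3:
            child_ns[child] = fields[2]
    all_parents = {p for ps in dag.parents.values() for p in ps}
    dag.roots = all_parents - set(dag.parents)
    if not dag.roots:
        raise CyclicOntologyError(f"{path}: no root terms; parent table is cyclic")
    for root in dag.roots:
        nss = {child_ns[c] for c, ps in dag.parents.items() if root in ps and c in child_ns}
        if len(nss) == 1:
            dag.namespace_of_root[root] = nss.pop()
    # validate acyclicity / root reachability once at load time
    for term in dag.parents:
        anc = ancestors(dag, term)
        if not anc & dag.roots:
            raise CyclicOntologyError(f"{path}: term {term!r} does not reach a root")
    return dag


def read_gene_list(path: str | Path, label: str = "unlabeled") -> GeneSet:
    ids: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line not in seen:
                seen.add(line)
                ids.append(line)
    if not ids:
        raise EmptyInputError(f"{path}: empty gene list")
    return GeneSet(ids, label)


def write_gene_list(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
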