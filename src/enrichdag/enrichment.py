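"""Network-neighborhood enrichment-score encoding.

A gene's feature value for a GO term or KEGG pathway is the -log10 of the
one-sided hypergeometric tail probability that the gene's *direct network
neighbors* over-represent the term's annotated genes.  With background size
N, K annotated genes in the background, n in-background neighbors and k
annotated neighbors, the raw p-value is P(X >= k) for X ~ Hypergeom(N, K, n)
and the score is -log10(p), capped to keep the matrix finite.  Higher score
means the term is more over-represented around that gene.

The same tail test drives plain gene-*set* enrichment
(:func:`enrich_gene_set`), with Benjamini-Hochberg adjustment across terms.

Conventions: the test is over-representation only (no depletion arm);
annotations are used exactly as listed, with no propagation up the ontology;
the default background universe is every network node carrying at least one
annotation, so the urn contains only genes that could have been drawn.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import AnnotationCatalog, GeneSet, InteractionNetwork

#: -log10 score cap; the smallest positive double has -log10 ~= 307.65.
SCORE_CAP = 300.0


def hypergeometric_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail probability P(X >= k), X ~ Hypergeom(N, K, n).

    N is the background size, K the annotated genes in the background, n the
    number drawn (the neighborhood size) and k the annotated among the drawn.
    Computed through the survival function for numerical stability.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K)):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    # scipy convention: hypergeom(M=population, n=successes, N=draws)
    return float(hypergeom.sf(k - 1, N, K, n))


@dataclass
class FeatureMatrix:
    """Genes x terms grid of enrichment scores with deterministic ordering."""

    genes: list[str]
    features: list[str]
    scores: np.ndarray  # shape (len(genes), len(features)), float
    namespaces: list[str]  # per-feature namespace, aligned with ``features``

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.genes), len(self.features)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.genes)} genes x {len(self.features)} features"
            )
        if len(self.namespaces) != len(self.features):
            raise ValueError("namespaces must align with features")
        if np.any(self.scores < 0) or not np.all(np.isfinite(self.scores)):
            raise ValueError("enrichment scores must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def subset_features(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(
            genes=list(self.genes),
            features=[self.features[i] for i in idx],
            scores=self.scores[:, idx],
            namespaces=[self.namespaces[i] for i in idx],
        )

    def subset_genes(self, gene_ids: Sequence[str]) -> "FeatureMatrix":
        pos = {g: i for i, g in enumerate(self.genes)}
        rows = [pos[g] for g in gene_ids]
        return FeatureMatrix(
            genes=list(gene_ids),
            features=list(self.features),
            scores=self.scores[rows, :],
            namespaces=list(self.namespaces),
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.features) + "\n")
            fh.write("#namespace\t" + "\t".join(self.namespaces) + "\n")
            for g, row in zip(self.genes, self.scores):
                fh.write(g + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            features = header[1:]
            ns_line = fh.readline().rstrip("\n").split("\t")
            if ns_line[0] != "#namespace":
                raise ValueError(f"{path}: missing #namespace line")
            namespaces = ns_line[1:]
            genes, rows = [], []
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                genes.append(fields[0])
                rows.append([float(v) for v in fields[1:]])
        return cls(genes, features, np.array(rows, dtype=float), namespaces)


def default_background(net: InteractionNetwork, cat: AnnotationCatalog) -> list[str]:
    """Network nodes with at least one annotation, sorted for determinism."""
    return sorted(net.nodes & cat.genes)


def enrichment_score(
    net: InteractionNetwork,
    cat: AnnotationCatalog,
    gene: str,
    term: str,
    background: Iterable[str],
    score_cap: float = SCORE_CAP,
) -> float:
    """Enrichment score of one gene for one term; 0 when the gene has no
    in-background neighbors or none of them carries the term."""
    bg = set(background)
    if not bg:
        raise ValueError("background must be nonempty")
    if term not in cat.term_to_genes:
        raise KeyError(term)
    annotated = cat.genes_of(term) & bg
    nbrs = net.neighbors(gene) & bg
    N, K, n = len(bg), len(annotated), len(nbrs)
    k = len(nbrs & annotated)
    p = hypergeometric_tail(N, K, n, k)
    if p <= 0.0:
        return score_cap
    return min(-np.log10(p), score_cap)


def encode_genes(
    net: InteractionNetwork,
    cat: AnnotationCatalog,
    genes: GeneSet | Sequence[str],
    background: Sequence[str] | None = None,
    score_cap: float = SCORE_CAP,
) -> FeatureMatrix:
    """Encode each gene as its vector of per-term enrichment scores.

    One row per input gene (input order preserved), one column per catalog
    term (GO namespaces before KEGG, sorted within).  Genes absent from the
    network, or with no in-background neighbors, get an all-zero row.
    Vectorized: neighbor-annotation overlaps are computed as a boolean
    membership-matrix sum and all per-gene tail probabilities in one
    survival-function call.
    """
    gene_ids = list(genes.ids if isinstance(genes, GeneSet) else genes)
    if not gene_ids:
        raise ValueError("gene set must be nonempty")
    if background is None:
        background = default_background(net, cat)
    bg = list(dict.fromkeys(background))
    bg_index = {g: i for i, g in enumerate(bg)}
    N = len(bg)
    if N == 0:
        raise ValueError("background must be nonempty")

    terms = cat.terms
    namespaces = [cat.term_namespace[t] for t in terms]
    # membership[i, j] == background gene i carries term j
    membership = np.zeros((N, len(terms)), dtype=bool)
    for j, t in enumerate(terms):
        for g in cat.genes_of(t):
            i = bg_index.get(g)
            if i is not None:
                membership[i, j] = True
    K = membership.sum(axis=0)

    scores = np.zeros((len(gene_ids), len(terms)), dtype=float)
    for r, g in enumerate(gene_ids):
        nbr_rows = [bg_index[x] for x in net.neighbors(g) if x in bg_index]
        n = len(nbr_rows)
        if n == 0:
            continue
        k = membership[nbr_rows, :].sum(axis=0)
        p = hypergeom.sf(k - 1, N, K, n)
        with np.errstate(divide="ignore"):
            s = np.where(k > 0, -np.log10(p), 0.0)
        scores[r] = np.clip(np.nan_to_num(s, posinf=score_cap), 0.0, score_cap)
    return FeatureMatrix(gene_ids, terms, scores, namespaces)


@dataclass
class EnrichmentResult:
    """One term's gene-set enrichment record."""

    term: str
    k: int  # overlap between query set and the term's annotated genes
    n: int  # query-set size within the background
    K: int  # annotated genes in the background
    N: int  # background size
    p: float
    p_adjusted: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"inconsistent overlap k={self.k} for n={self.n}, K={self.K}")
        if not (0 < self.p <= 1 and self.p_adjusted >= self.p):
            raise ValueError("invalid p-values")


def enrich_gene_set(
    genes: GeneSet | Sequence[str],
    cat: AnnotationCatalog,
    background: Sequence[str],
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of each term in a query gene set.

    Only terms overlapping the query (k >= 1) are reported; p-values are
    Benjamini-Hochberg adjusted over all tested terms and results are sorted
    by raw p ascending, ties broken by term ID.
    """
    query = list(genes.ids if isinstance(genes, GeneSet) else genes)
    bg = set(background)
    qset = set(query) & bg
    if set(query) - bg:
        missing = sorted(set(query) - bg)
        raise ValueError(f"query genes outside the background: {missing}")
    if not qset:
        return []
    N, n = len(bg), len(qset)
    records = []
    for t in cat.terms:
        annotated = cat.genes_of(t) & bg
        k = len(annotated & qset)
        if k == 0:
            continue
        p = hypergeometric_tail(N, len(annotated), n, k)
        records.append((t, k, len(annotated), p))
    if not records:
        return []
    pvals = np.array([r[3] for r in records])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")
    out = [
        EnrichmentResult(term=t, k=k, n=n, K=K, N=N, p=p, p_adjusted=float(pa))
        for (t, k, K, p), pa in zip(records, p_adj)
    ]
    out.sort(key=lambda r: (r.p, r.term))
    return out


def write_enrichment_results(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tn\tK\tN\tp\tp_adjusted\n")
        for r in results:
            fh.write(f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p:.6g}\t{r.p_adjusted:.6g}\n")
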