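"""Labeled-dataset assembly for imbalanced gene classification.

The study design draws negatives uniformly at random from the gene universe
at a fixed ratio to the positives (1:50 by default), splits the negatives
into ``parts`` disjoint blocks (10 by default), and pairs every block with
the full positive set.  Each resulting dataset therefore shares all
positives, has positive fraction |pos| / (|pos| + |neg|/parts), and the
negative blocks are disjoint and exhaustive across sibling datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .enrichment import FeatureMatrix
from .io import GeneSet


@dataclass
class LabeledDataset:
    """A feature matrix plus aligned binary labels (1 positive, 0 negative)."""

    matrix: FeatureMatrix
    labels: np.ndarray
    dataset_index: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.matrix.genes),):
            raise ValueError("labels must align 1:1 with matrix rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.labels)

    @property
    def positives(self) -> list[str]:
        return [g for g, y in zip(self.matrix.genes, self.labels) if y == 1]

    @property
    def negatives(self) -> list[str]:
        return [g for g, y in zip(self.matrix.genes, self.labels) if y == 0]


def sample_negatives(
    universe: GeneSet | list[str],
    positives: GeneSet | list[str],
    ratio: int = 50,
    seed: int = 0,
) -> GeneSet:
    """Uniform sample without replacement of ratio x |positives| non-positive
    genes; deterministic given ``seed``."""
    uni = list(universe.ids if isinstance(universe, GeneSet) else universe)
    pos = set(positives.ids if isinstance(positives, GeneSet) else positives)
    pool = sorted(set(uni) - pos)
    need = ratio * len(pos)
    if len(pool) < need:
        raise ValueError(
            f"universe too small: need {need} non-positive genes, have {len(pool)} "
            f"(shortfall {need - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=need, replace=False)
    return GeneSet([pool[i] for i in sorted(chosen)], label="negative")


def split_negatives(negatives: GeneSet | list[str], parts: int, seed: int = 0) -> list[list[str]]:
    """Shuffle negatives with ``seed`` and cut into ``parts`` disjoint blocks.

    When the count is not divisible, the remainder genes are assigned one
    each to the first blocks, keeping block sizes within 1 of each other.
    """
    if parts <= 0:
        raise ValueError(f"parts must be positive, got {parts}")
    neg = list(negatives.ids if isinstance(negatives, GeneSet) else negatives)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(neg))
    shuffled = [neg[i] for i in order]
    base, rem = divmod(len(neg), parts)
    blocks, start = [], 0
    for i in range(parts):
        size = base + (1 if i < rem else 0)
        blocks.append(shuffled[start : start + size])
        start += size
    return blocks


def split_into_datasets(
    positives: GeneSet,
    negatives: GeneSet,
    matrix: FeatureMatrix,
    parts: int = 10,
    seed: int = 0,
) -> list[LabeledDataset]:
    """Build ``parts`` datasets, each all positives plus one negative block.

    Row order within a dataset: positives first (input order), then the
    block's negatives (shuffle order).  ``matrix`` must contain every member
    gene; rows are selected from it, so sibling datasets share the positive
    rows bit-for-bit.
    """
    blocks = split_negatives(negatives, parts, seed)
    out = []
    for i, block in enumerate(blocks, start=1):
        members = list(positives.ids) + block
        sub = matrix.subset_genes(members)
        labels = np.array([1] * len(positives.ids) + [0] * len(block), dtype=int)
        out.append(LabeledDataset(matrix=sub, labels=labels, dataset_index=i))
    return out


def write_membership_manifest(datasets: list[LabeledDataset], path: str | Path) -> None:
    """TSV of (gene, label, dataset_index) rows for every dataset member."""
    with open(path, "w") as fh:
        fh.write("gene\tlabel\tdataset_index\n")
        for ds in datasets:
            for g, y in zip(ds.matrix.genes, ds.labels):
                fh.write(f"{g}\t{int(y)}\t{ds.dataset_index}\n")
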