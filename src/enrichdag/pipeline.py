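"""End-to-end orchestration of the prediction workflow.

Binds the stages together in the order the method prescribes:

    encode -> sample/split datasets -> Cramer's V filter -> mRMR rank
           -> incremental feature selection under stratified CV
           -> per-dataset optimal sets -> cross-dataset union

Feature filtering and ranking run independently per dataset, so each
dataset's ranking indices refer to its own surviving-feature matrix; the
union at the end is taken over term IDs, not column indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dagging import DaggingConfig
from .datasets import LabeledDataset, sample_negatives, split_into_datasets
from .enrichment import FeatureMatrix, default_background, encode_genes
from .evaluation import (
    IFSTable,
    MetricsRow,
    OptimalFeatureSet,
    optimal_terms,
    run_ifs,
    summarize_metrics,
    union_optimal,
)
from .io import AnnotationCatalog, GeneSet, InteractionNetwork
from .selection import DiscretizationScheme, RankedFeatures, filter_features, mrmr_rank


@dataclass
class PipelineConfig:
    negative_ratio: int = 50
    n_datasets: int = 10
    cv_threshold: float = 0.1  # Cramer's V cutoff
    top_m: int = 500  # mRMR ranking depth
    d_max: int = 500  # IFS prefix depth
    folds: int = 10
    dagging: DaggingConfig = field(default_factory=DaggingConfig)
    scheme: DiscretizationScheme = field(default_factory=DiscretizationScheme)
    seed: int = 0


@dataclass
class DatasetResult:
    dataset_index: int
    kept_feature_ids: list[str]
    ranked: RankedFeatures
    ifs: IFSTable
    optimal_terms: list[str]

    @property
    def metrics(self) -> MetricsRow:
        return self.ifs.optimal_metrics


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    datasets: list[LabeledDataset]
    per_dataset: list[DatasetResult]
    union: OptimalFeatureSet
    summary: dict[str, tuple[float, float]] | None

    @property
    def metrics_rows(self) -> list[MetricsRow]:
        return [r.metrics for r in self.per_dataset]


def _sub_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def evaluate_dataset(
    ds: LabeledDataset, cfg: PipelineConfig, cv_seed: int
) -> DatasetResult:
    """Filter, rank and run IFS on one labeled dataset."""
    keep = filter_features(ds.matrix, ds.labels, cfg.scheme, cfg.cv_threshold)
    if not keep:
        raise ValueError(f"dataset {ds.dataset_index}: no feature passed the Cramer's V filter")
    filtered = LabeledDataset(
        matrix=ds.matrix.subset_features(keep),
        labels=ds.labels,
        dataset_index=ds.dataset_index,
    )
    ranked = mrmr_rank(filtered.matrix, filtered.labels, cfg.scheme, cfg.top_m)
    table = run_ifs(filtered, ranked, cfg.dagging, cfg.d_max, cfg.folds, cv_seed)
    terms = optimal_terms(table, ranked, filtered.matrix.features)
    return DatasetResult(
        dataset_index=ds.dataset_index,
        kept_feature_ids=list(filtered.matrix.features),
        ranked=ranked,
        ifs=table,
        optimal_terms=terms,
    )


def run_pipeline(
    net: InteractionNetwork,
    cat: AnnotationCatalog,
    positives: GeneSet,
    universe: GeneSet | list[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full workflow and return every intermediate product.

    ``universe`` is the pool negatives are drawn from; by default it is the
    annotated-network background.  All randomness (negative sampling, the
    negative split, fold assignment, subset draws) derives from
    ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    background = default_background(net, cat)
    if universe is None:
        universe = background
    seeds = _sub_seeds(cfg.seed, 2 + cfg.n_datasets)
    negatives = sample_negatives(universe, positives, cfg.negative_ratio, seed=seeds[0])
    members = list(positives.ids) + list(negatives.ids)
    matrix = encode_genes(net, cat, members, background=background)
    datasets = split_into_datasets(positives, negatives, matrix, parts=cfg.n_datasets, seed=seeds[1])
    per_dataset = [
        evaluate_dataset(ds, cfg, seeds[2 + i]) for i, ds in enumerate(datasets)
    ]
    union = union_optimal([r.optimal_terms for r in per_dataset], cat)
    rows = [r.metrics for r in per_dataset]
    summary = summarize_metrics(rows) if len(rows) >= 2 else None
    return PipelineResult(
        matrix=matrix,
        datasets=datasets,
        per_dataset=per_dataset,
        union=union,
        summary=summary,
    )
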