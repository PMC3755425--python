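"""Packaged synthetic study definitions and their summary quantities.

Three named conditions exercise the full pipeline offline:

* **strong** — the default generator config (p0 = 0.05, p1 = 0.9, module
  wiring on): the planted signal is unambiguous, so the pipeline should
  recover the planted terms at the top of the relevance ranking and reach a
  near-perfect cross-validated MCC at the IFS optimum.
* **moderate** — p1 lowered to 0.30 with everything else unchanged: single
  features are weaker, the IFS optimum grows past one feature, and the
  cross-dataset union accumulates a substantial share of the planted set.
* **null** — no planted effect at all: p1 = p0 *and* no module wiring.
  Both tiers matter: keeping the extra positive-module edges with p1 = p0
  still leaks label information through neighborhood size alone, so the
  honest null removes them too.  Cross-validated MCC on the designated
  signal terms should then sit at chance.

Problem sizes are scaled for a single-CPU desk run: 1,000 genes / 300 terms
for the signal conditions with a 1:10 negative ratio over 5 datasets, and
500 genes / 100 terms for each null replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dagging import DaggingConfig
from .datasets import sample_negatives, split_into_datasets
from .enrichment import default_background, encode_genes
from .evaluation import cross_validate
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .synthetic import SyntheticConfig, generate


def strong_config(seed: int = 17) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


def moderate_config(seed: int = 17) -> SyntheticConfig:
    return SyntheticConfig(p1=0.30, seed=seed)


def null_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_genes=800,
        n_go_terms=90,
        n_kegg_terms=10,
        n_positives=60,
        n_signal_terms=10,
        p0=0.05,
        p1=0.05,
        mean_degree=8,
        positive_module_extra_degree=0,
        seed=seed,
    )


def study_pipeline_config(seed: int = 1, n_datasets: int = 5, d_max: int = 30) -> PipelineConfig:
    """Desk-scale pipeline settings for the packaged 1,000-gene corpus."""
    return PipelineConfig(
        negative_ratio=10,
        n_datasets=n_datasets,
        top_m=50,
        d_max=d_max,
        folds=10,
        dagging=DaggingConfig(k=10, seed=seed),
        seed=seed,
    )


@dataclass
class RecoveryStudy:
    result: PipelineResult
    signal_terms: list[str]
    mcc_per_dataset: list[float]
    maxrel_top50_recall_per_dataset: list[float]
    union_recall: float

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.mcc_per_dataset))

    @property
    def min_top50_recall(self) -> float:
        return float(min(self.maxrel_top50_recall_per_dataset))


def run_recovery_study(cfg: SyntheticConfig | None = None, pipeline_seed: int = 1,
                       n_datasets: int = 5, d_max: int = 30) -> RecoveryStudy:
    """Run the full pipeline on a planted-signal corpus and measure recovery.

    Reports, per dataset, the cross-validated MCC at the IFS optimum and the
    fraction of planted terms ranked inside the MaxRel top 50, plus the
    fraction of planted terms present in the cross-dataset optimal union.
    """
    cfg = cfg or strong_config()
    data = generate(cfg)
    pc = study_pipeline_config(pipeline_seed, n_datasets, d_max)
    result = run_pipeline(data.network, data.catalog, data.positives,
                          data.negatives_universe.ids, pc)
    sig = set(data.signal_terms)
    recalls = []
    for r in result.per_dataset:
        top50 = {r.kept_feature_ids[j] for j in r.ranked.maxrel_order[:50]}
        recalls.append(len(sig & top50) / len(sig))
    return RecoveryStudy(
        result=result,
        signal_terms=sorted(sig),
        mcc_per_dataset=[r.metrics.MCC for r in result.per_dataset],
        maxrel_top50_recall_per_dataset=recalls,
        union_recall=len(sig & set(result.union.union)) / len(sig),
    )


def run_null_study(n_seeds: int = 20, seed0: int = 100, cv_seed: int = 0) -> list[float]:
    """Cross-validated MCC on the designated signal terms of a null corpus,
    one replicate per seed.  With no planted effect these should hover at 0."""
    mccs = []
    for i in range(n_seeds):
        data = generate(null_config(seed0 + i))
        bg = default_background(data.network, data.catalog)
        neg = sample_negatives(data.negatives_universe, data.positives, 10, seed=cv_seed + i)
        matrix = encode_genes(data.network, data.catalog,
                              list(data.positives) + list(neg.ids), background=bg)
        ds = split_into_datasets(data.positives, neg, matrix, parts=1, seed=cv_seed + i)[0]
        idx = [matrix.features.index(t) for t in data.signal_terms]
        row = cross_validate(ds, idx, DaggingConfig(seed=cv_seed + i), folds=10, seed=cv_seed + i)
        mccs.append(row.MCC)
    return mccs
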