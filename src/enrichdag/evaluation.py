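"""Classifier evaluation, incremental feature selection and reporting.

Performance is measured from a pooled confusion matrix:

* sensitivity  Sn = TP / (TP + FN)
* specificity  Sp = TN / (TN + FP)
* accuracy     Acc = (TP + TN) / (TP + TN + FP + FN)
* Matthews correlation coefficient
  MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
  defined as 0 when the denominator vanishes.

Cross-validation is stratified and *pooled*: every held-out prediction
across the folds lands in one confusion matrix, so at the 110/550 dataset
geometry Sn and Sp are exact integer ratios.  Incremental feature selection
(IFS) evaluates the top-1, top-2, ... prefixes of the mRMR ranking and
selects the prefix maximizing cross-validated MCC, smallest prefix on ties.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .dagging import DaggingConfig, train_dagging
from .datasets import LabeledDataset
from .io import AnnotationCatalog, OntologyDAG, ancestors
from .selection import RankedFeatures


@dataclass
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsRow:
    Sn: float
    Sp: float
    Acc: float
    MCC: float


def metrics_from_counts(cm: ConfusionMatrix) -> MetricsRow:
    """Sn, Sp, Acc and MCC from integer counts; 0/0 ratios resolve to 0."""
    if cm.total == 0:
        raise ValueError("need at least one evaluated sample")
    tp, tn, fp, fn = (float(v) for v in (cm.TP, cm.TN, cm.FP, cm.FN))
    sn = tp / (tp + fn) if tp + fn > 0 else 0.0
    sp = tn / (tn + fp) if tn + fp > 0 else 0.0
    acc = (tp + tn) / cm.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return MetricsRow(Sn=sn, Sp=sp, Acc=acc, MCC=float(mcc))


def reconstruct_counts(sn: float, sp: float, n_pos: int, n_neg: int) -> ConfusionMatrix:
    """Recover integer TP/TN/FP/FN from rounded Sn/Sp at known class sizes.

    Audit utility for published summary tables: TP = round(sn*n_pos),
    TN = round(sp*n_neg), the complements fill FN and FP.
    """
    if not (0.0 <= sn <= 1.0 and 0.0 <= sp <= 1.0):
        raise ValueError("sn and sp must lie in [0, 1]")
    tp = round(sn * n_pos)
    tn = round(sp * n_neg)
    return ConfusionMatrix(TP=tp, TN=tn, FP=n_neg - tn, FN=n_pos - tp)


#: Published ten-dataset benchmark for this method on the retinoblastoma
#: screen geometry (110 positives / 550 negatives per dataset).  Each row is
#: (dataset_index, optimal_feature_count, Sn, Sp, Acc, MCC); the audit
#: utilities reconstruct the integer confusion matrix from Sn/Sp and check
#: that Acc and MCC are arithmetically consistent.
REFERENCE_BENCHMARK: list[tuple[int, int, float, float, float, float]] = [
    (1, 156, 0.5727, 0.9291, 0.8697, 0.5174),
    (2, 141, 0.6273, 0.9218, 0.8727, 0.5452),
    (3, 337, 0.7364, 0.8691, 0.8470, 0.5347),
    (4, 140, 0.6000, 0.9327, 0.8773, 0.5471),
    (5, 126, 0.5636, 0.9436, 0.8803, 0.5434),
    (6, 489, 0.6273, 0.9255, 0.8758, 0.5527),
    (7, 78, 0.5545, 0.9527, 0.8864, 0.5588),
    (8, 222, 0.6364, 0.9345, 0.8848, 0.5795),
    (9, 319, 0.6545, 0.9218, 0.8773, 0.5663),
    (10, 235, 0.5545, 0.9491, 0.8833, 0.5495),
]
REFERENCE_N_POS = 110
REFERENCE_N_NEG = 550


def reference_benchmark_rows() -> list[MetricsRow]:
    return [MetricsRow(Sn=sn, Sp=sp, Acc=acc, MCC=mcc) for _, _, sn, sp, acc, mcc in REFERENCE_BENCHMARK]


def cross_validate(
    dataset: LabeledDataset,
    feature_idx: Sequence[int],
    cfg: DaggingConfig | None = None,
    folds: int = 10,
    seed: int = 0,
) -> MetricsRow:
    """Stratified k-fold CV of a Dagging model on a feature subset.

    Held-out predictions from all folds are pooled into one confusion
    matrix before computing the metrics.  Fully deterministic given the
    fold seed and the Dagging config seed.
    """
    if folds < 2:
        raise ValueError(f"folds must be >= 2, got {folds}")
    cfg = cfg or DaggingConfig()
    X = dataset.matrix.scores[:, list(feature_idx)]
    y = dataset.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    if counts.min() < folds:
        raise ValueError(f"minority class has {counts.min()} samples; cannot stratify into {folds} folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    tp = tn = fp = fn = 0
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        fold_cfg = DaggingConfig(k=cfg.k, C=cfg.C, seed=cfg.seed + fold)
        model = train_dagging(X[train_idx], y[train_idx], fold_cfg)
        pred = model.predict(X[test_idx])
        truth = y[test_idx]
        tp += int(np.sum((pred == 1) & (truth == 1)))
        tn += int(np.sum((pred == 0) & (truth == 0)))
        fp += int(np.sum((pred == 1) & (truth == 0)))
        fn += int(np.sum((pred == 0) & (truth == 1)))
    cm = ConfusionMatrix(TP=tp, TN=tn, FP=fp, FN=fn)
    assert cm.total == len(y), "pooled confusion matrix must cover every sample exactly once"
    return metrics_from_counts(cm)


@dataclass
class IFSRecord:
    d: int
    metrics: MetricsRow


@dataclass
class IFSTable:
    records: list[IFSRecord]
    optimal_d: int

    @property
    def optimal_metrics(self) -> MetricsRow:
        return next(r.metrics for r in self.records if r.d == self.optimal_d)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("d,Sn,Sp,Acc,MCC\n")
            for r in self.records:
                m = r.metrics
                fh.write(f"{r.d},{m.Sn:.4f},{m.Sp:.4f},{m.Acc:.4f},{m.MCC:.4f}\n")


def run_ifs(
    dataset: LabeledDataset,
    ranked: RankedFeatures,
    cfg: DaggingConfig | None = None,
    D_max: int = 500,
    folds: int = 10,
    seed: int = 0,
) -> IFSTable:
    """Evaluate the top-d mRMR prefixes for d = 1..D_max and pick the MCC
    argmax (smallest d on ties)."""
    D_max = min(D_max, len(ranked.mrmr_order))
    if D_max < 1:
        raise ValueError("ranking is empty")
    records = []
    for d in range(1, D_max + 1):
        m = cross_validate(dataset, ranked.mrmr_order[:d], cfg, folds, seed)
        records.append(IFSRecord(d=d, metrics=m))
    best = max(records, key=lambda r: (r.metrics.MCC, -r.d))
    return IFSTable(records=records, optimal_d=best.d)


def plot_ifs_curve(table: IFSTable, path: str | Path, title: str = "IFS curve") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ds = [r.d for r in table.records]
    mccs = [r.metrics.MCC for r in table.records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(ds, mccs, lw=1)
    ax.axvline(table.optimal_d, color="red", ls="--", lw=0.8,
               label=f"optimal d = {table.optimal_d}")
    ax.set_xlabel("number of top-ranked features")
    ax.set_ylabel("MCC (10-fold CV)")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass
class OptimalFeatureSet:
    """Per-dataset optimal feature lists and their cross-dataset union."""

    per_dataset: list[list[str]]
    union: list[str]
    namespace_counts: dict[str, int] = field(default_factory=dict)


def optimal_terms(table: IFSTable, ranked: RankedFeatures, feature_ids: Sequence[str]) -> list[str]:
    """Term IDs of one dataset's optimal prefix, in ranking order."""
    return [feature_ids[j] for j in ranked.mrmr_order[: table.optimal_d]]


def union_optimal(per_dataset_terms: Sequence[Sequence[str]], cat: AnnotationCatalog) -> OptimalFeatureSet:
    """Set union of the per-dataset optimal feature lists with namespace
    tallies (e.g. how many GO terms vs KEGG pathways made the final set)."""
    if not per_dataset_terms:
        raise ValueError("need at least one dataset")
    union = sorted({t for terms in per_dataset_terms for t in terms})
    counts: dict[str, int] = {}
    for t in union:
        ns = cat.term_namespace.get(t, "unknown")
        counts[ns] = counts.get(ns, 0) + 1
    assert sum(counts.values()) == len(union)
    return OptimalFeatureSet(
        per_dataset=[list(t) for t in per_dataset_terms],
        union=union,
        namespace_counts=counts,
    )


def summarize_metrics(rows: Sequence[MetricsRow]) -> dict[str, tuple[float, float]]:
    """Mean and (n-1)-denominator sd of each metric across datasets."""
    if len(rows) < 2:
        raise ValueError("need >= 2 rows for a sample standard deviation")
    out = {}
    for name in ("Sn", "Sp", "Acc", "MCC"):
        vals = np.array([getattr(r, name) for r in rows])
        out[name] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def write_summary_csv(rows: Sequence[MetricsRow], path: str | Path,
                      optimal_d: Sequence[int] | None = None) -> None:
    summary = summarize_metrics(rows)
    with open(path, "w") as fh:
        fh.write("dataset,optimal_d,Sn,Sp,Acc,MCC\n")
        for i, r in enumerate(rows, start=1):
            d = optimal_d[i - 1] if optimal_d else ""
            fh.write(f"{i},{d},{r.Sn:.4f},{r.Sp:.4f},{r.Acc:.4f},{r.MCC:.4f}\n")
        fh.write("mean,," + ",".join(f"{summary[k][0]:.4f}" for k in ("Sn", "Sp", "Acc", "MCC")) + "\n")
        fh.write("sd,," + ",".join(f"{summary[k][1]:.4f}" for k in ("Sn", "Sp", "Acc", "MCC")) + "\n")


@dataclass
class CategoryRow:
    root: str
    child: str
    frequency: int
    category_size: int
    percentage: float


def term_category_report(
    selected: Sequence[str], dag: OntologyDAG, include_unknown: bool = False
) -> list[CategoryRow]:
    """Frequency and percentage of selected terms per root-child category.

    A category is one direct child c of a namespace root together with every
    ontology term having c among its ancestors; a selected term counts
    toward every category it descends from (DAG multiple inheritance).  The
    percentage denominator is the category's size over the whole ontology,
    not just the encoded features.
    """
    all_terms = set(dag.parents) | dag.roots
    known = [t for t in selected if t in all_terms]
    anc_cache = {t: ancestors(dag, t) for t in all_terms}
    rows = []
    for root, children in dag.children_of_roots().items():
        for child in children:
            members = {t for t in all_terms if t == child or child in anc_cache[t]}
            freq = sum(1 for t in known if t in members)
            pct = 100.0 * freq / len(members) if members else 0.0
            rows.append(CategoryRow(root=root, child=child, frequency=freq,
                                    category_size=len(members), percentage=pct))
    if include_unknown:
        unknown = [t for t in selected if t not in all_terms]
        if unknown:
            rows.append(CategoryRow(root="(none)", child="(unknown)", frequency=len(unknown),
                                    category_size=0, percentage=0.0))
    return rows


def write_category_report(rows: Sequence[CategoryRow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("root\tchild\tfrequency\tcategory_size\tpercentage\n")
        for r in rows:
            fh.write(f"{r.root}\t{r.child}\t{r.frequency}\t{r.category_size}\t{r.percentage:.2f}\n")
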