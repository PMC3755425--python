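"""Feature reduction and ranking.

Two stages sit between encoding and classification:

1. **Cramer's V filter** — each feature, discretized to three states, is
   tested for association with the class label through the chi-square-based
   Cramer's V coefficient; features below a threshold (0.1 by default) are
   dropped.
2. **mRMR ranking** — surviving features are ranked by minimum-redundancy
   maximum-relevance: greedy selection maximizing mutual information with
   the class minus the mean mutual information with already-selected
   features (the MID, difference, variant).  The pure relevance sort is kept
   alongside as the MaxRel order.

Both stages share one discretization scheme (three states split at
mean +- t*sd per feature) because mutual information and the contingency
test both need categorical inputs; the scores themselves are continuous.
Mutual information is plug-in (empirical joint distribution) in log base 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import chi2_contingency

from .enrichment import FeatureMatrix


@dataclass
class DiscretizationScheme:
    """Column-wise three-state binning at mean +- t * sample sd."""

    t: float = 1.0

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"threshold multiplier must be positive, got {self.t}")


def discretize(values: Sequence[float] | np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Map a real vector to states {-1, 0, +1} around its own mean +- t*sd.

    A constant vector (sd = 0) maps to all zeros.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot discretize an empty vector")
    mu = v.mean()
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0.0:
        return np.zeros(v.size, dtype=int)
    out = np.zeros(v.size, dtype=int)
    out[v < mu - scheme.t * sd] = -1
    out[v > mu + scheme.t * sd] = 1
    return out


def discretize_matrix(m: FeatureMatrix, scheme: DiscretizationScheme) -> np.ndarray:
    return np.column_stack([discretize(m.scores[:, j], scheme) for j in range(m.shape[1])])


def cramers_v(x: Sequence[int] | np.ndarray, y: Sequence[int] | np.ndarray) -> float:
    """Cramer's V = sqrt(chi2 / (n * min(r-1, c-1))) on the (x, y) table.

    Empty rows/columns are dropped before the chi-square statistic; if
    either variable then has a single observed category the association is
    undefined and 0 is returned.  No continuity correction is applied.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("need at least one sample")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    r, c = xi.max() + 1, yi.max() + 1
    if r < 2 or c < 2:
        return 0.0
    table = np.zeros((r, c), dtype=int)
    np.add.at(table, (xi, yi), 1)
    chi2 = chi2_contingency(table, correction=False)[0]
    n = x.size
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


def filter_features(
    m: FeatureMatrix,
    labels: np.ndarray,
    scheme: DiscretizationScheme | None = None,
    threshold: float = 0.1,
) -> list[int]:
    """Indices of features whose discretized Cramer's V with the labels is
    >= ``threshold``; original feature order preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    scheme = scheme or DiscretizationScheme()
    labels = np.asarray(labels)
    keep = []
    for j in range(m.shape[1]):
        if cramers_v(discretize(m.scores[:, j], scheme), labels) >= threshold:
            keep.append(j)
    return keep


def mutual_information(x: Sequence[int] | np.ndarray, y: Sequence[int] | np.ndarray) -> float:
    """Plug-in mutual information of two categorical vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size == 0:
        raise ValueError("need at least one sample")
    xi = np.unique(x, return_inverse=True)[1]
    yi = np.unique(y, return_inverse=True)[1]
    joint = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(joint, (xi, yi), 1.0)
    joint /= x.size
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


@dataclass
class RankedFeatures:
    """MaxRel and mRMR orderings over a (filtered) feature matrix.

    Orders hold column indices into the matrix they were computed from.
    ``maxrel_order`` is the full relevance sort; ``mrmr_order`` holds the
    first ``top_m`` greedy picks.  By construction the two orders start with
    the same feature.
    """

    maxrel_order: list[int]
    mrmr_order: list[int]
    relevance: np.ndarray = field(repr=False)
    mrmr_scores: list[float] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.mrmr_order and self.maxrel_order and self.mrmr_order[0] != self.maxrel_order[0]:
            raise ValueError("mRMR must start from the most relevant feature")


def mrmr_rank(
    m: FeatureMatrix,
    labels: np.ndarray,
    scheme: DiscretizationScheme | None = None,
    top_m: int = 500,
) -> RankedFeatures:
    """Greedy MID ranking: pick argmax [I(f;c) - mean_{s in S} I(f;s)].

    The first pick maximizes relevance alone; ties always break toward the
    lower original column index, making the ranking fully deterministic.
    """
    if top_m < 1:
        raise ValueError(f"top_m must be >= 1, got {top_m}")
    scheme = scheme or DiscretizationScheme()
    labels = np.asarray(labels)
    disc = discretize_matrix(m, scheme)
    n_feat = disc.shape[1]
    relevance = np.array([mutual_information(disc[:, j], labels) for j in range(n_feat)])

    # stable sort on -relevance keeps lower index first among ties
    maxrel_order = list(np.argsort(-relevance, kind="stable"))

    n_pick = min(top_m, n_feat)
    selected: list[int] = []
    scores: list[float] = []
    red_sum = np.zeros(n_feat)
    remaining = np.ones(n_feat, dtype=bool)
    for step in range(n_pick):
        if step == 0:
            crit = relevance.copy()
        else:
            crit = relevance - red_sum / len(selected)
        crit = np.where(remaining, crit, -np.inf)
        best = int(np.argmax(crit))  # argmax returns the first (lowest) index on ties
        selected.append(best)
        scores.append(float(crit[best]))
        remaining[best] = False
        if step < n_pick - 1:
            col = disc[:, best]
            for j in np.flatnonzero(remaining):
                red_sum[j] += mutual_information(disc[:, j], col)
    return RankedFeatures(
        maxrel_order=[int(i) for i in maxrel_order],
        mrmr_order=selected,
        relevance=relevance,
        mrmr_scores=scores,
    )


def write_ranking_tables(
    ranked: RankedFeatures, feature_ids: Sequence[str], maxrel_path: str | Path, mrmr_path: str | Path
) -> None:
    """MaxRel and mRMR tables as TSV (rank, feature_id, score)."""
    with open(maxrel_path, "w") as fh:
        fh.write("rank\tfeature_id\trelevance_bits\n")
        for r, j in enumerate(ranked.maxrel_order, start=1):
            fh.write(f"{r}\t{feature_ids[j]}\t{ranked.relevance[j]:.6f}\n")
    with open(mrmr_path, "w") as fh:
        fh.write("rank\tfeature_id\tmid_score\n")
        for r, (j, s) in enumerate(zip(ranked.mrmr_order, ranked.mrmr_scores), start=1):
            fh.write(f"{r}\t{feature_ids[j]}\t{s:.6f}\n")
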