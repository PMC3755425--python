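"""Dagging: a disjoint-subsample majority-vote ensemble.

From a training set of n samples, k disjoint subsets of size n' = floor(n/k)
are drawn without replacement (k*n' <= n; the n mod k leftovers are unused).
One base classifier is fitted per subset and a query is labeled by majority
vote over the k hard predictions, ties going to the negative class.

The base learner is a linear soft-margin maximum-margin classifier (libsvm's
sequential-minimal-optimization solver, C = 1 by default) trained on
features standardized with the full training slice's mean and sd.  A subset
that happens to contain a single class contributes a constant vote for that
class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.svm import SVC


@dataclass
class DaggingConfig:
    k: int = 10
    C: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.C <= 0:
            raise ValueError(f"C must be positive, got {self.C}")


class _ConstantMember:
    """Degenerate member for a single-class subset: always votes that class."""

    def __init__(self, label: int) -> None:
        self.label = int(label)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.label, dtype=int)


def make_disjoint_subsets(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """A seeded permutation of 0..n-1 cut into k blocks of size floor(n/k)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k:
        raise ValueError(f"cannot cut {n} samples into {k} disjoint non-empty subsets")
    size = n // k
    perm = np.random.default_rng(seed).permutation(n)
    return [perm[i * size : (i + 1) * size] for i in range(k)]


@dataclass
class DaggingModel:
    members: list = field(repr=False)
    feature_ids: list[str]
    mean: np.ndarray = field(repr=False)
    sd: np.ndarray = field(repr=False)
    config: DaggingConfig = field(default_factory=DaggingConfig)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd

    def vote_counts(self, X: np.ndarray) -> np.ndarray:
        """Per-sample positive-vote counts over the ensemble members."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_ids):
            raise ValueError(f"expected {len(self.feature_ids)} features, got {X.shape[1]}")
        Z = self._standardize(X)
        votes = np.zeros(len(Z), dtype=int)
        for m in self.members:
            votes += np.asarray(m.predict(Z), dtype=int)
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Majority-vote labels; an exact tie resolves to the negative class."""
        votes = self.vote_counts(np.atleast_2d(np.asarray(X, dtype=float)))
        return (votes > len(self.members) - votes).astype(int)


def train_dagging(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DaggingConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> DaggingModel:
    """Fit a Dagging ensemble on a training slice.

    Standardization parameters come from the full slice, then each of the k
    disjoint subsets trains one linear SVC member.
    """
    cfg = cfg or DaggingConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("training matrix must be 2-D with at least one feature")
    if len(set(y.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(X.shape[1])]
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0.0] = 1.0
    Z = (X - mean) / sd

    subsets = make_disjoint_subsets(len(y), cfg.k, cfg.seed)
    flat = np.concatenate(subsets) if subsets else np.array([], dtype=int)
    assert len(flat) == len(set(flat.tolist())), "subsets must be pairwise disjoint"

    members = []
    for idx in subsets:
        yi = y[idx]
        if len(set(yi.tolist())) < 2:
            members.append(_ConstantMember(yi[0]))
        else:
            svc = SVC(kernel="linear", C=cfg.C, random_state=cfg.seed)
            svc.fit(Z[idx], yi)
            members.append(svc)
    return DaggingModel(
        members=members,
        feature_ids=list(feature_ids),
        mean=mean,
        sd=sd,
        config=cfg,
    )


def save_model(model: DaggingModel, path: str | Path) -> None:
    """Persist the ensemble as a JSON manifest with per-member weights."""
    members = []
    for m in model.members:
        if isinstance(m, _ConstantMember):
            members.append({"kind": "constant", "label": m.label})
        else:
            members.append(
                {
                    "kind": "linear",
                    "coef": np.asarray(m.coef_).ravel().tolist(),
                    "intercept": float(np.asarray(m.intercept_).ravel()[0]),
                    "classes": np.asarray(m.classes_).tolist(),
                }
            )
    doc = {
        "config": {"k": model.config.k, "C": model.config.C, "seed": model.config.seed},
        "feature_ids": model.feature_ids,
        "mean": model.mean.tolist(),
        "sd": model.sd.tolist(),
        "members": members,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


class _LinearMember:
    """Reloaded linear member: sign of w.x + b mapped back onto the classes."""

    def __init__(self, coef: np.ndarray, intercept: float, classes: list[int]) -> None:
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)
        self.classes = list(classes)

    def predict(self, X: np.ndarray) -> np.ndarray:
        margin = X @ self.coef + self.intercept
        return np.where(margin > 0, self.classes[1], self.classes[0]).astype(int)


def load_model(path: str | Path) -> DaggingModel:
    doc = json.loads(Path(path).read_text())
    members = []
    for m in doc["members"]:
        if m["kind"] == "constant":
            members.append(_ConstantMember(m["label"]))
        else:
            members.append(_LinearMember(m["coef"], m["intercept"], m["classes"]))
    return DaggingModel(
        members=members,
        feature_ids=doc["feature_ids"],
        mean=np.array(doc["mean"], dtype=float),
        sd=np.array(doc["sd"], dtype=float),
        config=DaggingConfig(**doc["config"]),
    )
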