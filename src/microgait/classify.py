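"""One-vs-one SVM voting classification of walkers from gait features.

Each walker contributes feature vectors [cycle, max torso speed, max feet
speed, stride]; one binary RBF-SVM is trained per class pair on a random
fixed-size training subset, and a sample's class is the vote winner over all
C(n_classes, 2) pairwise decisions (ties to the lowest label).

The dataset generator is a synthetic stand-in for a measurement campaign:
per-sample Gaussian jitter on each subject's nominal height and speed, then
the full simulate-whiten-search-track-extract pipeline per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .boulic import WalkParams
from .model import GaitMicroDoppler

__all__ = [
    "TABLE_SUBJECTS",
    "GaitDataset",
    "OvOGaitClassifier",
    "make_gait_dataset",
    "train_ovo",
    "evaluate_protocol",
]

#: Nominal (height [m], speed [m/s]) of the four reference walkers.
TABLE_SUBJECTS: tuple[tuple[float, float], ...] = (
    (1.62, 1.34),
    (1.73, 1.45),
    (1.74, 1.51),
    (1.76, 1.58),
)

FEATURE_NAMES = ("cycle", "max_torso_speed", "max_feet_speed", "stride")


@dataclass
class GaitDataset:
    """Feature matrix (n_samples x 4) with integer subject labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("non-finite features")
        counts = np.bincount(self.y)
        if counts.min() != counts.max():
            raise ValueError("classes must be balanced")

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.y).size)

    @property
    def per_class(self) -> int:
        return int(np.bincount(self.y)[0])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.feature_names))
        df["label"] = self.y
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GaitDataset":
        names = tuple(c for c in df.columns if c != "label")
        return cls(df[list(names)].to_numpy(), df["label"].to_numpy(), names)


def make_gait_dataset(
    subjects: tuple[tuple[float, float], ...] = TABLE_SUBJECTS,
    n_samples: int = 100,
    jitter: float = 0.03,
    seed: int = 0,
    **model_kwargs,
) -> GaitDataset:
    """Simulate ``n_samples`` gait-feature vectors per subject.

    Every sample jitters the subject's nominal height and speed by Gaussian
    noise of relative standard deviation ``jitter``, simulates a fresh walk
    and runs the full extraction pipeline.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for label, (height, speed) in enumerate(subjects):
        for _ in range(n_samples):
            h = height * (1 + jitter * rng.standard_normal())
            v = speed * (1 + jitter * rng.standard_normal())
            params = WalkParams(
                height=h, velocity=v, seed=int(rng.integers(2**31 - 1))
            )
            res = GaitMicroDoppler.from_simulation(params, **model_kwargs).fit()
            rows.append(res.features.as_vector())
            labels.append(label)
    return GaitDataset(np.array(rows), np.array(labels))


@dataclass
class OvOGaitClassifier:
    """One-vs-one voting ensemble of binary SVMs.

    ``pairwise_models`` maps each class pair (i, j), i < j, to a fitted
    scaler+SVC pipeline; prediction gives one vote per pairwise win and
    breaks vote ties toward the lowest class index.
    """

    pairwise_models: dict[tuple[int, int], object] = field(default_factory=dict)
    classes: tuple[int, ...] = ()

    @property
    def n_pairs(self) -> int:
        return len(self.pairwise_models)

    def predict(self, X: np.ndarray, return_votes: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        votes = np.zeros((X.shape[0], len(self.classes)), dtype=int)
        pos = {c: k for k, c in enumerate(self.classes)}
        for (i, j), clf in self.pairwise_models.items():
            pred = clf.predict(X)
            for r, p in enumerate(pred):
                votes[r, pos[int(p)]] += 1
        labels = np.array([self.classes[k] for k in np.argmax(votes, axis=1)])
        return (labels, votes) if return_votes else labels


def train_ovo(
    ds: GaitDataset,
    train_per_class: int = 30,
    seed: int = 0,
    svm_kwargs: dict | None = None,
) -> tuple[OvOGaitClassifier, np.ndarray, np.ndarray]:
    """Train the pairwise SVMs on a random per-class training subset.

    Returns (classifier, train_indices, test_indices); the split is
    reproducible from ``seed``.  Feature standardization is fitted on the
    training fold of each pair only.
    """
    if train_per_class >= ds.per_class:
        raise ValueError("train_per_class must leave samples for testing")
    rng = np.random.default_rng(seed)
    classes = tuple(int(c) for c in np.unique(ds.y))
    train_idx = []
    for c in classes:
        idx = np.flatnonzero(ds.y == c)
        train_idx.append(rng.permutation(idx)[:train_per_class])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.setdiff1d(np.arange(ds.y.size), train_idx)

    kw = {"kernel": "rbf", "C": 1.0, "gamma": "scale"}
    kw.update(svm_kwargs or {})
    models: dict[tuple[int, int], object] = {}
    for i, j in combinations(classes, 2):
        m = np.isin(ds.y[train_idx], (i, j))
        sel = train_idx[m]
        clf = make_pipeline(StandardScaler(), SVC(**kw))
        clf.fit(ds.X[sel], ds.y[sel])
        models[(i, j)] = clf
    return OvOGaitClassifier(models, classes), train_idx, test_idx


def evaluate_protocol(
    ds: GaitDataset,
    train_per_class: int = 30,
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
    svm_kwargs: dict | None = None,
) -> dict:
    """Repeat the random-split train/test protocol once per seed.

    Returns per-seed accuracies, their mean, and the summed confusion matrix
    (rows true, columns predicted).
    """
    n_cls = ds.n_classes
    confusion = np.zeros((n_cls, n_cls), dtype=int)
    accs = []
    for seed in seeds:
        clf, _, test_idx = train_ovo(ds, train_per_class, seed, svm_kwargs)
        pred = clf.predict(ds.X[test_idx])
        truth = ds.y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            confusion[t, p] += 1
    return {
        "accuracies": accs,
        "mean_accuracy": float(np.mean(accs)),
        "confusion": confusion,
    }
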