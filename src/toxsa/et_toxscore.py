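"""Toxicity scoring with an Extremely Randomized Trees ensemble.

The classifier is trained on binary fingerprints with toxicity labels
(1 = toxic, 0 = non-toxic) and emits a Tox-score in [0, 1]: the mean over
trees of each leaf's toxic class fraction, so 0 means a low and 1 a high
probability of being toxic.  Trees are grown on the full learning sample
(no bootstrap) with both the candidate features and cut-points drawn at
random, per the Extra-Trees construction; with log2(1024) = 10 candidate
features per node, 500 trees, depth <= 70 and leaf/split minima of 3 and 19.

Classification applies a tunable cutoff (default 0.58): a molecule is
labeled non-toxic — the positive class — iff its Tox-score <= threshold.

Tree growing is delegated to scikit-learn's ``ExtraTreesClassifier`` with
``bootstrap=False``; its ``predict_proba`` is exactly the mean of per-tree
leaf class fractions, and predictions here are computed tree-by-tree so a
forest can also be assembled from individually trained trees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import ExtraTreesClassifier

from .dataset import LabeledDataset

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.58
TOXIC, NON_TOXIC = 1, 0


def default_k_features(n_bits: int) -> int:
    """Features drawn per node: log2 of the fingerprint length (10 for 1024)."""
    return max(1, int(round(math.log2(n_bits))))


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 500
    k_features: int | None = None  # None -> log2(n_bits) at fit time
    max_depth: int = 70
    min_samples_leaf: int = 3
    min_samples_split: int = 19
    gini_threshold: float = 0.0  # minimum impurity decrease to split
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.k_features is not None and self.k_features < 1:
            raise ValueError("k_features must be >= 1")
        if not self.min_samples_leaf < self.min_samples_split:
            raise ValueError("min_samples_leaf must be < min_samples_split")


@dataclass
class ForestModel:
    """A trained ensemble: either a fitted sklearn forest or a list of trees.

    ``classes`` records the label-encoder mapping of a forest fit (trees
    inside an sklearn ensemble see encoded classes, not the original 0/1
    labels); ``None`` means each tree's own ``classes_`` are the original
    labels, as for individually trained trees.
    """

    trees: list = field(default_factory=list)
    config: ForestConfig | None = None
    n_bits: int = 0
    metadata: dict = field(default_factory=dict)
    classes: list | None = None

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def train_forest(ds: LabeledDataset, config: ForestConfig | None = None) -> ForestModel:
    """Grow the ensemble on the full sample.

    With a single-class training set a warning is emitted and the resulting
    model scores every molecule at that class's constant fraction.
    """
    if len(ds) == 0:
        raise ValueError("empty training set")
    if ds.y is None:
        raise ValueError("toxicity labels required")
    config = config or ForestConfig()
    y = np.asarray(ds.y, dtype=int)
    if not set(np.unique(y).tolist()) <= {0, 1}:
        raise ValueError("toxicity labels must be in {0, 1}")
    if np.unique(y).size < 2:
        logger.warning("single-class training set: model will emit a constant score")
    k = config.k_features or default_k_features(ds.n_bits)
    est = ExtraTreesClassifier(
        n_estimators=config.n_trees,
        max_features=min(k, ds.n_bits),
        max_depth=config.max_depth,
        min_samples_leaf=config.min_samples_leaf,
        min_samples_split=config.min_samples_split,
        min_impurity_decrease=config.gini_threshold,
        bootstrap=False,
        criterion="gini",
        random_state=config.seed,
        n_jobs=1,
    )
    est.fit(ds.X, y)
    meta = dict(ds.meta)
    meta.update(n_train=len(ds), class_counts={
        int(c): int(n) for c, n in zip(*np.unique(y, return_counts=True))
    })
    return ForestModel(list(est.estimators_), config, ds.n_bits, meta,
                       classes=[int(c) for c in est.classes_])


def _tree_toxic_fraction(tree, X: np.ndarray, classes: list | None) -> np.ndarray:
    """Leaf class-fraction of the toxic class for each row."""
    proba = tree.predict_proba(X)
    if classes is None:
        classes = list(tree.classes_)
    if TOXIC in classes:
        return proba[:, classes.index(TOXIC)]
    return np.zeros(X.shape[0])


def predict_toxscore(model: ForestModel, fps: np.ndarray) -> np.ndarray:
    """Tox-score = mean over trees of the leaf toxic fraction; in [0, 1]."""
    X = np.atleast_2d(np.asarray(fps))
    if model.n_bits and X.shape[1] != model.n_bits:
        raise ValueError(
            f"fingerprint width {X.shape[1]} != model width {model.n_bits}"
        )
    scores = np.zeros(X.shape[0])
    for tree in model.trees:
        scores += _tree_toxic_fraction(tree, X, model.classes)
    return scores / model.n_trees


def classify(scores, threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Label molecules from Tox-scores: non-toxic (0) iff score <= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("Tox-scores must lie in [0, 1]")
    return np.where(s <= threshold, NON_TOXIC, TOXIC)
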