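"""Generic learners on similarity-derived inputs: tree ensemble and max-margin.

The tree ensemble (a random forest, K=200 trees, m=3 tried attributes) is fed a
signed-similarity feature vector per molecule: the D=10 largest Tanimoto
similarities to the training set, sorted descending, each multiplied by an
activity coefficient c_j (+1 if that training molecule is active, -1 if not).
Its score is the fraction of tree votes for the active class.

The max-margin learner uses the Tanimoto kernel on fingerprints directly
(symmetric, unit-diagonal and empirically positive semidefinite), with cost and
tolerance picked by an internal 3-fold cross-validated grid search; raw margins
are min-max rescaled to (0, 1) so downstream calibration analysis can bin them.
The signed-similarity features are also available for the margin learner via
``use_features=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .neighbors import FingerprintCollection, TrainingData, neighbor_order


def build_feature_vector(query, train: TrainingData, D: int = 10) -> np.ndarray:
    """Signed top-D similarity features for one query."""
    bits = query.bits if hasattr(query, "bits") else frozenset(query)
    qcol = FingerprintCollection.from_bitsets(
        ["q"], [bits], n_bits=train.fingerprints.matrix.shape[1]
    )
    return build_feature_matrix(qcol, train, D)[0]


def build_feature_matrix(
    queries: FingerprintCollection, train: TrainingData, D: int = 10
) -> np.ndarray:
    """Signed top-D similarity features for a batch of queries.

    Similarities are sorted descending (ties by ascending training-molecule
    id), truncated/zero-padded to length D, and each entry multiplied by +1 or
    -1 according to the matched training molecule's activity.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    sims = queries.tanimoto_to(train.fingerprints)
    order = neighbor_order(sims, train.ids)
    d_eff = min(D, sims.shape[1])
    idx = order[:, :d_eff]
    top = np.take_along_axis(sims, idx, axis=1)
    signs = np.where(train.labels[idx] == 1, 1.0, -1.0)
    feats = np.zeros((sims.shape[0], D))
    feats[:, :d_eff] = top * signs
    return feats


def tanimoto_kernel(a: FingerprintCollection, b: FingerprintCollection) -> np.ndarray:
    return a.tanimoto_to(b)


@dataclass
class TreeEnsembleConfig:
    n_trees: int = 200  # K
    tried_attributes: int = 3  # m ~ sqrt(D)
    feature_length: int = 10  # D

    def __post_init__(self) -> None:
        if self.tried_attributes > self.feature_length:
            raise ValueError("tried_attributes must not exceed feature_length")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")


class TreeEnsembleScorer:
    """Random forest on signed-similarity features; score = active vote fraction."""

    def __init__(self, config: TreeEnsembleConfig | None = None):
        self.config = config or TreeEnsembleConfig()

    def fit(self, train: TrainingData, seed: int = 0) -> "TreeEnsembleScorer":
        if train.labels.min() == train.labels.max():
            raise ValueError("training set must contain both classes")
        self._train = train
        X = build_feature_matrix(train.fingerprints, train, self.config.feature_length)
        self._forest = RandomForestClassifier(
            n_estimators=self.config.n_trees,
            max_features=self.config.tried_attributes,
            random_state=seed,
            n_jobs=1,
        )
        self._forest.fit(X, train.labels)
        return self

    def score(self, queries: FingerprintCollection) -> np.ndarray:
        X = build_feature_matrix(queries, self._train, self.config.feature_length)
        return self._forest.predict_proba(X)[:, 1]


@dataclass
class MaxMarginConfig:
    costs: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0)
    tolerances: tuple[float, ...] = (1e-3, 1e-2, 1e-1)
    cv_folds: int = 3
    use_features: bool = False  # signed-similarity features instead of the kernel
    feature_length: int = 10


class MaxMarginScorer:
    """SVM with a precomputed Tanimoto kernel (default) or signed features.

    Hyperparameters are chosen by an internal stratified 3-fold CV over a small
    cost/tolerance grid, scored by AUC; decision values are min-max rescaled to
    (0, 1) using the training-margin range.
    """

    def __init__(self, config: MaxMarginConfig | None = None):
        self.config = config or MaxMarginConfig()

    def _gram(self, queries: FingerprintCollection) -> np.ndarray:
        if self.config.use_features:
            return build_feature_matrix(queries, self._train, self.config.feature_length)
        return tanimoto_kernel(queries, self._train.fingerprints)

    def fit(self, train: TrainingData, seed: int = 0) -> "MaxMarginScorer":
        y = train.labels
        if y.min() == y.max():
            raise ValueError("training set must contain both classes")
        self._train = train
        K = self._gram(train.fingerprints)
        kernel = "linear" if self.config.use_features else "precomputed"

        best = (-np.inf, self.config.costs[0], self.config.tolerances[0])
        n_splits = min(self.config.cv_folds, int(np.bincount(y).min()))
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            folds = list(skf.split(K, y))
            for cost in self.config.costs:
                for tol in self.config.tolerances:
                    aucs = []
                    for tr, va in folds:
                        Ktr = K[np.ix_(tr, tr)] if kernel == "precomputed" else K[tr]
                        Kva = K[np.ix_(va, tr)] if kernel == "precomputed" else K[va]
                        if y[tr].min() == y[tr].max() or y[va].min() == y[va].max():
                            continue
                        clf = SVC(C=cost, tol=tol, kernel=kernel)
                        clf.fit(Ktr, y[tr])
                        aucs.append(roc_auc_score(y[va], clf.decision_function(Kva)))
                    mean_auc = float(np.mean(aucs)) if aucs else -np.inf
                    if mean_auc > best[0]:
                        best = (mean_auc, cost, tol)
        self.best_cost, self.best_tol = best[1], best[2]

        self._svc = SVC(C=self.best_cost, tol=self.best_tol, kernel=kernel)
        self._svc.fit(K, y)
        margins = self._svc.decision_function(K)
        self._lo = float(margins.min())
        self._hi = float(margins.max())
        return self

    def score(self, queries: FingerprintCollection) -> np.ndarray:
        margins = self._svc.decision_function(self._gram(queries))
        span = self._hi - self._lo
        if span <= 0:
            return np.full(len(margins), 0.5)
        scaled = (margins - self._lo) / span
        # keep strictly inside (0,1) so calibration bins stay well defined
        return np.clip(scaled, 1e-6, 1.0 - 1e-6)
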