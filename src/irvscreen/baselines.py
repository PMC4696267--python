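"""Untrained similarity baselines: MeanSim, MaxSim and kNN.

MeanSim scores a query by its average Tanimoto similarity to all known actives
(rank-identical to similarity-ensemble E-value scoring for a fixed target);
MaxSim by the similarity to the single most similar active; kNN by the active
fraction among the k closest training molecules (actives and inactives alike).
"""

from __future__ import annotations

import numpy as np

from .chem import Fingerprint
from .neighbors import (
    FingerprintCollection,
    TrainingData,
    neighbor_order,
    top_k_neighbors,
)


def _as_collection(fps, n_bits=None) -> FingerprintCollection:
    if isinstance(fps, FingerprintCollection):
        return fps
    return FingerprintCollection.from_bitsets(
        [f"a{i}" for i in range(len(fps))], list(fps), n_bits=n_bits
    )


def _query_sims(query, actives: FingerprintCollection) -> np.ndarray:
    bits = query.bits if isinstance(query, Fingerprint) else frozenset(query)
    n_bits = actives.matrix.shape[1]
    indicator = np.zeros(n_bits, dtype=np.float32)
    indicator[[b for b in bits if 0 <= b < n_bits]] = 1.0
    inter = actives.matrix.dot(indicator).astype(np.float64)
    union = len(bits) + actives.popcounts.astype(np.float64) - inter
    return np.where(union > 0, inter / np.maximum(union, 1), 0.0)


def meansim_score(query, actives) -> float:
    """Arithmetic mean Tanimoto similarity of the query to all known actives."""
    actives = _as_collection(actives)
    if len(actives) == 0:
        raise ValueError("MeanSim requires at least one active molecule")
    return float(_query_sims(query, actives).mean())


def maxsim_score(query, actives) -> tuple[float, str]:
    """Similarity to the most similar known active, plus that active's id
    (ties broken by ascending id) for inspection of the rationale."""
    actives = _as_collection(actives)
    if len(actives) == 0:
        raise ValueError("MaxSim requires at least one active molecule")
    sims = _query_sims(query, actives)
    best = neighbor_order(sims, actives.ids)[0]
    return float(sims[best]), actives.ids[best]


def knn_score(query, train: TrainingData, k: int) -> float:
    """Fraction of actives among the (at most) k nearest training molecules.

    The denominator is min(k, |train|) so that small training sets still yield
    valid proportions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sims = _query_sims(query, train.fingerprints)
    idx, _ = top_k_neighbors(sims, train.ids, k)
    taken = idx[0][idx[0] >= 0]
    if len(taken) == 0:
        return 0.0
    return float(train.labels[taken].sum() / len(taken))


# ---------------------------------------------------------------------------
# batch scorer factories sharing one contract: fit(train, seed) -> score(fps)

class MeanSimScorer:
    """Mean similarity to the training actives; ignores inactives."""

    def fit(self, train: TrainingData, seed: int = 0) -> "MeanSimScorer":
        mask = train.labels == 1
        if not mask.any():
            raise ValueError("MeanSim requires at least one active in training")
        self._actives = train.fingerprints.subset(np.flatnonzero(mask))
        return self

    def score(self, queries: FingerprintCollection) -> np.ndarray:
        return queries.tanimoto_to(self._actives).mean(axis=1)


class MaxSimScorer:
    """Maximum similarity to any training active."""

    def fit(self, train: TrainingData, seed: int = 0) -> "MaxSimScorer":
        mask = train.labels == 1
        if not mask.any():
            raise ValueError("MaxSim requires at least one active in training")
        self._actives = train.fingerprints.subset(np.flatnonzero(mask))
        return self

    def score(self, queries: FingerprintCollection) -> np.ndarray:
        return queries.tanimoto_to(self._actives).max(axis=1)


class KNNScorer:
    """Active fraction among the k nearest training molecules (default k=11)."""

    def __init__(self, k: int = 11):
        self.k = k

    def fit(self, train: TrainingData, seed: int = 0) -> "KNNScorer":
        self._train = train
        return self

    def score(self, queries: FingerprintCollection) -> np.ndarray:
        sims = queries.tanimoto_to(self._train.fingerprints)
        idx, _ = top_k_neighbors(sims, self._train.ids, self.k)
        out = np.empty(len(queries))
        for i, row in enumerate(idx):
            taken = row[row >= 0]
            out[i] = self._train.labels[taken].mean() if len(taken) else 0.0
        return out
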