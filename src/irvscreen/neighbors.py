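"""Similarity lists and k-nearest-neighbor structures.

Every predictor in the package consumes the same neighbor substrate: exhaustive
Tanimoto similarities of a query against a labeled training set, sorted with a
deterministic tie rule (descending similarity, then ascending molecule id).
Datasets are at most a few thousand molecules per target, so similarities are
computed exactly — bulk queries go through one sparse matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse

from .chem import Fingerprint


@dataclass(frozen=True)
class Neighbor:
    neighbor_id: str
    similarity: float
    rank: int  # 1-based position in the similarity-sorted list
    label: int  # binary activity class c_i
    potency_class: int  # 0..3


@dataclass(frozen=True)
class NeighborSet:
    query_id: str
    neighbors: tuple[Neighbor, ...]


class FingerprintCollection:
    """Immutable stack of sparse binary fingerprints with aligned ids."""

    def __init__(self, ids: Sequence[str], matrix: sparse.csr_matrix):
        if matrix.shape[0] != len(ids):
            raise ValueError("ids and matrix rows disagree")
        self.ids = list(ids)
        self.matrix = matrix.astype(np.float32).tocsr()
        self.popcounts = np.asarray(self.matrix.sum(axis=1)).ravel()

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_bitsets(
        cls,
        ids: Sequence[str],
        bitsets: Sequence[frozenset[int] | set[int] | Fingerprint],
        n_bits: int | None = None,
    ) -> "FingerprintCollection":
        sets = [b.bits if isinstance(b, Fingerprint) else b for b in bitsets]
        if n_bits is None:
            n_bits = 1 + max((max(s) for s in sets if s), default=-1)
        rows, cols = [], []
        for i, s in enumerate(sets):
            rows.extend([i] * len(s))
            cols.extend(s)
        data = np.ones(len(rows), dtype=np.float32)
        mat = sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(sets), n_bits), dtype=np.float32
        )
        return cls(ids, mat)

    def bitset(self, i: int) -> frozenset[int]:
        row = self.matrix.getrow(i)
        return frozenset(int(c) for c in row.indices)

    def subset(self, indices: Sequence[int]) -> "FingerprintCollection":
        idx = np.asarray(indices, dtype=int)
        return FingerprintCollection([self.ids[i] for i in idx], self.matrix[idx])

    def tanimoto_to(self, other: "FingerprintCollection") -> np.ndarray:
        """Dense |self| × |other| matrix of pairwise Tanimoto similarities."""
        a, b = self.matrix, other.matrix
        if a.shape[1] != b.shape[1]:
            # fingerprints built against different bit universes: widen both
            n_bits = max(a.shape[1], b.shape[1])
            a = sparse.csr_matrix((a.data, a.indices, a.indptr), shape=(a.shape[0], n_bits))
            b = sparse.csr_matrix((b.data, b.indices, b.indptr), shape=(b.shape[0], n_bits))
        # counts are small integers, exact in float32; divide in float64
        inter = np.asarray((a @ b.T).todense()).astype(np.float64)
        union = (
            self.popcounts.astype(np.float64)[:, None]
            + other.popcounts.astype(np.float64)[None, :]
            - inter
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
        return sim


@dataclass
class TrainingData:
    """Labeled fingerprints for one target: the input every scorer fits on."""

    fingerprints: FingerprintCollection
    labels: np.ndarray  # binary c_i per molecule
    potency_classes: np.ndarray  # 0..3 per molecule

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.potency_classes = np.asarray(self.potency_classes, dtype=int)
        n = len(self.fingerprints)
        if len(self.labels) != n or len(self.potency_classes) != n:
            raise ValueError("labels/potency_classes misaligned with fingerprints")

    @property
    def ids(self) -> list[str]:
        return self.fingerprints.ids

    def __len__(self) -> int:
        return len(self.fingerprints)


def all_similarities(
    query: Fingerprint | frozenset[int],
    train: Sequence[tuple[str, Fingerprint | frozenset[int]]],
) -> list[tuple[str, float]]:
    """One Tanimoto value per training molecule, input order preserved."""
    from .chem import tanimoto

    return [(mol_id, tanimoto(query, fp)) for mol_id, fp in train]


def _id_rank(ids: Sequence[str]) -> np.ndarray:
    """Rank of each id in ascending lexicographic order (tie-break key)."""
    order = np.argsort(np.asarray(ids, dtype=object), kind="stable")
    rank = np.empty(len(ids), dtype=np.int64)
    rank[order] = np.arange(len(ids))
    return rank


def neighbor_order(sims: np.ndarray, ids: Sequence[str]) -> np.ndarray:
    """Argsort of a similarity row/matrix: descending similarity, ascending id."""
    sims = np.asarray(sims, dtype=np.float64)
    rank = _id_rank(ids)
    if sims.ndim == 1:
        return np.lexsort((rank, -sims))
    return np.lexsort((np.broadcast_to(rank, sims.shape), -sims), axis=-1)


def top_k_neighbors(
    sim_matrix: np.ndarray,
    train_ids: Sequence[str],
    k: int,
    exclude: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Top-k training indices and similarities for each query row.

    ``exclude`` is an optional boolean mask (n_query × n_train) of entries to
    drop before ranking (leave-one-out self-exclusion). Rows are padded with
    index -1 / similarity NaN when fewer than k candidates exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    S = np.array(sim_matrix, dtype=np.float64, copy=True)
    if S.ndim == 1:
        S = S[None, :]
    if exclude is not None:
        S[exclude] = -np.inf
    order = neighbor_order(S, train_ids)
    k_eff = min(k, S.shape[1])
    idx = order[:, :k_eff]
    sims = np.take_along_axis(S, idx, axis=1)
    valid = np.isfinite(sims)
    idx = np.where(valid, idx, -1)
    sims = np.where(valid, sims, np.nan)
    return idx, sims


def nearest_neighbors(
    query: Fingerprint | frozenset[int],
    train: TrainingData,
    k: int,
    query_id: str = "query",
    leave_one_out: bool = False,
) -> NeighborSet:
    """The k closest training molecules of one query, as a NeighborSet.

    When ``leave_one_out`` is set, a training molecule whose id equals
    ``query_id`` is excluded (cross-validation folds never contain the query,
    so this matters only in leave-one-out contexts).
    """
    bits = query.bits if isinstance(query, Fingerprint) else frozenset(query)
    n_bits = train.fingerprints.matrix.shape[1]
    # bits outside the training universe cannot intersect anything but still
    # count toward the union, so track the true popcount separately
    indicator = np.zeros(n_bits, dtype=np.float32)
    in_range = [b for b in bits if 0 <= b < n_bits]
    indicator[in_range] = 1.0
    inter = train.fingerprints.matrix.dot(indicator).astype(np.float64)
    union = len(bits) + train.fingerprints.popcounts.astype(np.float64) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(union > 0, inter / np.maximum(union, 1), 0.0)[None, :]
    exclude = None
    if leave_one_out:
        exclude = np.array([[tid == query_id for tid in train.ids]])
    idx, s = top_k_neighbors(sims, train.ids, k, exclude=exclude)
    neighbors = []
    for r, (j, sim) in enumerate(zip(idx[0], s[0]), start=1):
        if j < 0:
            break
        neighbors.append(
            Neighbor(
                neighbor_id=train.ids[j],
                similarity=float(sim),
                rank=r,
                label=int(train.labels[j]),
                potency_class=int(train.potency_classes[j]),
            )
        )
    return NeighborSet(query_id=query_id, neighbors=tuple(neighbors))
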