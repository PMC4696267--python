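"""Assessment protocols: tenfold CV, simulated screens, calibration, t-tests.

Three protocols are provided. (1) Standard tenfold cross-validation per
target: molecules are randomly partitioned into 10 folds, each fold is scored
by a model trained on the other nine, and the pooled held-out scores form one
ranked list per target. (2) Simulated target-prediction screens: the same
per-fold models additionally score a large pool of presumed-inactive random
molecules, emulating the realistic setting where actives are rare. (3)
Training augmentation: random-negative molecules are added to each fold's
training set as inactives (test sets untouched) before protocol (2).

Metrics are the ROC AUC (Mann-Whitney formulation, ties at midrank) and
enrichment — the percentage of true actives recovered within the top N% of the
ranked list (N in {5, 10, 20, 30}). Calibration is assessed by a reliability
curve (bins of width 0.1 over well-learned targets) and methods are compared
by paired t-tests of per-target AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .activity import RANDOM_NEGATIVE_POTENCY_CLASS
from .neighbors import FingerprintCollection, TrainingData, neighbor_order

ENRICHMENT_PERCENTS = (5, 10, 20, 30)


# ---------------------------------------------------------------------------
# metrics

def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability a random active outranks a random inactive; ties count 1/2."""
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def enrichment(
    scores: Sequence[float],
    labels: Sequence[int],
    percent: float,
    ids: Sequence[str] | None = None,
) -> float:
    """Percentage of all true actives found within the top ``percent`` % of the
    score-ranked list (ties broken by ascending id for determinism)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(scores)
    n_actives = int(labels.sum())
    if n_actives == 0:
        raise ValueError("enrichment undefined with zero actives")
    if ids is None:
        ids = [f"{i:09d}" for i in range(n)]
    order = neighbor_order(scores, ids)
    top = order[: math.ceil(percent / 100.0 * n)]
    return 100.0 * float(labels[top].sum()) / n_actives


# ---------------------------------------------------------------------------
# results container

@dataclass
class ScreenResult:
    """Pooled ranked predictions for one target, with summary metrics."""

    target_id: str
    ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    dataset_size: int = 0  # molecules in the underlying target dataset

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        order = neighbor_order(self.scores, self.ids)
        self.ids = [self.ids[i] for i in order]
        self.scores = self.scores[order]
        self.labels = self.labels[order]
        if not self.dataset_size:
            self.dataset_size = len(self.ids)

    @property
    def auc(self) -> float | None:
        try:
            return auc(self.scores, self.labels)
        except ValueError:
            return None

    def enrichment(self, percent: float) -> float | None:
        try:
            return enrichment(self.scores, self.labels, percent, self.ids)
        except ValueError:
            return None


# ---------------------------------------------------------------------------
# fold plans and cross-validation

@dataclass(frozen=True)
class FoldPlan:
    target_id: str
    folds: tuple[tuple[int, ...], ...]  # index partition of the dataset
    valid: bool  # every fold holds >= 1 active and >= 1 inactive


def make_folds(
    labels: Sequence[int], n_folds: int = 10, seed: int = 0, target_id: str = ""
) -> FoldPlan:
    """Random partition into ``n_folds`` folds of sizes differing by at most
    one; flagged invalid when any fold lacks one of the classes (such targets
    are skipped by the protocols, mirroring the minimum-requirement filter)."""
    labels = np.asarray(labels)
    n = len(labels)
    if n < n_folds:
        return FoldPlan(target_id=target_id, folds=(), valid=False)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = tuple(tuple(int(i) for i in fold) for fold in np.array_split(perm, n_folds))
    valid = all(
        labels[list(f)].min() == 0 and labels[list(f)].max() == 1 for f in folds
    )
    return FoldPlan(target_id=target_id, folds=folds, valid=valid)


def augment_training(train: TrainingData, pool: FingerprintCollection) -> TrainingData:
    """Extend a training set with random-pool molecules labeled inactive
    (potency class 3 — the non-binder vote). Test sets are never touched."""
    if len(pool) == 0:
        return train
    overlap = set(train.ids) & set(pool.ids)
    if overlap:
        raise ValueError(f"negative pool overlaps training molecules: {sorted(overlap)[:5]}")
    from scipy import sparse

    n_bits = max(train.fingerprints.matrix.shape[1], pool.matrix.shape[1])
    def widen(m):
        return sparse.csr_matrix((m.data, m.indices, m.indptr), shape=(m.shape[0], n_bits))

    merged = FingerprintCollection(
        list(train.ids) + list(pool.ids),
        sparse.vstack([widen(train.fingerprints.matrix), widen(pool.matrix)]).tocsr(),
    )
    labels = np.concatenate([train.labels, np.zeros(len(pool), dtype=int)])
    potency = np.concatenate(
        [train.potency_classes, np.full(len(pool), RANDOM_NEGATIVE_POTENCY_CLASS, dtype=int)]
    )
    return TrainingData(merged, labels, potency)


@dataclass
class CVRun:
    """One tenfold cross-validation on one target: the plan, the per-fold
    fitted scorers, and the pooled held-out result."""

    plan: FoldPlan
    result: ScreenResult
    fold_scorers: list
    fold_test_indices: list[tuple[int, ...]]


def cross_validate(
    data: TrainingData,
    method_factory: Callable[[], object],
    n_folds: int = 10,
    seed: int = 0,
    target_id: str = "",
    augment_pool: FingerprintCollection | None = None,
) -> CVRun | None:
    """Train on nine folds, score the held-out fold, pool all held-out scores.

    Returns None (with the reason implicit in the invalid plan) when the fold
    plan cannot provide both classes in every fold. ``augment_pool`` molecules
    are added to each fold's *training* set only.
    """
    plan = make_folds(data.labels, n_folds=n_folds, seed=seed, target_id=target_id)
    if not plan.valid:
        return None
    if augment_pool is not None:
        overlap = set(data.ids) & set(augment_pool.ids)
        if overlap:
            raise ValueError("augmentation pool overlaps the target's molecules")
    ids: list[str] = []
    scores: list[float] = []
    labels: list[int] = []
    fold_scorers = []
    for fold in plan.folds:
        test_idx = np.asarray(fold)
        train_idx = np.asarray(sorted(set(range(len(data))) - set(fold)))
        train_fold = TrainingData(
            data.fingerprints.subset(train_idx),
            data.labels[train_idx],
            data.potency_classes[train_idx],
        )
        if augment_pool is not None:
            train_fold = augment_training(train_fold, augment_pool)
        scorer = method_factory().fit(train_fold, seed=seed)
        fold_scorers.append(scorer)
        held_out = data.fingerprints.subset(test_idx)
        s = scorer.score(held_out)
        ids.extend(held_out.ids)
        scores.extend(float(v) for v in s)
        labels.extend(int(v) for v in data.labels[test_idx])
    result = ScreenResult(
        target_id=target_id, ids=ids, scores=np.array(scores), labels=np.array(labels),
        dataset_size=len(data),
    )
    return CVRun(
        plan=plan, result=result, fold_scorers=fold_scorers,
        fold_test_indices=[tuple(f) for f in plan.folds],
    )


def simulated_screen(
    cv_run: CVRun,
    data: TrainingData,
    test_negative_pool: FingerprintCollection,
    negatives_once: bool = False,
) -> ScreenResult:
    """Augment the cross-validation test sets with the random-negative pool.

    The per-fold models from ``cv_run`` are reused: each fold's held-out
    molecules are pooled with the full negative pool scored by that fold's
    model. By default every negative therefore appears once per fold (the fold
    outputs are pooled); with ``negatives_once`` the fold-model scores of each
    negative are averaged so it appears a single time.
    """
    overlap = set(data.ids) & set(test_negative_pool.ids)
    if overlap:
        raise ValueError(f"negative pool overlaps the target dataset: {sorted(overlap)[:5]}")
    if len(test_negative_pool) == 0:
        return cv_run.result
    ids = list(cv_run.result.ids)
    scores = list(cv_run.result.scores)
    labels = list(cv_run.result.labels)
    neg_scores = np.stack(
        [scorer.score(test_negative_pool) for scorer in cv_run.fold_scorers]
    )
    if negatives_once:
        mean_scores = neg_scores.mean(axis=0)
        ids.extend(test_negative_pool.ids)
        scores.extend(float(v) for v in mean_scores)
        labels.extend([0] * len(test_negative_pool))
    else:
        for j, fold_scores in enumerate(neg_scores):
            ids.extend(f"{nid}@fold{j}" for nid in test_negative_pool.ids)
            scores.extend(float(v) for v in fold_scores)
            labels.extend([0] * len(test_negative_pool))
    return ScreenResult(
        target_id=cv_run.result.target_id, ids=ids, scores=np.array(scores),
        labels=np.array(labels), dataset_size=cv_run.result.dataset_size,
    )


# ---------------------------------------------------------------------------
# calibration, comparison, strata

@dataclass(frozen=True)
class ReliabilityBin:
    center: float
    fraction: float | None  # observed active fraction; None for empty bins
    count: int


def reliability_curve(
    results: Sequence[ScreenResult], min_auc: float = 0.90, n_bins: int = 10
) -> list[ReliabilityBin]:
    """Pool predictions from targets whose AUC exceeds ``min_auc``, partition
    the [0,1] score range into ``n_bins`` equal bins, and report each bin's
    observed active fraction. A well-calibrated probabilistic scorer tracks
    the diagonal."""
    scores: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for r in results:
        a = r.auc
        # undefined AUC (single-class target) passes only an inactive filter
        if (a is not None and a > min_auc) or (a is None and min_auc <= 0):
            scores.append(r.scores)
            labels.append(r.labels)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    centers = (edges[:-1] + edges[1:]) / 2
    if not scores:
        return [ReliabilityBin(float(c), None, 0) for c in centers]
    s = np.concatenate(scores)
    y = np.concatenate(labels)
    if s.min() < 0 or s.max() > 1:
        raise ValueError("reliability curve requires scores in [0, 1]")
    which = np.clip(np.digitize(s, edges[1:-1]), 0, n_bins - 1)
    out = []
    for b, c in enumerate(centers):
        mask = which == b
        count = int(mask.sum())
        frac = float(y[mask].mean()) if count else None
        out.append(ReliabilityBin(float(c), frac, count))
    return out


@dataclass(frozen=True)
class PairedComparison:
    n: int
    mean_difference: float
    t: float | None
    p: float
    note: str = ""


def paired_comparison(
    auc_a: dict[str, float], auc_b: dict[str, float]
) -> PairedComparison:
    """Two-sided paired t-test of per-target AUC (method A minus method B)
    over the shared-target intersection."""
    shared = sorted(set(auc_a) & set(auc_b))
    if len(shared) < 2:
        raise ValueError("paired comparison requires at least 2 shared targets")
    a = np.array([auc_a[t] for t in shared])
    b = np.array([auc_b[t] for t in shared])
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return PairedComparison(len(shared), 0.0, None, 1.0, "identical methods")
        return PairedComparison(
            len(shared), float(d.mean()), None, 0.0, "constant nonzero difference"
        )
    t_stat, p = stats.ttest_rel(a, b)
    return PairedComparison(len(shared), float(d.mean()), float(t_stat), float(p))


def size_stratified_report(
    results_by_method: dict[str, list[ScreenResult]],
    thresholds: Sequence[int] = (0, 100, 200),
) -> dict[int, dict[str, dict[str, float | None]]]:
    """Mean AUC/enrichment per method over targets whose dataset size exceeds
    each threshold, plus the fraction of targets on which each method is best
    by AUC (ties split equally). Empty strata are reported as missing (None).
    """
    report: dict[int, dict[str, dict[str, float | None]]] = {}
    methods = list(results_by_method)
    for thr in thresholds:
        stratum: dict[str, dict[str, float | None]] = {}
        per_target_auc: dict[str, dict[str, float]] = {}
        for m in methods:
            rs = [r for r in results_by_method[m] if r.dataset_size > thr]
            if not rs:
                stratum[m] = {"auc_mean": None, "n_targets": 0, "best_fraction": None}
                continue
            aucs = [r.auc for r in rs if r.auc is not None]
            entry: dict[str, float | None] = {
                "auc_mean": float(np.mean(aucs)) if aucs else None,
                "n_targets": len(rs),
            }
            for pct in ENRICHMENT_PERCENTS:
                es = [r.enrichment(pct) for r in rs]
                es = [e for e in es if e is not None]
                entry[f"enrichment_{pct}"] = float(np.mean(es)) if es else None
            stratum[m] = entry
            for r in rs:
                if r.auc is not None:
                    per_target_auc.setdefault(r.target_id, {})[m] = r.auc
        # best-method fractions (ties split equally), over targets seen by all
        wins = {m: 0.0 for m in methods}
        n_scored = 0
        for tid, by_m in per_target_auc.items():
            if len(by_m) != len(methods):
                continue
            n_scored += 1
            best = max(by_m.values())
            winners = [m for m, v in by_m.items() if v == best]
            for m in winners:
                wins[m] += 1.0 / len(winners)
        for m in methods:
            if isinstance(stratum.get(m), dict) and stratum[m].get("n_targets"):
                stratum[m]["best_fraction"] = wins[m] / n_scored if n_scored else None
        report[thr] = stratum
    return report
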