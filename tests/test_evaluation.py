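"""Metrics and protocols: AUC, enrichment, folds, screens, calibration, t-tests."""

import numpy as np
import pytest

import irvscreen as iv
from irvscreen.evaluation import (
    ScreenResult,
    auc,
    augment_training,
    cross_validate,
    enrichment,
    make_folds,
    paired_comparison,
    reliability_curve,
    simulated_screen,
    size_stratified_report,
)
from irvscreen.neighbors import FingerprintCollection, TrainingData
from conftest import random_bitsets


def _brute_force_auc(scores, labels):
    """All-pairs concordance count with ties at 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class ConstantScorer:
    def fit(self, train, seed=0):
        return self

    def score(self, queries):
        return np.full(len(queries), 0.3)


class TestAUC:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
            ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),
            ([0.8, 0.3, 0.5, 0.1], [1, 1, 0, 0], 0.75),
        ],
    )
    def test_known_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    def test_agrees_with_brute_force_including_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 200))
            scores = rng.choice(np.linspace(0, 1, 7), n)  # force heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc(scores, labels) == pytest.approx(
                _brute_force_auc(scores, labels), abs=1e-12
            )

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3.0 * s - 1.0])
    def test_invariant_under_monotone_transforms(self, rng, transform):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        assert auc(transform(scores), labels) == pytest.approx(auc(scores, labels))


class TestEnrichment:
    def test_actives_on_top(self):
        scores = [0.9, 0.8] + [0.1] * 8
        labels = [1, 1] + [0] * 8
        assert enrichment(scores, labels, 20) == 100.0

    def test_actives_at_bottom(self):
        scores = list(np.linspace(1, 0.1, 20))
        labels = [0] * 18 + [1, 1]
        assert enrichment(scores, labels, 5) == 0.0

    def test_partial_recovery(self, rng):
        # 100 molecules, 10 actives, exactly 6 in the top 10
        scores = np.linspace(1.0, 0.01, 100)
        labels = np.zeros(100, dtype=int)
        labels[[0, 1, 2, 3, 4, 5]] = 1
        labels[[50, 60, 70, 80]] = 1
        assert enrichment(scores, labels, 10) == pytest.approx(60.0)

    def test_full_list_recovers_everything(self, rng):
        scores = rng.random(37)
        labels = (rng.random(37) < 0.3).astype(int)
        if labels.sum() == 0:
            labels[0] = 1
        assert enrichment(scores, labels, 100) == 100.0

    def test_zero_actives_undefined(self):
        with pytest.raises(ValueError):
            enrichment([0.1, 0.2], [0, 0], 10)

    def test_brute_force_agreement(self, rng):
        import math

        for _ in range(100):
            n = int(rng.integers(4, 200))
            scores = rng.choice(np.linspace(0, 1, 9), n)
            labels = rng.integers(0, 2, n)
            if labels.sum() == 0:
                continue
            pct = float(rng.choice([5, 10, 20, 30]))
            ids = [f"i{j:04d}" for j in range(n)]
            order = sorted(range(n), key=lambda j: (-scores[j], ids[j]))
            top = order[: math.ceil(pct / 100 * n)]
            expected = 100.0 * sum(labels[j] for j in top) / labels.sum()
            assert enrichment(scores, labels, pct, ids) == pytest.approx(expected)


class TestFolds:
    def test_balanced_partition(self):
        labels = np.array([1, 0] * 50)
        plan = make_folds(labels, n_folds=10, seed=0)
        sizes = [len(f) for f in plan.folds]
        assert sum(sizes) == 100 and max(sizes) - min(sizes) <= 1
        flat = [i for f in plan.folds for i in f]
        assert sorted(flat) == list(range(100))

    def test_pigeonhole_invalidates_sparse_actives(self):
        labels = np.array([1] + [0] * 9)
        plan = make_folds(labels, n_folds=10, seed=0)
        assert not plan.valid

    def test_deterministic(self):
        labels = np.array([1, 0] * 20)
        assert make_folds(labels, seed=4) == make_folds(labels, seed=4)

    def test_too_small_invalid(self):
        assert not make_folds(np.array([1, 0, 1]), n_folds=10).valid


def _clustered_training_data(rng, n_active=30, n_inactive=30):
    actives = [frozenset({0, 1, 2, 3, int(i)}) for i in rng.integers(4, 12, n_active)]
    inactives = [frozenset({40, 41, 42, int(i)}) for i in rng.integers(43, 55, n_inactive)]
    bitsets = actives + inactives
    labels = np.array([1] * n_active + [0] * n_inactive)
    fps = FingerprintCollection.from_bitsets(
        [f"m{i:03d}" for i in range(len(bitsets))], bitsets, n_bits=64
    )
    return TrainingData(fps, labels, np.where(labels == 1, 0, 3))


class TestCrossValidate:
    def test_pooled_predictions_cover_every_molecule_once(self, rng):
        td = _clustered_training_data(rng)
        run = cross_validate(td, lambda: iv.MaxSimScorer(), seed=0, target_id="t")
        assert sorted(run.result.ids) == sorted(td.ids)

    def test_separable_clusters_score_high(self, rng):
        td = _clustered_training_data(rng)
        run = cross_validate(td, lambda: iv.MaxSimScorer(), seed=0, target_id="t")
        assert run.result.auc > 0.9

    def test_constant_scorer_gives_half(self, rng):
        td = _clustered_training_data(rng)
        run = cross_validate(td, ConstantScorer, seed=0, target_id="t")
        assert run.result.auc == pytest.approx(0.5)

    def test_invalid_plan_returns_none(self, rng):
        bitsets = random_bitsets(rng, 12)
        labels = np.array([1] + [0] * 11)
        td = TrainingData(
            FingerprintCollection.from_bitsets([f"m{i}" for i in range(12)], bitsets),
            labels, np.where(labels == 1, 0, 3),
        )
        assert cross_validate(td, ConstantScorer, seed=0) is None


class TestAugmentation:
    def _pool(self, rng, n=20, prefix="rc"):
        return FingerprintCollection.from_bitsets(
            [f"{prefix}{i:03d}" for i in range(n)],
            random_bitsets(rng, n, n_bits=64, density=0.1),
            n_bits=64,
        )

    def test_counts_and_labels(self, rng):
        td = _clustered_training_data(rng)
        pool = self._pool(rng)
        aug = augment_training(td, pool)
        assert len(aug) == len(td) + 20
        assert aug.labels.sum() == td.labels.sum()  # actives conserved
        assert np.all(aug.potency_classes[len(td):] == 3)

    def test_empty_pool_identity(self, rng):
        td = _clustered_training_data(rng)
        assert augment_training(td, self._pool(rng, 0)) is td

    def test_overlap_fatal(self, rng):
        td = _clustered_training_data(rng)
        pool = FingerprintCollection.from_bitsets(
            [td.ids[0]], random_bitsets(rng, 1), n_bits=64
        )
        with pytest.raises(ValueError, match="overlap"):
            augment_training(td, pool)


class TestSimulatedScreen:
    def test_protocol_arithmetic(self, rng):
        td = _clustered_training_data(rng)
        pool = FingerprintCollection.from_bitsets(
            [f"rc{i:04d}" for i in range(50)],
            random_bitsets(rng, 50, n_bits=64, density=0.1),
            n_bits=64,
        )
        run = cross_validate(td, lambda: iv.MaxSimScorer(), seed=0, target_id="t")
        screen = simulated_screen(run, td, pool)
        # each negative scored by each of the 10 fold models and pooled
        assert len(screen.ids) == len(td) + 10 * 50
        once = simulated_screen(run, td, pool, negatives_once=True)
        assert len(once.ids) == len(td) + 50

    def test_empty_pool_degenerates_to_cv(self, rng):
        td = _clustered_training_data(rng)
        run = cross_validate(td, lambda: iv.MaxSimScorer(), seed=0, target_id="t")
        empty = FingerprintCollection.from_bitsets([], [], n_bits=64)
        assert simulated_screen(run, td, empty) is run.result

    def test_pool_overlap_fatal(self, rng):
        td = _clustered_training_data(rng)
        run = cross_validate(td, lambda: iv.MaxSimScorer(), seed=0, target_id="t")
        pool = FingerprintCollection.from_bitsets(
            [td.ids[3]], random_bitsets(rng, 1), n_bits=64
        )
        with pytest.raises(ValueError, match="overlap"):
            simulated_screen(run, td, pool)

    def test_test_sets_untouched_by_augmentation(self, rng):
        td = _clustered_training_data(rng)
        pool = FingerprintCollection.from_bitsets(
            [f"rc{i:03d}" for i in range(30)],
            random_bitsets(rng, 30, n_bits=64, density=0.1),
            n_bits=64,
        )
        run = cross_validate(
            td, lambda: iv.MaxSimScorer(), seed=0, target_id="t", augment_pool=pool
        )
        # held-out predictions still cover exactly the target's molecules
        assert sorted(run.result.ids) == sorted(td.ids)


class TestReliabilityCurve:
    def test_perfectly_calibrated_scores(self, rng):
        scores = rng.random(10_000)
        labels = (rng.random(10_000) < scores).astype(int)
        r = ScreenResult("t", [f"m{i}" for i in range(10_000)], scores, labels)
        bins = reliability_curve([r], min_auc=0.0)
        for b in bins:
            if b.count >= 100:
                assert b.fraction == pytest.approx(b.center, abs=0.03)

    def test_all_high_scores_all_active(self):
        r = ScreenResult("t", ["a", "b"], np.array([0.95, 0.96]), np.array([1, 1]))
        bins = reliability_curve([r], min_auc=0.0)
        assert bins[-1].fraction == 1.0 and bins[-1].count == 2

    def test_uniform_scores_no_actives(self, rng):
        scores = rng.random(500)
        labels = np.zeros(500, dtype=int)
        labels[np.argmax(scores)] = 1  # one active so AUC is defined
        r = ScreenResult("t", [f"m{i}" for i in range(500)], scores, labels)
        for b in reliability_curve([r], min_auc=0.0):
            if b.count and b.center < 0.9:
                assert b.fraction == 0.0

    def test_low_auc_targets_excluded(self, rng):
        scores = rng.random(200)
        labels = rng.integers(0, 2, 200)
        r = ScreenResult("t", [f"m{i}" for i in range(200)], scores, labels)
        bins = reliability_curve([r], min_auc=0.99)
        assert all(b.count == 0 for b in bins)


class TestPairedComparison:
    def test_identical_methods(self):
        a = {f"t{i}": 0.8 for i in range(5)}
        out = paired_comparison(a, dict(a))
        assert out.mean_difference == 0.0 and out.p == 1.0

    def test_consistent_small_advantage_is_significant(self, rng):
        base = {f"t{i}": 0.8 + 0.01 * rng.random() for i in range(50)}
        better = {k: v + 0.02 + rng.normal(0, 1e-4) for k, v in base.items()}
        out = paired_comparison(better, base)
        assert out.mean_difference == pytest.approx(0.02, abs=0.001)
        assert out.p < 0.005

    def test_disjoint_targets_error(self):
        with pytest.raises(ValueError):
            paired_comparison({"a": 0.5, "b": 0.6}, {"c": 0.5, "d": 0.6})

    def test_matches_closed_form_t(self):
        a = {"t1": 0.90, "t2": 0.85, "t3": 0.88}
        b = {"t1": 0.80, "t2": 0.84, "t3": 0.83}
        d = np.array([0.10, 0.01, 0.05])
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        out = paired_comparison(a, b)
        assert out.t == pytest.approx(expected_t)


class TestSizeStratifiedReport:
    def _result(self, tid, auc_target, n, rng):
        # construct a ranked list with approximately the requested AUC
        labels = np.array([1] * (n // 2) + [0] * (n - n // 2))
        scores = np.where(labels == 1, 0.6, 0.4) + rng.normal(0, 0.02, n)
        if auc_target < 0.6:
            scores = rng.random(n)
        return ScreenResult(tid, [f"{tid}m{i}" for i in range(n)], scores, labels)

    def test_mean_over_stratum(self, rng):
        r1 = self._result("t1", 0.9, 60, rng)
        r2 = self._result("t2", 0.9, 160, rng)
        report = size_stratified_report({"m": [r1, r2]}, thresholds=(0, 100))
        assert report[0]["m"]["n_targets"] == 2
        assert report[100]["m"]["n_targets"] == 1
        assert report[0]["m"]["auc_mean"] == pytest.approx(
            np.mean([r1.auc, r2.auc])
        )

    def test_best_fractions_sum_to_one(self, rng):
        results = {
            "a": [self._result(f"t{i}", 0.9, 50, rng) for i in range(4)],
            "b": [self._result(f"t{i}", 0.5, 50, rng) for i in range(4)],
        }
        report = size_stratified_report(results, thresholds=(0,))
        total = report[0]["a"]["best_fraction"] + report[0]["b"]["best_fraction"]
        assert total == pytest.approx(1.0)

    def test_empty_stratum_missing(self, rng):
        report = size_stratified_report(
            {"m": [self._result("t", 0.9, 30, rng)]}, thresholds=(100,)
        )
        assert report[100]["m"]["n_targets"] == 0
        assert report[100]["m"]["auc_mean"] is None
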