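"""End-to-end verification experiments on synthetic corpora.

Each function here runs one self-contained study — equation-level checks
against independently coded references, cross-validated benchmarking of all
scorers, the potency-sensitivity comparison, the random-negative augmentation
effect, and the calibration analysis — and returns plain numbers. They are
used both by the test suite and by the reproduction script.

Problem sizes are chosen so the full set runs in minutes on one CPU: ten
targets of ~100 molecules for benchmarking, twenty replicate corpora for the
potency comparison, and the full 1000/9000 random-negative split for the
simulated screens.
"""

from __future__ import annotations

import math

import numpy as np

from . import evaluation as ev
from .activity import potency_class, split_random_pool
from .baselines import MaxSimScorer, MeanSimScorer
from .chem import tanimoto
from .irv import (
    IRVParameters,
    IRVScorer,
    TrainConfig,
    _build_table,
    _forward,
    initialize_parameters,
    loss_and_gradient,
)
from .ml import MaxMarginScorer, TreeEnsembleScorer
from .neighbors import FingerprintCollection, TrainingData, top_k_neighbors
from .synthetic import (
    clustered_corpus_config,
    generate_corpus,
    potency_graded_config,
)


# ---------------------------------------------------------------------------
# equation-level checks

def forward_example_error() -> float:
    """Deviation of the network forward pass from a scalar hand evaluation of
    the two-neighbor case: neighbors (s=0.8, active) and (s=0.3, inactive),
    w_y=0, w_s=2, w_r=0, votes (-1, +1), w_z=0."""
    from .irv import _NeighborTable

    params = IRVParameters(w_z=0.0, w_y=0.0, w_s=2.0, w_r=0.0, votes=(-1.0, 1.0), k=2)
    table = _NeighborTable(
        sims=np.array([[0.8, 0.3]]),
        ranks=np.array([[1.0, 2.0]]),
        vote_idx=np.array([[1, 0]]),
        valid=np.ones((1, 2), dtype=bool),
        neighbor_ids=[["n1", "n2"]],
    )
    z_impl = float(_forward(table, params)[0][0])
    # independent scalar route
    logit = math.tanh(0.0 + 2.0 * 0.8 + 0.0 * 1.0) * 1.0 + math.tanh(2.0 * 0.3) * -1.0
    z_oracle = 1.0 / (1.0 + math.exp(-logit))
    return abs(z_impl - z_oracle)


def potency_vote_routing_error() -> float:
    """Check the potency-vote branch boundaries at EC50 = 1, 5 and 10 µM
    (and interior points) against the branch table; returns the worst
    absolute vote error."""
    votes = (4.0, 3.0, 2.0, 1.0)
    params = IRVParameters(0.0, 0.0, 0.0, 0.0, votes=votes, k=6, mode="potency")
    expected = {0.5: 4.0, 0.999: 4.0, 1.0: 3.0, 4.9: 3.0, 5.0: 2.0, 9.99: 2.0,
                10.0: 1.0, 12.0: 1.0, 1000.0: 1.0}
    worst = 0.0
    for ec50, want in expected.items():
        got = params.votes[potency_class(ec50)]
        worst = max(worst, abs(got - want))
    return worst


def gradient_check(seed: int, n_molecules: int = 20) -> float:
    """Max |analytic - central finite difference| over all weights, both vote
    modes, on a random labeled fingerprint set."""
    rng = np.random.default_rng(seed)
    bitsets = [
        frozenset(int(i) for i in np.flatnonzero(rng.random(64) < 0.2))
        for _ in range(n_molecules)
    ]
    fps = FingerprintCollection.from_bitsets(
        [f"m{i:02d}" for i in range(n_molecules)], bitsets, n_bits=64
    )
    labels = rng.integers(0, 2, n_molecules)
    labels[0], labels[1] = 0, 1
    td = TrainingData(fps, labels, rng.integers(0, 4, n_molecules))
    t = labels.astype(float)
    eps = 1e-5
    worst = 0.0
    for mode in ("standard", "potency"):
        params = initialize_parameters(mode, k=6, seed=seed)
        flat = params.flat() + rng.normal(0, 0.3, params.flat().size)
        params = IRVParameters.from_flat(flat, 6, mode)
        table = _build_table(fps, td, params, leave_one_out=True)
        _, grad = loss_and_gradient(table, t, params)
        for j in range(len(flat)):
            up, dn = flat.copy(), flat.copy()
            up[j] += eps
            dn[j] -= eps
            lu, _ = loss_and_gradient(table, t, IRVParameters.from_flat(up, 6, mode))
            ld, _ = loss_and_gradient(table, t, IRVParameters.from_flat(dn, 6, mode))
            worst = max(worst, abs(grad[j] - (lu - ld) / (2 * eps)))
    return worst


# ---------------------------------------------------------------------------
# brute-force oracle equivalence

def _brute_auc(scores, labels) -> float:
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return total / (len(pos) * len(neg))


def oracle_equivalence(seed: int, n_instances: int = 100) -> dict[str, float]:
    """Max discrepancy between the vectorized implementations and naive
    per-pair / full-sort / pair-count references over random instances of
    size up to 200."""
    rng = np.random.default_rng(seed)
    worst = {"tanimoto": 0.0, "nearest_neighbors": 0.0, "auc": 0.0, "enrichment": 0.0}
    for _ in range(n_instances):
        n = int(rng.integers(5, 201))
        bitsets = [
            frozenset(int(i) for i in np.flatnonzero(rng.random(32) < 0.3))
            for _ in range(min(n, 40))
        ]
        ids = [f"m{i:03d}" for i in range(len(bitsets))]
        coll = FingerprintCollection.from_bitsets(ids, bitsets, n_bits=32)
        M = coll.tanimoto_to(coll)
        for i in range(len(bitsets)):
            for j in range(0, len(bitsets), 7):
                worst["tanimoto"] = max(
                    worst["tanimoto"], abs(M[i, j] - tanimoto(bitsets[i], bitsets[j]))
                )
        k = int(rng.integers(1, 9))
        idx, s = top_k_neighbors(M[:1], ids, k)
        brute = sorted(
            zip(M[0], ids), key=lambda t: (-t[0], t[1])
        )[:k]
        for col, (bs, bid) in enumerate(brute):
            worst["nearest_neighbors"] = max(
                worst["nearest_neighbors"],
                abs(s[0, col] - bs) + (0.0 if ids[idx[0, col]] == bid else 1.0),
            )
        scores = rng.choice(np.linspace(0, 1, 7), n)
        labels = rng.integers(0, 2, n)
        if 0 < labels.sum() < n:
            worst["auc"] = max(
                worst["auc"], abs(ev.auc(scores, labels) - _brute_auc(scores, labels))
            )
        if labels.sum() > 0:
            pct = float(rng.choice([5, 10, 20, 30]))
            eids = [f"e{j:04d}" for j in range(n)]
            order = sorted(range(n), key=lambda j: (-scores[j], eids[j]))
            top = order[: math.ceil(pct / 100 * n)]
            brute_enr = 100.0 * sum(labels[j] for j in top) / labels.sum()
            worst["enrichment"] = max(
                worst["enrichment"],
                abs(ev.enrichment(scores, labels, pct, eids) - brute_enr),
            )
    return worst


# ---------------------------------------------------------------------------
# benchmark protocols

BENCHMARK_METHODS = {
    "meansim": lambda: MeanSimScorer(),
    "maxsim": lambda: MaxSimScorer(),
    "irv": lambda: IRVScorer(mode="standard", k=6),
    "psirv": lambda: IRVScorer(mode="potency", k=6),
    "tree": lambda: TreeEnsembleScorer(),
    "margin": lambda: MaxMarginScorer(),
}


def benchmark_cross_validation(
    seed: int, cutoff: float = 10.0, methods: dict | None = None
) -> dict[str, float]:
    """Tenfold-CV mean AUC per method on the standard clustered benchmark
    corpus (10 targets, 50 actives + 50 in-assay inactives each)."""
    corpus = generate_corpus(clustered_corpus_config(seed=seed))
    methods = methods or BENCHMARK_METHODS
    out: dict[str, float] = {}
    for name, factory in methods.items():
        aucs = []
        for tgt in corpus.targets:
            td = tgt.training_data(cutoff)
            run = ev.cross_validate(td, factory, seed=seed, target_id=tgt.target_id)
            if run is not None and run.result.auc is not None:
                aucs.append(run.result.auc)
        out[name] = float(np.mean(aucs))
    return out


def potency_sensitivity_comparison(
    seed: int, n_replicates: int = 20, cutoff: float = 5.0
) -> dict[str, float]:
    """IRV vs PS-IRV mean tenfold-CV AUC over replicate potency-graded corpora,
    with a paired t-test of the per-replicate means."""
    irv_means, ps_means = [], []
    for rep in range(n_replicates):
        corpus = generate_corpus(potency_graded_config(seed=seed + 1000 * rep + 1))
        a_irv, a_ps = [], []
        for tgt in corpus.targets:
            td = tgt.training_data(cutoff)
            r1 = ev.cross_validate(
                td, lambda: IRVScorer(mode="standard", k=6), seed=rep, target_id=tgt.target_id
            )
            r2 = ev.cross_validate(
                td, lambda: IRVScorer(mode="potency", k=6), seed=rep, target_id=tgt.target_id
            )
            if r1 is not None and r2 is not None:
                a_irv.append(r1.result.auc)
                a_ps.append(r2.result.auc)
        if a_irv:
            irv_means.append(float(np.mean(a_irv)))
            ps_means.append(float(np.mean(a_ps)))
    comp = ev.paired_comparison(
        {f"rep{i}": v for i, v in enumerate(ps_means)},
        {f"rep{i}": v for i, v in enumerate(irv_means)},
    )
    return {
        "irv_mean_auc": float(np.mean(irv_means)),
        "psirv_mean_auc": float(np.mean(ps_means)),
        "mean_difference": comp.mean_difference,
        "t": comp.t if comp.t is not None else float("nan"),
        "p": comp.p,
        "n_replicates": len(ps_means),
    }


def augmentation_effect(
    seed: int, n_targets: int = 4, cutoff: float = 10.0,
    n_train_negatives: int = 1000,
) -> dict[str, float]:
    """Simulated-screen mean AUC for the potency-sensitive voter with and
    without random-negative training augmentation, on identical corpora,
    folds and test pools."""
    cfg = clustered_corpus_config(seed=seed, n_targets=n_targets)
    corpus = generate_corpus(cfg)
    pool = split_random_pool(corpus.negative_ids, n_train=n_train_negatives, seed=seed)
    train_neg = corpus.negative_collection(pool.train_ids)
    test_neg = corpus.negative_collection(pool.test_ids)
    plain, augmented = [], []
    factory = lambda: IRVScorer(mode="potency", k=6)
    for tgt in corpus.targets:
        td = tgt.training_data(cutoff)
        r0 = ev.cross_validate(td, factory, seed=seed, target_id=tgt.target_id)
        r1 = ev.cross_validate(
            td, factory, seed=seed, target_id=tgt.target_id, augment_pool=train_neg
        )
        if r0 is None or r1 is None:
            continue
        plain.append(ev.simulated_screen(r0, td, test_neg).auc)
        augmented.append(ev.simulated_screen(r1, td, test_neg).auc)
    return {
        "screen_auc_plain": float(np.mean(plain)),
        "screen_auc_augmented": float(np.mean(augmented)),
        "n_targets": len(plain),
    }


def calibration_deviation(
    seed: int, n_targets: int = 10, cutoff: float = 5.0, min_count: int = 100
) -> dict[str, float]:
    """Reliability-curve analysis of voters trained to convergence: pooled
    held-out CV predictions of targets with AUC > 0.90 are binned by
    predicted probability; reports the worst |fraction - bin center| over
    bins with at least ``min_count`` predictions."""
    cfg = potency_graded_config(
        seed=seed, n_targets=n_targets, actives_per_target=60, inactives_per_target=60
    )
    corpus = generate_corpus(cfg)
    config = TrainConfig(epochs=5000)
    results = []
    for tgt in corpus.targets:
        td = tgt.training_data(cutoff)
        run = ev.cross_validate(
            td, lambda: IRVScorer(mode="standard", k=6, config=config),
            seed=seed, target_id=tgt.target_id,
        )
        if run is not None:
            results.append(run.result)
    bins = ev.reliability_curve(results, min_auc=0.90)
    checked = [b for b in bins if b.count >= min_count]
    worst = max((abs(b.fraction - b.center) for b in checked), default=float("nan"))
    return {
        "max_bin_deviation": float(worst),
        "n_bins_checked": len(checked),
        "n_predictions": int(sum(b.count for b in bins)),
    }


def protocol_conservation(seed: int) -> dict[str, float]:
    """Structural protocol guarantees, counted over one corpus: pooled CV
    predictions cover each molecule exactly once; single-class folds are
    flagged invalid; augmentation leaves test sets untouched."""
    cfg = clustered_corpus_config(seed=seed, n_targets=3)
    corpus = generate_corpus(cfg)
    pool = split_random_pool(corpus.negative_ids, n_train=100, seed=seed)
    train_neg = corpus.negative_collection(pool.train_ids)
    coverage_violations = 0
    test_set_changes = 0
    for tgt in corpus.targets:
        td = tgt.training_data(10.0)
        run = ev.cross_validate(td, lambda: MaxSimScorer(), seed=seed, target_id=tgt.target_id)
        if sorted(run.result.ids) != sorted(td.ids):
            coverage_violations += 1
        run_aug = ev.cross_validate(
            td, lambda: MaxSimScorer(), seed=seed, target_id=tgt.target_id,
            augment_pool=train_neg,
        )
        if sorted(run_aug.result.ids) != sorted(td.ids):
            test_set_changes += 1
    # a 10-molecule target with one active cannot yield a valid tenfold plan
    labels = np.zeros(10, dtype=int)
    labels[0] = 1
    sparse_plan_valid = ev.make_folds(labels, n_folds=10, seed=seed).valid
    return {
        "cv_coverage_violations": float(coverage_violations),
        "augmentation_test_set_changes": float(test_set_changes),
        "sparse_fold_plan_flagged_invalid": float(not sparse_plan_valid),
    }
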