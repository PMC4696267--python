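"""Seeded generator of ChEMBL-like corpora for protocol testing.

Each target is a small assay panel: clusters of self-similar active molecules
(random perturbations of one or more prototype bit sets), in-assay inactives
(strongly perturbed prototypes with EC50 at or above 10 µM), and a shared pool
of dissimilar random molecules serving as presumed-inactive negatives. Active
EC50 values are graded by similarity to the nearest cluster prototype through
a strictly decreasing map g(sim) = 10^(g0 - g1*sim) µM with multiplicative
lognormal noise, so higher similarity means higher potency and the standard
1/5/10 µM cutoffs each split the actives non-trivially.

Fingerprints are abstract bit sets (no chemistry is simulated), which keeps
every evaluation protocol exercisable without external data while preserving
the geometry that matters to similarity-based methods: tight self-similar
active clusters against a dissimilar random background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .activity import ActivityRecord, potency_class
from .chem import Fingerprint, write_fingerprint_file
from .neighbors import FingerprintCollection, TrainingData


@dataclass
class SyntheticCorpusConfig:
    n_targets: int = 10
    actives_per_target: int = 50
    inactives_per_target: int = 50
    negative_pool_size: int = 10_000
    n_bits: int = 512  # fingerprint length B
    prototype_density: float = 0.1
    active_flip_prob: float = 0.05  # p_a
    active_flip_prob_max: float | None = None  # draw per-active flip prob in [p_a, max]
    inactive_flip_factor: float = 3.0  # in-assay inactives flip w.p. factor * p_a
    negative_density: float = 0.1
    clusters_per_target: int = 2
    cluster_weights: tuple[float, ...] | None = (0.7, 0.3)  # occupancy; None = uniform
    sigma_log10: float = 0.2  # multiplicative lognormal EC50 noise, log10 units
    g0: float = 2.0  # g(sim) = 10^(g0 - g1*sim) µM
    g1: float = 4.0
    ec50_bounds: tuple[float, float] = (1e-3, 1e3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.active_flip_prob < 0.5):
            raise ValueError("active_flip_prob must be in (0, 0.5)")
        if self.active_flip_prob_max is not None and not (
            self.active_flip_prob <= self.active_flip_prob_max < 0.5
        ):
            raise ValueError("active_flip_prob_max must be in [p_a, 0.5)")
        for name in ("prototype_density", "negative_density"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.g1 <= 0:
            raise ValueError("g1 must be positive: higher similarity must mean lower EC50")
        if self.cluster_weights is not None:
            if len(self.cluster_weights) != self.clusters_per_target:
                raise ValueError("cluster_weights length must equal clusters_per_target")
            if any(w <= 0 for w in self.cluster_weights):
                raise ValueError("cluster_weights must be positive")

    def cluster_of(self, index: int, n: int) -> int:
        """Deterministic cluster assignment of the index-th molecule out of n,
        proportional to the (possibly unequal) cluster weights."""
        weights = self.cluster_weights or (1.0,) * self.clusters_per_target
        total = sum(weights)
        bounds = np.cumsum([w / total for w in weights]) * n
        return int(np.searchsorted(bounds, index, side="right").clip(0, len(weights) - 1))


@dataclass
class SyntheticTarget:
    target_id: str
    ids: list[str]
    bitsets: list[frozenset[int]]
    ec50s: np.ndarray  # µM
    prototypes: list[frozenset[int]]

    def records(self) -> list[ActivityRecord]:
        return [
            ActivityRecord(mid, self.target_id, float(e))
            for mid, e in zip(self.ids, self.ec50s)
        ]

    def training_data(self, cutoff: float) -> TrainingData:
        fps = FingerprintCollection.from_bitsets(self.ids, self.bitsets)
        labels = np.array([1 if e < cutoff else 0 for e in self.ec50s], dtype=int)
        potency = np.array([potency_class(float(e)) for e in self.ec50s], dtype=int)
        return TrainingData(fps, labels, potency)


@dataclass
class SyntheticCorpus:
    config: SyntheticCorpusConfig
    targets: list[SyntheticTarget]
    negative_ids: list[str]
    negative_bitsets: list[frozenset[int]]

    def negative_collection(self, subset: Sequence[str] | None = None) -> FingerprintCollection:
        if subset is None:
            return FingerprintCollection.from_bitsets(
                self.negative_ids, self.negative_bitsets, n_bits=self.config.n_bits
            )
        index = {nid: i for i, nid in enumerate(self.negative_ids)}
        ids = list(subset)
        return FingerprintCollection.from_bitsets(
            ids, [self.negative_bitsets[index[i]] for i in ids], n_bits=self.config.n_bits
        )


def clustered_corpus_config(seed: int, n_targets: int = 10, **overrides) -> SyntheticCorpusConfig:
    """Standard benchmark conditions: per target, two unequal clusters of
    tight actives (fixed flip probability 0.05) against strongly perturbed
    in-assay inactives and a dissimilar random pool."""
    return SyntheticCorpusConfig(n_targets=n_targets, seed=seed, **overrides)


def potency_graded_config(seed: int, n_targets: int = 4, **overrides) -> SyntheticCorpusConfig:
    """Potency-informative conditions: actives spread over a graded similarity
    shell (flip probability uniform in [0.02, 0.18]) so their EC50s span the
    1/5/10 µM classes, with in-assay inactives placed outside the shell. The
    natural label cutoff here is 5 µM, which puts potency classes on both
    sides of the label boundary."""
    defaults = dict(
        n_targets=n_targets,
        actives_per_target=60,
        inactives_per_target=40,
        active_flip_prob=0.02,
        active_flip_prob_max=0.18,
        inactive_flip_factor=12.5,
        sigma_log10=0.2,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticCorpusConfig(**defaults)


def _random_bitset(rng: np.random.Generator, n_bits: int, density: float) -> frozenset[int]:
    mask = rng.random(n_bits) < density
    return frozenset(int(i) for i in np.flatnonzero(mask))


def _flip(rng: np.random.Generator, bits: frozenset[int], n_bits: int, p: float) -> frozenset[int]:
    vec = np.zeros(n_bits, dtype=bool)
    vec[list(bits)] = True
    flips = rng.random(n_bits) < p
    return frozenset(int(i) for i in np.flatnonzero(vec ^ flips))


def _tanimoto_sets(a: frozenset[int], b: frozenset[int]) -> float:
    union = len(a | b)
    return len(a & b) / union if union else 0.0


def generate_corpus(config: SyntheticCorpusConfig) -> SyntheticCorpus:
    """Generate a corpus; byte-identical for identical configs (seeded)."""
    rng = np.random.default_rng(config.seed)
    targets: list[SyntheticTarget] = []
    for t in range(config.n_targets):
        tid = f"T{t:03d}"
        prototypes = [
            _random_bitset(rng, config.n_bits, config.prototype_density)
            for _ in range(config.clusters_per_target)
        ]
        ids: list[str] = []
        bitsets: list[frozenset[int]] = []
        ec50s: list[float] = []
        for a in range(config.actives_per_target):
            proto = prototypes[config.cluster_of(a, config.actives_per_target)]
            if config.active_flip_prob_max is None:
                p = config.active_flip_prob
            else:
                p = rng.uniform(config.active_flip_prob, config.active_flip_prob_max)
            bits = _flip(rng, proto, config.n_bits, p)
            sim = max(_tanimoto_sets(bits, pr) for pr in prototypes)
            log10_ec50 = config.g0 - config.g1 * sim + config.sigma_log10 * rng.standard_normal()
            ec50 = float(np.clip(10.0**log10_ec50, *config.ec50_bounds))
            ids.append(f"{tid}_act{a:03d}")
            bitsets.append(bits)
            ec50s.append(ec50)
        p_inact = min(config.inactive_flip_factor * config.active_flip_prob, 0.49)
        for i in range(config.inactives_per_target):
            proto = prototypes[config.cluster_of(i, config.inactives_per_target)]
            bits = _flip(rng, proto, config.n_bits, p_inact)
            # measured non-binders: EC50 at or above the 10 µM cutoff
            ec50 = float(10.0 ** rng.uniform(1.0, 3.0))
            ids.append(f"{tid}_ina{i:03d}")
            bitsets.append(bits)
            ec50s.append(ec50)
        targets.append(
            SyntheticTarget(
                target_id=tid, ids=ids, bitsets=bitsets,
                ec50s=np.array(ec50s), prototypes=prototypes,
            )
        )
    negative_ids = [f"RC{i:05d}" for i in range(config.negative_pool_size)]
    negative_bitsets = [
        _random_bitset(rng, config.n_bits, config.negative_density)
        for _ in range(config.negative_pool_size)
    ]
    return SyntheticCorpus(
        config=config, targets=targets,
        negative_ids=negative_ids, negative_bitsets=negative_bitsets,
    )


def write_corpus(corpus: SyntheticCorpus, directory: str | Path) -> dict[str, Path]:
    """Write fingerprint files, an activity CSV and the negative-pool id list
    in the package's standard formats; round-trips through the loaders."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    all_ids: list[str] = []
    all_fps: list[Fingerprint] = []
    rows = ["molecule_id,target_id,ec50_uM"]
    for tgt in corpus.targets:
        all_ids.extend(tgt.ids)
        all_fps.extend(Fingerprint(b) for b in tgt.bitsets)
        for r in tgt.records():
            rows.append(f"{r.molecule_id},{r.target_id},{r.ec50!r}")
    all_ids.extend(corpus.negative_ids)
    all_fps.extend(Fingerprint(b) for b in corpus.negative_bitsets)
    paths = {
        "fingerprints": directory / "fingerprints.tsv",
        "activities": directory / "activities.csv",
        "negative_pool": directory / "negative_pool.txt",
    }
    write_fingerprint_file(paths["fingerprints"], all_ids, all_fps)
    paths["activities"].write_text("\n".join(rows) + "\n")
    paths["negative_pool"].write_text("\n".join(corpus.negative_ids) + "\n")
    return paths
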