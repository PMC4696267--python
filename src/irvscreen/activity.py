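"""Activity tables: loading, duplicate averaging, potency cutoffs, target filters.

Bioactivity is summarized by EC50 in µM (lower = more potent). A molecule is
labeled active against a target when its EC50 is strictly smaller than the
chosen cutoff; the default cutoffs are 1, 5 and 10 µM so results can be checked
for cutoff sensitivity. The same three thresholds partition molecules into four
potency classes (0: <1 µM, 1: [1,5), 2: [5,10), 3: ≥10 µM) used by the
potency-sensitive voter. Random-negative molecules carry no EC50 and are
assigned potency class 3, the only class available to non-binders.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_CUTOFFS_UM = (1.0, 5.0, 10.0)
RANDOM_NEGATIVE_POTENCY_CLASS = 3


@dataclass(frozen=True)
class ActivityRecord:
    molecule_id: str
    target_id: str
    ec50: float  # µM; > 0

    def __post_init__(self) -> None:
        if not (self.ec50 > 0):
            raise ValueError(f"ec50 must be positive, got {self.ec50}")

    def label(self, cutoff: float) -> int:
        return label_activity(self.ec50, cutoff)

    @property
    def potency_class(self) -> int:
        return potency_class(self.ec50)


@dataclass
class TargetDataset:
    target_id: str
    records: list[ActivityRecord]

    def __post_init__(self) -> None:
        ids = [r.molecule_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(
                f"target {self.target_id}: duplicate molecule ids "
                "(run resolve_duplicates first)"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def molecule_ids(self) -> list[str]:
        return [r.molecule_id for r in self.records]

    def labels(self, cutoff: float) -> np.ndarray:
        return np.array([r.label(cutoff) for r in self.records], dtype=int)

    def potency_classes(self) -> np.ndarray:
        return np.array([r.potency_class for r in self.records], dtype=int)

    def n_actives(self, cutoff: float) -> int:
        return int(self.labels(cutoff).sum())


@dataclass(frozen=True)
class RandomNegativePool:
    """Molecules assumed inactive against every target, split once into a
    training pool (added to training sets) and a test pool (added to
    simulated-screen test sets)."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test negative pools overlap")


def label_activity(ec50: float, cutoff: float) -> int:
    """1 iff EC50 is strictly smaller than the cutoff (boundary → inactive)."""
    return 1 if ec50 < cutoff else 0


def potency_class(ec50: float | None, thresholds: Sequence[float] = DEFAULT_CUTOFFS_UM) -> int:
    """Potency class 0..len(thresholds): index of the first threshold the EC50
    is below, or the top class for non-binders / unknown EC50 (None)."""
    if ec50 is None:
        return len(thresholds)
    if not (ec50 > 0):
        raise ValueError(f"ec50 must be positive, got {ec50}")
    for k, t in enumerate(thresholds):
        if ec50 < t:
            return k
    return len(thresholds)


def load_activities(path: str | Path) -> tuple[list[ActivityRecord], list[dict]]:
    """Load a delimited table with columns molecule_id, target_id, ec50_uM.

    Rows with non-numeric or non-positive EC50 are rejected with reasons.
    A missing column is fatal.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"molecule_id": str, "target_id": str})
    required = {"molecule_id", "target_id", "ec50_uM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    records: list[ActivityRecord] = []
    rejects: list[dict] = []
    ec50 = pd.to_numeric(df["ec50_uM"], errors="coerce")
    for i, row in df.iterrows():
        value = ec50.iloc[i]
        if pd.isna(value):
            rejects.append(
                {"row": int(i), "reason": f"non-numeric ec50 {row['ec50_uM']!r}"}
            )
        elif value <= 0:
            rejects.append({"row": int(i), "reason": f"non-positive ec50 {value}"})
        else:
            records.append(
                ActivityRecord(str(row["molecule_id"]), str(row["target_id"]), float(value))
            )
    return records, rejects


def resolve_duplicates(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Collapse repeated (molecule, target) measurements to their arithmetic
    mean EC50, preserving first-appearance order. Idempotent."""
    groups: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for r in records:
        key = (r.molecule_id, r.target_id)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r.ec50)
    return [
        ActivityRecord(mol, tgt, float(np.mean(groups[(mol, tgt)]))) for mol, tgt in order
    ]


def group_by_target(records: Sequence[ActivityRecord]) -> list[TargetDataset]:
    by_target: dict[str, list[ActivityRecord]] = {}
    for r in records:
        by_target.setdefault(r.target_id, []).append(r)
    return [TargetDataset(tid, recs) for tid, recs in by_target.items()]


def filter_targets(
    datasets: Sequence[TargetDataset],
    min_molecules: int = 10,
    min_actives: int | None = None,
    cutoff: float | None = None,
) -> tuple[list[TargetDataset], int]:
    """Keep targets with at least ``min_molecules`` records; optionally also
    require ``min_actives`` actives at ``cutoff``. Returns (kept, n_discarded).
    """
    kept = []
    for ds in datasets:
        if len(ds) < min_molecules:
            continue
        if min_actives is not None:
            if cutoff is None:
                raise ValueError("min_actives filter requires a cutoff")
            if ds.n_actives(cutoff) < min_actives:
                continue
        kept.append(ds)
    return kept, len(datasets) - len(kept)


def split_random_pool(
    pool_ids: Sequence[str], n_train: int = 1000, seed: int = 0
) -> RandomNegativePool:
    """Split the random-negative pool into disjoint train/test subsets
    (nominally 1000 train / remainder test); reproducible from the seed."""
    ids = list(pool_ids)
    if len(ids) < n_train:
        raise ValueError(f"pool of {len(ids)} smaller than n_train={n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = tuple(ids[i] for i in sorted(perm[:n_train]))
    test = tuple(ids[i] for i in sorted(perm[n_train:]))
    return RandomNegativePool(train_ids=train, test_ids=test)
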