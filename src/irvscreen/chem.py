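"""Molecules, circular-substructure fingerprints and Tanimoto similarity.

Molecules are parsed from SMILES with RDKit and reduced to a labeled heavy-atom
graph: each atom carries ``element + heavy-atom degree`` (e.g. ``C3`` for a
carbon bonded to three heavy atoms) and each bond one of the four order labels
``- = # :`` (single, double, triple, aromatic). Hydrogens are implicit.

A fingerprint is the set of distinct canonical atom-environment strings of
radius 0, 1 and 2 bonds, mapped to integer bit indices through an explicit,
lossless :class:`SubstructureDictionary` (no hashed folding, so no bit
collisions). Presence only — no counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # rejection reasons are reported, not printed by RDKit

_BOND_LABELS = {
    Chem.BondType.SINGLE: "-",
    Chem.BondType.DOUBLE: "=",
    Chem.BondType.TRIPLE: "#",
    Chem.BondType.AROMATIC: ":",
}

DEFAULT_RADIUS = 2


@dataclass(frozen=True)
class MolGraph:
    """Labeled heavy-atom graph: atom label strings plus labeled undirected bonds."""

    atom_labels: tuple[str, ...]
    bonds: tuple[tuple[int, int, str], ...]

    def adjacency(self) -> list[list[tuple[int, str]]]:
        adj: list[list[tuple[int, str]]] = [[] for _ in self.atom_labels]
        for i, j, lab in self.bonds:
            adj[i].append((j, lab))
            adj[j].append((i, lab))
        return adj


@dataclass(frozen=True)
class Molecule:
    id: str
    smiles: str
    graph: MolGraph


@dataclass(frozen=True)
class RejectedLine:
    line_number: int
    text: str
    reason: str


@dataclass(frozen=True)
class Fingerprint:
    """Sparse binary fingerprint: a duplicate-free set of bit indices."""

    bits: frozenset[int]

    @property
    def n_substructures(self) -> int:
        return len(self.bits)


class SubstructureDictionary:
    """Stable, lossless mapping from canonical substructure strings to bit indices.

    New substructures are assigned the next free index on first sight; the
    mapping is persisted alongside any saved model so bit indices stay
    meaningful across sessions.
    """

    def __init__(self, mapping: dict[str, int] | None = None, frozen: bool = False):
        self._map: dict[str, int] = dict(mapping) if mapping else {}
        self.frozen = frozen

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, key: str) -> bool:
        return key in self._map

    def index_of(self, substructure: str) -> int:
        try:
            return self._map[substructure]
        except KeyError:
            if self.frozen:
                raise KeyError(
                    f"substructure {substructure!r} absent from frozen dictionary"
                ) from None
            idx = len(self._map)
            self._map[substructure] = idx
            return idx

    def encode(self, substructures: Iterable[str]) -> frozenset[int]:
        return frozenset(self.index_of(s) for s in substructures)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self._map, indent=0, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path, frozen: bool = True) -> "SubstructureDictionary":
        return cls(json.loads(Path(path).read_text()), frozen=frozen)


def mol_graph_from_rdkit(mol: Chem.Mol) -> MolGraph:
    labels = tuple(f"{a.GetSymbol()}{a.GetDegree()}" for a in mol.GetAtoms())
    bonds = tuple(
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_LABELS.get(b.GetBondType(), "-"))
        for b in mol.GetBonds()
    )
    return MolGraph(labels, bonds)


def molecule_from_smiles(smiles: str, mol_id: str) -> Molecule:
    """Parse one SMILES string; raises ValueError with a reason on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError("RDKit could not parse SMILES")
    return Molecule(id=mol_id, smiles=smiles, graph=mol_graph_from_rdkit(mol))


def parse_molecules(path: str | Path) -> tuple[list[Molecule], list[RejectedLine]]:
    """Read a SMILES file: ``SMILES[<ws>id]`` per line, id auto-assigned from
    the line number when absent. Unparseable lines are returned as rejects,
    never silently dropped; order is preserved.
    """
    path = Path(path)
    molecules: list[Molecule] = []
    rejects: list[RejectedLine] = []
    seen_ids: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            mol_id = parts[1].strip() if len(parts) > 1 else f"line{lineno}"
            if mol_id in seen_ids:
                rejects.append(RejectedLine(lineno, line, f"duplicate id {mol_id!r}"))
                continue
            try:
                molecules.append(molecule_from_smiles(smiles, mol_id))
                seen_ids.add(mol_id)
            except ValueError as exc:
                rejects.append(RejectedLine(lineno, line, str(exc)))
    return molecules, rejects


def environment_strings(graph: MolGraph, max_radius: int = DEFAULT_RADIUS) -> set[str]:
    """Canonical atom-environment strings at radii ``0..max_radius``.

    The radius-``t`` string of an atom is built by breadth-first label
    propagation: at each step an atom's string is its previous string followed
    by the lexicographically sorted list of ``bond-label + neighbor string``
    terms. Sorting makes the string a pure function of the labeled graph,
    independent of atom input order. A radius is skipped for an atom once its
    bond-ball stops growing, so e.g. methane contributes a single substructure.
    """
    n = len(graph.atom_labels)
    if n == 0:
        return set()
    adj = graph.adjacency()

    labels = list(graph.atom_labels)
    out: set[str] = set(labels)
    # ball[a] = set of atoms within the current radius of a; used to detect
    # when an environment has stopped growing.
    ball = [frozenset([a]) for a in range(n)]
    for _ in range(max_radius):
        new_labels = []
        new_ball = []
        for a in range(n):
            terms = sorted(lab + labels[b] for b, lab in adj[a])
            new_labels.append(labels[a] + "(" + ",".join(terms) + ")")
            grown = set(ball[a])
            for b, _lab in adj[a]:
                grown |= ball[b]
            new_ball.append(frozenset(grown))
        for a in range(n):
            if new_ball[a] != ball[a]:
                out.add(new_labels[a])
        labels, ball = new_labels, new_ball
    return out


def compute_fingerprint(
    graph: MolGraph | Molecule,
    dictionary: SubstructureDictionary,
    max_radius: int = DEFAULT_RADIUS,
) -> Fingerprint:
    """Circular-substructure fingerprint of a molecule (presence bits only)."""
    if isinstance(graph, Molecule):
        graph = graph.graph
    return Fingerprint(dictionary.encode(environment_strings(graph, max_radius)))


def tanimoto(a: Fingerprint | frozenset[int] | set[int], b) -> float:
    """Tanimoto (Jaccard) similarity |a∩b| / |a∪b|; two empty sets give 0."""
    sa = a.bits if isinstance(a, Fingerprint) else frozenset(a)
    sb = b.bits if isinstance(b, Fingerprint) else frozenset(b)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


def write_fingerprint_file(
    path: str | Path, ids: Sequence[str], fingerprints: Sequence[Fingerprint]
) -> None:
    """One line per molecule: ``id TAB sorted,comma,separated,bit,indices``."""
    with Path(path).open("w") as fh:
        for mol_id, fp in zip(ids, fingerprints):
            bits = ",".join(str(b) for b in sorted(fp.bits))
            fh.write(f"{mol_id}\t{bits}\n")


def read_fingerprint_file(path: str | Path) -> tuple[list[str], list[Fingerprint]]:
    ids: list[str] = []
    fps: list[Fingerprint] = []
    with Path(path).open() as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line:
                continue
            mol_id, _, bits = line.partition("\t")
            ids.append(mol_id)
            fps.append(
                Fingerprint(frozenset(int(b) for b in bits.split(",") if b != ""))
            )
    return ids, fps
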