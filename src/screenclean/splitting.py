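"""Scaffold-aware and random train/validation/test splitting.

Scaffold splitting groups molecules by their ring-framework scaffold and
assigns whole groups to partitions so no scaffold spans two partitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .records import CuratedDataset

__all__ = ["SplitAssignment", "murcko_scaffold", "scaffold_split", "random_split"]

PARTITIONS = ("train", "val", "test")


@dataclass
class SplitAssignment:
    """Assignment of molecule keys to train/val/test partitions."""

    labels: dict[str, str] = field(default_factory=dict)
    scaffolds: dict[str, str] = field(default_factory=dict)
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    mode: str = "scaffold"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")
        bad = {v for v in self.labels.values() if v not in PARTITIONS}
        if bad:
            raise ValueError(f"unknown partition labels {bad}")

    def partition(self, name: str) -> list[str]:
        return [k for k, v in self.labels.items() if v == name]

    def sizes(self) -> tuple[int, int, int]:
        return tuple(len(self.partition(p)) for p in PARTITIONS)  # type: ignore[return-value]


def murcko_scaffold(smiles: str) -> str:
    """Ring-framework scaffold of a molecule; '' for acyclic molecules.

    Stereo descriptors are stripped first so enantiomers share a
    scaffold. Raises ValueError on invalid SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    Chem.RemoveStereochemistry(mol)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


def _targets(n: int, fractions: tuple[float, float, float]) -> list[int]:
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    n_train = n - n_val - n_test
    return [n_train, n_val, n_test]


def _keys(dataset: CuratedDataset) -> list[str]:
    keys = dataset.molecule_keys()
    if len(keys) != len(dataset.records):
        warnings.warn(
            "dataset has multiple records per molecule; splitting on distinct molecule keys",
            stacklevel=3,
        )
    return keys


def scaffold_split(
    dataset: CuratedDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Partition molecules so no scaffold appears in two partitions.

    Scaffold groups larger than the val and test targets go to train
    first (largest first); remaining groups are shuffled by ``seed`` and
    greedily assigned to the partition furthest below its target count.
    A group larger than the train target still lands in train, with a
    warning.
    """
    keys = _keys(dataset)
    scaffolds = {k: murcko_scaffold(k) for k in keys}
    groups: dict[str, list[str]] = {}
    for key in keys:
        groups.setdefault(scaffolds[key], []).append(key)

    targets = _targets(len(keys), fractions)
    filled = [0, 0, 0]
    labels: dict[str, str] = {}

    group_items = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    # Groups too big for either held-out partition go straight to train.
    threshold = max(targets[1], targets[2])
    big = [(s, m) for s, m in group_items if len(m) > threshold]
    rest = [(s, m) for s, m in group_items if len(m) <= threshold]
    for scaffold, members in big:
        if len(members) > targets[0]:
            warnings.warn(
                f"scaffold group of size {len(members)} exceeds the train target {targets[0]}; "
                "assigned to train",
                stacklevel=2,
            )
        for key in members:
            labels[key] = "train"
        filled[0] += len(members)

    rng = np.random.default_rng(seed)
    rng.shuffle(rest)
    for scaffold, members in rest:
        deficits = [targets[i] - filled[i] for i in range(3)]
        part = int(np.argmax(deficits))  # argmax prefers train on ties
        for key in members:
            labels[key] = PARTITIONS[part]
        filled[part] += len(members)

    return SplitAssignment(
        labels=labels, scaffolds=scaffolds, fractions=fractions, seed=seed, mode="scaffold"
    )


def random_split(
    dataset: CuratedDataset,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> SplitAssignment:
    """Seeded uniform shuffle then contiguous slicing by fractions."""
    keys = _keys(dataset)
    rng = np.random.default_rng(seed)
    shuffled = list(keys)
    rng.shuffle(shuffled)
    n_train, n_val, _ = _targets(len(keys), fractions)
    labels = {}
    for i, key in enumerate(shuffled):
        if i < n_train:
            labels[key] = "train"
        elif i < n_train + n_val:
            labels[key] = "val"
        else:
            labels[key] = "test"
    return SplitAssignment(
        labels=labels,
        scaffolds={},
        fractions=fractions,
        seed=seed,
        mode="random",
    )
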