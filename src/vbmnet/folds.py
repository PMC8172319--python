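"""Stratified k-fold train/validation/test partitioning.

The scheme: subjects are stratified by diagnostic status, shuffled once with
the given seed, and dealt into ``k`` partitions.  In round ``r`` partition
``r`` is the test set; walking the remaining partitions in cyclic order
``r+1, r+2, ...``, the first ``k-2`` form the training set and the last one
— partition ``(r-1) mod k`` — is the validation set.  Every subject is
therefore tested exactly once, and validation partitions also rotate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = ["FoldSplit", "make_folds", "save_folds", "load_folds"]


@dataclass(frozen=True)
class FoldSplit:
    round_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set.union(*sets)) != total:
            raise ValueError(f"round {self.round_index}: overlapping partitions")

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


def make_folds(strata: Mapping[str, int | str], k: int = 10, seed: int = 0) -> list[FoldSplit]:
    """Build the k cross-validation rounds.

    Parameters
    ----------
    strata
        Mapping subject id -> stratification label (diagnostic status).
    k
        Number of partitions (>= 3 so train/val/test are all nonempty).
    seed
        Shuffle seed; identical inputs give identical folds.
    """
    if k < 3:
        raise ValueError("k must be >= 3 (need disjoint train/val/test)")
    rng = np.random.default_rng(seed)

    partitions: list[list[str]] = [[] for _ in range(k)]
    # iterate strata in sorted label order for determinism
    by_label: dict = {}
    for sid, label in strata.items():
        by_label.setdefault(label, []).append(str(sid))
    offset = 0
    for label in sorted(by_label, key=str):
        members = sorted(by_label[label])
        if len(members) < k:
            raise ValueError(f"stratum {label!r} has {len(members)} members; "
                             f"needs at least k={k}")
        members = [members[i] for i in rng.permutation(len(members))]
        # deal sequentially, continuing from the previous stratum's offset so
        # remainders spread over different partitions
        for j, sid in enumerate(members):
            partitions[(offset + j) % k].append(sid)
        offset += len(members)

    splits = []
    for r in range(k):
        rest = [(r + 1 + i) % k for i in range(k - 1)]
        train_parts, val_part = rest[:k - 2], rest[-1]
        train = [sid for p in train_parts for sid in partitions[p]]
        splits.append(FoldSplit(
            round_index=r,
            train_ids=tuple(train),
            val_ids=tuple(partitions[val_part]),
            test_ids=tuple(partitions[r]),
        ))
    return splits


def save_folds(splits: Sequence[FoldSplit], path: str | Path) -> None:
    payload = [{"round": s.round_index, "train": list(s.train_ids),
                "val": list(s.val_ids), "test": list(s.test_ids)} for s in splits]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_folds(path: str | Path) -> list[FoldSplit]:
    payload = json.loads(Path(path).read_text())
    return [FoldSplit(d["round"], tuple(d["train"]), tuple(d["val"]), tuple(d["test"]))
            for d in payload]
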