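"""Pareto Optimization for Subset Selection (POSS) over layer-inclusion masks.

A mask bit ``d_j = 1`` excludes layer ``j`` and ``d_j = 0`` includes it.
POSS evolves a non-dominated archive under the bi-objective
(minimize loss, minimize number of included layers): starting from the
all-excluded mask, each step mutates a uniformly chosen archived mask by
flipping every bit independently with probability ``1/n``, evaluates it, and
inserts it unless some archived record dominates it, evicting records the
newcomer dominates.  The archive therefore traces a loss-vs-size frontier
from which a final mask is picked subject to a minimum-depth constraint.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

__all__ = [
    "ArchiveRecord",
    "ParetoArchive",
    "pareto_dominates",
    "poss_optimize",
    "select_final",
]


@dataclass(frozen=True)
class ArchiveRecord:
    mask: tuple[int, ...]  # 1 = exclude layer, 0 = include
    loss: float

    @property
    def included(self) -> int:
        return len(self.mask) - sum(self.mask)

    @property
    def excluded(self) -> int:
        return sum(self.mask)


def pareto_dominates(a: tuple[float, float], b: tuple[float, float]) -> bool:
    """True iff a = (loss, size) dominates b: <= in both, < in one."""
    return a[0] <= b[0] and a[1] <= b[1] and a != b


@dataclass
class ParetoArchive:
    """Mutually non-dominated (mask, loss, included-size) records."""

    records: list[ArchiveRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def objectives(self, r: ArchiveRecord) -> tuple[float, float]:
        return (r.loss, r.included)

    def insert(self, candidate: ArchiveRecord) -> bool:
        """Insert unless dominated (or duplicated); evict dominated records."""
        c = self.objectives(candidate)
        for r in self.records:
            if pareto_dominates(self.objectives(r), c) or self.objectives(r) == c:
                return False
        self.records = [
            r for r in self.records if not pareto_dominates(c, self.objectives(r))
        ]
        self.records.append(candidate)
        return True

    def best_loss(self) -> ArchiveRecord:
        return min(self.records, key=lambda r: (r.loss, r.included, r.mask))

    def is_mutually_nondominated(self) -> bool:
        for a in self.records:
            for b in self.records:
                if a is not b and pareto_dominates(
                    self.objectives(a), self.objectives(b)
                ):
                    return False
        return True

    def to_csv(self, path: Union[str, Path]) -> None:
        with open(path, "w", newline="") as f:
            writer = csv.writer(f)
            writer.writerow(["mask", "loss", "included", "excluded"])
            for r in sorted(self.records, key=lambda r: r.included):
                writer.writerow(
                    ["".join(map(str, r.mask)), r.loss, r.included, r.excluded]
                )


def poss_optimize(
    loss: Callable[[Sequence[int]], float],
    n: int,
    budget: int = 4000,
    seed: int = 0,
    check_invariant: bool = False,
) -> ParetoArchive:
    """Run POSS for ``budget`` evaluations over length-``n`` masks.

    A raising loss discards the mutant but still consumes budget.  With
    ``check_invariant`` the archive is verified mutually non-dominated after
    every insertion (used by property tests).
    """
    if n < 1:
        raise ValueError("mask length must be >= 1")
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    archive = ParetoArchive()

    start = tuple([1] * n)  # all layers excluded
    try:
        archive.insert(ArchiveRecord(start, float(loss(start))))
    except Exception:
        pass
    evaluations = 1

    while evaluations < budget:
        if len(archive) == 0:
            mask = np.ones(n, dtype=int)
        else:
            parent = archive.records[int(rng.integers(len(archive)))]
            mask = np.array(parent.mask, dtype=int)
        flips = rng.random(n) < (1.0 / n)
        mask = np.where(flips, 1 - mask, mask)
        candidate = tuple(int(b) for b in mask)
        evaluations += 1
        try:
            value = float(loss(candidate))
        except Exception:
            continue
        archive.insert(ArchiveRecord(candidate, value))
        if check_invariant and not archive.is_mutually_nondominated():
            raise AssertionError("archive lost mutual non-domination")
    return archive


def select_final(archive: ParetoArchive, min_layers: int = 0) -> tuple[int, ...]:
    """Lowest-loss archived mask with at least ``min_layers`` included.

    Ties break toward fewer included layers, then lexicographic mask order.
    """
    feasible = [r for r in archive if r.included >= min_layers]
    if not feasible:
        raise ValueError(
            f"no archived mask includes at least {min_layers} layers"
        )
    return min(feasible, key=lambda r: (r.loss, r.included, r.mask)).mask
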