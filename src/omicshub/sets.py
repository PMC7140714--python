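"""Venn set algebra over identifier sets, plus residue-interval arithmetic.

Two-way partitions split a pair of gene sets into line-specific and common
regions; three-way partitions give the seven disjoint Venn regions of three
interactome sets. Percentages are reported both exactly and as
round-half-up integers for report rendering.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

logger = logging.getLogger(__name__)

__all__ = [
    "TwoWayPartition",
    "ThreeWayPartition",
    "ResidueInterval",
    "partition_two",
    "partition_three",
    "common_fraction",
    "region_length",
    "round_half_up",
]


class EmptyUnionError(ValueError):
    """A fraction over an empty union is undefined."""


class InvalidIntervalError(ValueError):
    """Residue interval with start > end or start < 1."""


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _normalize_ids(ids: Iterable[str], label: str) -> set[str]:
    stripped = [str(i).strip() for i in ids]
    counts = Counter(stripped)
    dups = [i for i, c in counts.items() if c > 1]
    if dups:
        logger.warning(
            "set %r: %d duplicate identifier(s) collapsed (e.g. %s)",
            label, len(dups), dups[0],
        )
    return set(stripped)


@dataclass(frozen=True)
class TwoWayPartition:
    specific_a: frozenset[str]
    specific_b: frozenset[str]
    common: frozenset[str]
    labels: tuple[str, str] = ("A", "B")

    @property
    def union_size(self) -> int:
        return len(self.specific_a) + len(self.specific_b) + len(self.common)

    def sizes(self) -> dict[str, int]:
        a, b = self.labels
        return {
            f"{a}_specific": len(self.specific_a),
            f"{b}_specific": len(self.specific_b),
            "common": len(self.common),
        }


@dataclass(frozen=True)
class ThreeWayPartition:
    """The seven disjoint regions of a three-set Venn diagram.

    Region keys are membership masks over ``labels``: "100" = only in the
    first set, "111" = in all three, etc.
    """

    regions: dict[str, frozenset[str]]
    labels: tuple[str, str, str] = ("A", "B", "C")

    @property
    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())

    @property
    def triple_intersection(self) -> frozenset[str]:
        return self.regions["111"]

    def triple_fraction(self) -> float:
        if self.union_size == 0:
            raise EmptyUnionError("union of the three sets is empty")
        return 100.0 * len(self.regions["111"]) / self.union_size

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in sorted(self.regions.items())}


def partition_two(
    a: Iterable[str], b: Iterable[str], labels: tuple[str, str] = ("A", "B")
) -> TwoWayPartition:
    """Split two identifier sets into specific-to-A, specific-to-B, common."""
    sa = _normalize_ids(a, labels[0])
    sb = _normalize_ids(b, labels[1])
    return TwoWayPartition(
        specific_a=frozenset(sa - sb),
        specific_b=frozenset(sb - sa),
        common=frozenset(sa & sb),
        labels=labels,
    )


def partition_three(
    a: Iterable[str],
    b: Iterable[str],
    c: Iterable[str],
    labels: tuple[str, str, str] = ("A", "B", "C"),
) -> ThreeWayPartition:
    """The seven disjoint Venn regions of three identifier sets."""
    sa = _normalize_ids(a, labels[0])
    sb = _normalize_ids(b, labels[1])
    sc = _normalize_ids(c, labels[2])
    regions: dict[str, set[str]] = {
        f"{ia}{ib}{ic}": set()
        for ia in (0, 1) for ib in (0, 1) for ic in (0, 1)
        if ia or ib or ic
    }
    for x in sa | sb | sc:
        key = f"{int(x in sa)}{int(x in sb)}{int(x in sc)}"
        regions[key].add(x)
    return ThreeWayPartition(
        regions={k: frozenset(v) for k, v in regions.items()}, labels=labels
    )


def common_fraction(p: TwoWayPartition) -> float:
    """Common region as a percentage of the union of both sets.

    100 * |common| / (|specific_a| + |specific_b| + |common|). Use
    ``round_half_up`` for the nearest-integer report rendering.
    """
    if p.union_size == 0:
        raise EmptyUnionError("both input sets are empty")
    return 100.0 * len(p.common) / p.union_size


@dataclass(frozen=True)
class ResidueInterval:
    """1-based inclusive residue coordinates, e.g. G92..R405."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise InvalidIntervalError("residue coordinates are 1-based")
        if self.start > self.end:
            raise InvalidIntervalError(
                f"start {self.start} exceeds end {self.end}"
            )

    def residues(self) -> range:
        return range(self.start, self.end + 1)


def region_length(iv: ResidueInterval) -> int:
    """Number of residues in a 1-based inclusive interval: end - start + 1."""
    return iv.end - iv.start + 1
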