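"""Indexed interval overlap queries (intervaltree-backed).

All batch overlap rules in the pipeline go through :class:`IntervalIndex`;
its results are checked against a brute-force all-pairs scan in the test
suite, so the index is an implementation detail, not a semantics change.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Generic, Iterable, Sequence, TypeVar

from intervaltree import IntervalTree

from .core import GenomicInterval

T = TypeVar("T")


class IntervalIndex(Generic[T]):
    """Maps a query interval to the stored payloads whose intervals overlap it.

    Results are returned in insertion order (deterministic regardless of the
    underlying tree's set semantics).
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, T]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._n = 0
        for interval, payload in items:
            self.add(interval, payload)

    def add(self, interval: GenomicInterval, payload: T) -> None:
        self._trees[interval.chrom].addi(interval.start, interval.end, (self._n, payload))
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlapping(self, query: GenomicInterval) -> Sequence[T]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = tree.overlap(query.start, query.end)
        return [payload for _, payload in sorted(iv.data for iv in hits)]
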