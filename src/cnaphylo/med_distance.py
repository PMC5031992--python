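"""Minimum-event distances between integer copy-number profiles.

The event model: a single event picks one chromosome, one contiguous run of
fragments on it, and adds +1 or -1 to every covered fragment.  Under the
*strict* model an event may never cover a fragment whose current copy number
is 0, so copies lost down to 0 can never be regained.  The minimum number of
events transforming one profile into another then has a closed form: writing
D = target - source and splitting it into its positive part P and negative
part N per chromosome,

    count = sum_i max(0, P_i - P_{i-1}) + sum_i max(0, N_i - N_{i-1})

with P_0 = N_0 = 0 at every chromosome start (each "ascent" of the difference
profile needs one more overlapping event).  A breadth-first search over the
strict event model serves as an exact, independent oracle on small profiles.

The relaxed symmetric count (same formula, no reachability check) is used as
the pairwise dissimilarity for tree building, where finiteness is required.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import UsageError

#: Sentinel returned when no event sequence can transform source into target.
UNREACHABLE = math.inf


@dataclass(frozen=True)
class CNVector:
    """An ordered integer copy-number profile with chromosome boundaries.

    ``chromosome_breaks`` holds the start index of every chromosome after the
    first (strictly increasing, all in ``(0, len(values))``); events never
    span a break.
    """

    values: tuple[int, ...]
    chromosome_breaks: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.values):
            raise UsageError("copy numbers must be non-negative")
        br = self.chromosome_breaks
        if any(b <= 0 or b >= len(self.values) for b in br) or list(br) != sorted(set(br)):
            raise UsageError(
                "chromosome_breaks must be strictly increasing indices inside the profile"
            )

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.int64)

    def chromosome_slices(self) -> list[slice]:
        bounds = [0, *self.chromosome_breaks, len(self.values)]
        return [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]


def cn_vector(values: Iterable[int], chromosome_breaks: Iterable[int] = ()) -> CNVector:
    """Convenience constructor accepting any iterables."""
    return CNVector(tuple(int(v) for v in values), tuple(int(b) for b in chromosome_breaks))


def _check_compatible(a: CNVector, b: CNVector) -> None:
    if len(a) != len(b) or a.chromosome_breaks != b.chromosome_breaks:
        raise UsageError(
            "profiles must have equal length and identical chromosome breaks "
            f"(got {len(a)}/{a.chromosome_breaks} vs {len(b)}/{b.chromosome_breaks})"
        )


def _ascent_count(diff: np.ndarray) -> int:
    """Events needed for one chromosome's difference profile (relaxed model)."""
    pos = np.maximum(diff, 0)
    neg = np.maximum(-diff, 0)
    up_pos = np.maximum(np.diff(pos, prepend=0), 0).sum()
    up_neg = np.maximum(np.diff(neg, prepend=0), 0).sum()
    return int(up_pos + up_neg)


def directed_event_count(source: CNVector, target: CNVector) -> int | float:
    """Minimum events from ``source`` to ``target`` under the strict model.

    Returns :data:`UNREACHABLE` iff ``source`` is 0 on a fragment where
    ``target`` is positive (copies lost to 0 cannot be regained).
    """
    _check_compatible(source, target)
    s = source.as_array()
    t = target.as_array()
    if bool(np.any((s == 0) & (t > 0))):
        return UNREACHABLE
    return sum(_ascent_count(t[sl] - s[sl]) for sl in source.chromosome_slices())


def symmetric_distance(a: CNVector, b: CNVector) -> int:
    """Relaxed event count; symmetric, finite, used for tree inference."""
    _check_compatible(a, b)
    av = a.as_array()
    bv = b.as_array()
    return sum(_ascent_count(bv[sl] - av[sl]) for sl in a.chromosome_slices())


def _bfs_neighbours(state: tuple[int, ...], slices: Sequence[slice], max_cn: int):
    for sl in slices:
        for i in range(sl.start, sl.stop):
            for j in range(i, sl.stop):
                run = state[i : j + 1]
                if 0 in run:  # strict model: events never cover a CN-0 fragment
                    continue
                if max(run) < max_cn:
                    yield state[:i] + tuple(v + 1 for v in run) + state[j + 1 :]
                yield state[:i] + tuple(v - 1 for v in run) + state[j + 1 :]


def bfs_distances(source: CNVector, max_cn: int) -> dict[tuple[int, ...], int]:
    """All strict-model distances from ``source``, by breadth-first search.

    The state space is capped at ``max_cn`` copies per fragment; its size
    ``(max_cn+1)**n_fragments`` must stay small.
    """
    n = len(source)
    if (max_cn + 1) ** n > 200_000:
        raise UsageError(
            f"state space (max_cn+1)^n = {(max_cn + 1) ** n} exceeds the oracle bound"
        )
    slices = source.chromosome_slices()
    start = tuple(source.values)
    if max(start, default=0) > max_cn:
        raise UsageError("source exceeds max_cn")
    dist = {start: 0}
    queue = deque([start])
    while queue:
        state = queue.popleft()
        d = dist[state] + 1
        for nxt in _bfs_neighbours(state, slices, max_cn):
            if nxt not in dist:
                dist[nxt] = d
                queue.append(nxt)
    return dist


def bfs_oracle(source: CNVector, target: CNVector, max_cn: int) -> int | float:
    """Exact strict-model minimum by exhaustive search (verification oracle)."""
    _check_compatible(source, target)
    if max(target.values, default=0) > max_cn:
        raise UsageError("target exceeds max_cn")
    return bfs_distances(source, max_cn).get(tuple(target.values), UNREACHABLE)


def pairwise_symmetric(vectors: Sequence[CNVector]) -> np.ndarray:
    """Square matrix of relaxed distances among ``vectors``."""
    n = len(vectors)
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = symmetric_distance(vectors[i], vectors[j])
    return out
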