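"""Truncating per-dimension hits into candidate multivariate sequences.

Per-dimension kNN search returns univariate windows that rarely start at
exactly the same time across dimensions.  Truncation turns them into aligned
multivariate candidates in four steps:

1. **Group** — matches are joined whenever they come from the same source and
   overlap by strictly more than half the window length; groups are the
   connected components of that relation (a match overlapping nothing forms a
   singleton).
2. **Delete isolated** — a group covering fewer than half the dimensions
   (``2 * |members| < n_dims``) is discarded.
3. **Align** — each surviving group becomes one candidate window starting at
   the rounded mean of its members' starts; a dimension covered by a member
   reuses that member's stored distance (cheap), uncovered dimensions are
   measured afresh against the aligned window.
4. **Reorder** — candidates are re-ranked per dimension by those distances.

Whole matching degenerates cleanly: matches on the same item overlap fully and
matches on different items not at all, so groups coincide with items and the
aligned window is the item itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .data_model import warn_once
from .dtw_search import Match

__all__ = [
    "MatchGroup",
    "CandidateMTS",
    "group_matches",
    "delete_isolated",
    "align_group",
    "reorder_candidates",
]

Measure = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class MatchGroup:
    """A connected set of per-dimension matches from one source."""

    group_id: int
    members: list[Match] = field(default_factory=list)

    @property
    def dims(self) -> set[int]:
        return {m.dim for m in self.members}

    @property
    def source_id(self) -> str:
        return self.members[0].source_id


@dataclass
class CandidateMTS:
    """An aligned candidate multivariate similar sequence."""

    source_id: str
    start: int
    length: int
    per_dim_distance: np.ndarray
    group_id: int
    n_source_dims: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.source_id, self.start)


def _overlap(a: Match, b: Match) -> float:
    if a.source_id != b.source_id:
        return 0.0
    return max(0.0, min(a.start + a.length, b.start + b.length) - max(a.start, b.start))


def group_matches(matches: Sequence[Match], l: int) -> list[MatchGroup]:
    """Partition matches into connected components of "overlap > l/2"."""
    n = len(matches)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if _overlap(matches[i], matches[j]) > l / 2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    buckets: dict[int, list[Match]] = {}
    for i, m in enumerate(matches):
        buckets.setdefault(find(i), []).append(m)
    groups = sorted(
        buckets.values(),
        key=lambda ms: (ms[0].source_id, min(m.start for m in ms), min(m.dim for m in ms)),
    )
    return [
        MatchGroup(gid, sorted(ms, key=lambda m: (m.dim, m.start, m.distance)))
        for gid, ms in enumerate(groups, start=1)
    ]


def delete_isolated(groups: Sequence[MatchGroup], n_dims: int) -> list[MatchGroup]:
    """Keep the groups whose member count reaches half the dimensions."""
    if n_dims < 1:
        raise ValueError("n_dims must be >= 1")
    return [g for g in groups if 2 * len(g.members) >= n_dims]


def align_group(
    group: MatchGroup,
    query_pc: np.ndarray,
    data_pc: Mapping[str, np.ndarray],
    measure: Measure,
    recompute_all: bool = False,
) -> CandidateMTS | None:
    """Collapse a group into one candidate window at the mean start time.

    The start is the arithmetic mean of member starts rounded half-up.  For
    each dimension the stored distance of a covering member is reused unless
    ``recompute_all`` is set, in which case (and for uncovered dimensions)
    the distance is measured between the query's series and the aligned
    window.  A window running past the series end cannot be formed; the group
    is dropped with a warning and ``None`` is returned.
    """
    members = group.members
    l = members[0].length
    src = members[0].source_id
    start = math.floor(sum(m.start for m in members) / len(members) + 0.5)
    series = data_pc[src]
    if start + l > series.shape[0]:
        warn_once(
            f"group {group.group_id}: aligned window [{start}, {start + l}) "
            f"exceeds series {src!r}; group dropped"
        )
        return None
    p = query_pc.shape[1]
    stored: dict[int, float] = {}
    for m in members:
        if m.dim not in stored or m.distance < stored[m.dim]:
            stored[m.dim] = m.distance
    dists = np.empty(p)
    for i in range(p):
        if i in stored and not recompute_all:
            dists[i] = stored[i]
        else:
            dists[i] = measure(query_pc[:, i], series[start : start + l, i])
    return CandidateMTS(src, start, l, dists, group.group_id, len(stored))


def reorder_candidates(
    candidates: Sequence[CandidateMTS],
) -> list[list[CandidateMTS]]:
    """Per-dimension rankings of candidates by their aligned distances.

    Ties break by earlier start, then group id.
    """
    if not candidates:
        return []
    p = len(candidates[0].per_dim_distance)
    return [
        sorted(
            candidates,
            key=lambda c: (c.per_dim_distance[i], c.start, c.group_id),
        )
        for i in range(p)
    ]
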