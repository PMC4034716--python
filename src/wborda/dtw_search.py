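"""Constrained dynamic time warping and per-dimension univariate kNN search.

DTW aligns two series along a monotone warping path; the distance here is the
square root of the minimum cumulative sum of squared pointwise differences
(symmetric step pattern, no slope weights).  Warping is restricted to a
Sakoe-Chiba band: with band width ``w = max(1, ceil(band_fraction * max_len))``
the allowed cells satisfy ``|i - j| <= w - 1``, so width 1 permits only the
diagonal and the distance degenerates to Euclidean on equal-length series.
The default band fraction is 0.05 (5% of the longer series).

Two search modes are provided, both operating on a single principal-component
dimension:

* whole matching — rank every item in a collection by DTW distance to the
  query's same-dimension series;
* subsequence matching — slide a length-l window over a long series, rank all
  windows, and greedily keep the best non-redundant ones (windows overlapping
  an already-selected window by more than an exclusion zone, default l/2, are
  skipped, as are windows overlapping the query's own position when the query
  was cut from the long series).

Ties in distance break deterministically: smaller start index, then
lexicographic source id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Match",
    "MatchList",
    "InfeasibleBandError",
    "band_width",
    "dtw_distance",
    "knn_whole_matching",
    "knn_subsequence",
    "window_overlap",
]


class InfeasibleBandError(ValueError):
    """The band is too narrow to admit any warping path."""


@dataclass(frozen=True)
class Match:
    """One univariate similar sequence found in one dimension."""

    dim: int
    source_id: str
    start: int
    length: int
    distance: float


@dataclass
class MatchList:
    """The k' nearest univariate sequences of one dimension, best first."""

    dim: int
    matches: list[Match] = field(default_factory=list)
    kprime: int = 0

    def __iter__(self):
        return iter(self.matches)

    def __len__(self) -> int:
        return len(self.matches)


def band_width(len_a: int, len_b: int, band_fraction: float) -> int:
    """Sakoe-Chiba band width: ``max(1, ceil(band_fraction * max(len_a, len_b)))``."""
    if not 0 < band_fraction <= 1:
        raise ValueError("band_fraction must lie in (0, 1]")
    return max(1, math.ceil(band_fraction * max(len_a, len_b)))


def _banded_cost(a: Sequence[float], b: Sequence[float], r: int) -> float:
    """Minimum cumulative squared cost over paths with ``|i - j| <= r``."""
    la, lb = len(a), len(b)
    inf = math.inf
    prev = [inf] * (lb + 1)
    prev[0] = 0.0
    for i in range(1, la + 1):
        cur = [inf] * (lb + 1)
        ai = a[i - 1]
        lo = max(1, i - r)
        hi = min(lb, i + r)
        for j in range(lo, hi + 1):
            d = ai - b[j - 1]
            best = prev[j]
            pd = prev[j - 1]
            if pd < best:
                best = pd
            cd = cur[j - 1]
            if cd < best:
                best = cd
            cur[j] = d * d + best
        prev = cur
    return prev[lb]


def dtw_distance(a, b, band_fraction: float = 0.05) -> float:
    """Band-constrained DTW distance between two univariate series.

    Symmetric in its arguments; zero iff the optimal path accumulates no cost
    (in particular ``dtw_distance(a, a) == 0``).  Raises
    :class:`InfeasibleBandError` when the length difference exceeds what the
    band admits.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("sequences must be nonempty")
    w = band_width(a.size, b.size, band_fraction)
    if abs(a.size - b.size) > w - 1:
        raise InfeasibleBandError(
            f"length difference {abs(a.size - b.size)} exceeds band width {w}"
        )
    return math.sqrt(_banded_cost(a.tolist(), b.tolist(), w - 1))


def _sorted_matches(matches: list[Match]) -> list[Match]:
    return sorted(matches, key=lambda m: (m.distance, m.start, m.source_id))


def knn_whole_matching(
    query_pc: np.ndarray,
    items_pc: Mapping[str, np.ndarray],
    dim: int,
    kprime: int,
    band_fraction: float = 0.05,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> MatchList:
    """The k' items whose dim-th PC series are nearest the query's.

    ``items_pc`` maps item id to its own m x p principal-component matrix; the
    query item itself (named in ``exclude``) plays the role of s_0 and is never
    returned.
    """
    q = np.asarray(query_pc)[:, dim]
    candidates = [sid for sid in items_pc if sid not in exclude]
    if kprime > len(candidates):
        raise ValueError(
            f"kprime={kprime} exceeds the {len(candidates)} available items"
        )
    matches = [
        Match(
            dim,
            sid,
            0,
            int(items_pc[sid].shape[0]),
            dtw_distance(q, items_pc[sid][:, dim], band_fraction),
        )
        for sid in candidates
    ]
    return MatchList(dim, _sorted_matches(matches)[:kprime], kprime)


def window_overlap(start_a: int, start_b: int, length: int) -> int:
    """Number of shared time points of two equal-length windows."""
    return max(0, length - abs(start_a - start_b))


def knn_subsequence(
    query_dim: np.ndarray,
    long_dim: np.ndarray,
    kprime: int,
    band_fraction: float = 0.05,
    exclusion_zone: float | None = None,
    source_id: str = "long",
    dim: int = 0,
    query_start: int | None = None,
) -> MatchList:
    """The k' best non-redundant length-l windows of a long univariate series.

    All sliding windows are ranked by DTW distance to ``query_dim``; selection
    is greedy in that order, skipping windows that overlap a previously
    selected window — or the query's own position when ``query_start`` is
    given — by more than ``exclusion_zone`` points (default ``l/2``).
    """
    q = np.asarray(query_dim, dtype=float).ravel()
    s = np.asarray(long_dim, dtype=float).ravel()
    l, M = q.size, s.size
    if l > M:
        raise ValueError(f"query length {l} exceeds series length {M}")
    if kprime < 1:
        raise ValueError("kprime must be >= 1")
    if exclusion_zone is None:
        exclusion_zone = l / 2
    w = band_width(l, l, band_fraction)
    r = w - 1
    qlist = q.tolist()
    slist = s.tolist()
    ranked = sorted(
        (math.sqrt(_banded_cost(qlist, slist[t : t + l], r)), t)
        for t in range(M - l + 1)
    )
    selected: list[Match] = []
    for dist, t in ranked:
        if query_start is not None and window_overlap(t, query_start, l) > exclusion_zone:
            continue
        if any(window_overlap(t, m.start, l) > exclusion_zone for m in selected):
            continue
        selected.append(Match(dim, source_id, t, l, dist))
        if len(selected) == kprime:
            break
    if len(selected) < kprime:
        raise ValueError(
            f"only {len(selected)} admissible windows for kprime={kprime} "
            f"(exclusion_zone={exclusion_zone})"
        )
    return MatchList(dim, selected, kprime)
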