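"""BORDA voting, the weighted voting score, and the end-to-end kNN search.

Classical BORDA voting aggregates rankings by positional points: within each
voter's ranking the first of ``e`` candidates earns ``e`` points, the second
``e - 1``, down to 1.  The baseline multivariate measure (here ``"borda"``)
applies this to the per-dimension candidate rankings after eliminating
candidates that appear in fewer than half the dimensions.

Positional points ignore how *much* better one neighbor is than the next.
The weighted scheme replaces them with a score built from the actual distance
gaps: with ``d_i`` the candidate's distance in dimension ``j``, ``d_k'`` the
distance of that dimension's worst-ranked candidate and ``w_j`` the
dimension's eigenvalue weight,

    vs_i = w_j * (1 + k' * (1 - d_i / d_k')).

The query itself (distance 0) would anchor at ``w_j * (k' + 1)`` and the
worst neighbor at ``w_j``; the score decreases strictly in ``d_i`` and
depends on distances only through the ratio ``d_i / d_k'``, so it is
invariant to rescaling any single dimension.  A candidate's weighted BORDA
score is the sum of these over dimensions; the top ``k`` candidates are the
multivariate nearest neighbors.

:func:`knn_search` orchestrates the full pipeline — per-item PCA, retained
component selection, per-dimension constrained-DTW search, truncation, and
final ranking — for both whole matching (corpus = dataset of items) and
subsequence matching (corpus = one long series).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .config import SearchConfig
from .data_model import LongSeries, MTSDataset, MTSItem, warn_once
from .dtw_search import Match, MatchList, dtw_distance, knn_subsequence, knn_whole_matching
from .pca_weights import (
    WeightVector,
    choose_num_components,
    compute_weights,
    fit_pca,
    project,
)
from .truncation import (
    CandidateMTS,
    align_group,
    delete_isolated,
    group_matches,
    reorder_candidates,
)

__all__ = [
    "Ranking",
    "ScoredCandidate",
    "SearchResult",
    "borda_scores",
    "weighted_voting_score",
    "s_borda_rank",
    "s_wborda_rank",
    "knn_search",
]

DistFn = Callable[[int, str, np.ndarray, str, np.ndarray], float]


@dataclass
class Ranking:
    """One voter's (dimension's) preference list, most-preferred first."""

    voter_id: object
    candidates: list

    def __post_init__(self) -> None:
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError(
                f"ranking of voter {self.voter_id!r} contains duplicate candidates"
            )


@dataclass
class ScoredCandidate:
    """A candidate with its aggregated voting score."""

    candidate: object
    score: float
    votes: int


@dataclass
class SearchResult:
    """One returned multivariate neighbor."""

    rank: int
    source_id: str
    start: int
    length: int
    score: float
    votes: int
    label: str | None = None
    per_dim_distance: np.ndarray | None = None


def borda_scores(rankings: Sequence[Ranking], top_points: int) -> dict:
    """Classical BORDA: position ``j`` (1-based) earns ``top_points - j + 1``.

    A candidate's score sums over rankings; absence from a ranking earns 0.
    """
    scores: dict = {}
    for ranking in rankings:
        if len(ranking.candidates) > top_points:
            raise ValueError(
                f"ranking of voter {ranking.voter_id!r} has more than "
                f"{top_points} candidates"
            )
        for pos, cand in enumerate(ranking.candidates, start=1):
            scores[cand] = scores.get(cand, 0) + (top_points - pos + 1)
    return scores


def weighted_voting_score(
    d_i: float, d_kprime: float, kprime: int, w_j: float
) -> float:
    """The distance-gap voting score ``w_j * (1 + k' * (1 - d_i / d_k'))``.

    When every candidate coincides with the query (``d_k' = 0``) all scores
    collapse to the query anchor ``w_j * (1 + k')``.
    """
    if kprime < 1:
        raise ValueError("kprime must be >= 1")
    if w_j < 0:
        raise ValueError("weight must be nonnegative")
    if d_i < 0:
        raise ValueError("distance must be nonnegative")
    if d_kprime == 0.0:
        return w_j * (1 + kprime)
    if d_i > d_kprime * (1 + 1e-12):
        raise ValueError(
            f"d_i={d_i} exceeds the worst-ranked distance d_kprime={d_kprime}"
        )
    return w_j * (1 + kprime * (1 - d_i / d_kprime))


def _top_k(scored: list[ScoredCandidate], k: int, what: str) -> list[ScoredCandidate]:
    if len(scored) < k:
        warn_once(f"only {len(scored)} {what} available for k={k}")
    return scored[:k]


def s_borda_rank(
    per_dim_rankings: Sequence[Ranking],
    n_dims: int,
    k: int,
    tiebreak: Callable[[object], tuple] | None = None,
) -> list[ScoredCandidate]:
    """Rank candidates by summed positional points across dimensions.

    Candidates voted for in fewer than half the dimensions are eliminated
    before scoring; each surviving candidate earns points from its position
    in the full per-dimension list (top position = list length).
    """
    votes: dict = {}
    for ranking in per_dim_rankings:
        for cand in ranking.candidates:
            votes[cand] = votes.get(cand, 0) + 1
    survivors = {c for c, v in votes.items() if 2 * v >= n_dims}
    scores: dict = {c: 0 for c in survivors}
    for ranking in per_dim_rankings:
        top_points = len(ranking.candidates)
        for pos, cand in enumerate(ranking.candidates, start=1):
            if cand in survivors:
                scores[cand] += top_points - pos + 1
    key = tiebreak if tiebreak is not None else lambda c: (c,)
    ordered = sorted(scores, key=lambda c: (-scores[c],) + tuple(key(c)))
    scored = [ScoredCandidate(c, float(scores[c]), votes[c]) for c in ordered]
    return _top_k(scored, k, "candidates survive elimination")


def s_wborda_rank(
    candidates: Sequence[CandidateMTS],
    weights: WeightVector,
    k: int,
    kprime: int | None = None,
) -> list[ScoredCandidate]:
    """Rank aligned candidates by their summed weighted voting scores.

    Per dimension the worst-ranked anchor ``d_k'`` is the largest distance
    among the candidates and ``k'`` defaults to the number of candidates
    ranked in that dimension.
    """
    if not candidates:
        warn_once("no candidates to rank")
        return []
    p = len(weights)
    kp = kprime if kprime is not None else len(candidates)
    d_anchor = [max(c.per_dim_distance[j] for c in candidates) for j in range(p)]
    scored = [
        ScoredCandidate(
            c,
            sum(
                weighted_voting_score(
                    float(c.per_dim_distance[j]), float(d_anchor[j]), kp,
                    float(weights.weights[j]),
                )
                for j in range(p)
            ),
            c.n_source_dims,
        )
        for c in candidates
    ]
    scored.sort(key=lambda s: (-s.score, s.candidate.start, s.candidate.key))
    return _top_k(scored, k, "candidates")


# ---------------------------------------------------------------------------
# end-to-end search
# ---------------------------------------------------------------------------


def _default_dist(band_fraction: float) -> DistFn:
    def dist(dim, id_a, series_a, id_b, series_b):
        return dtw_distance(series_a, series_b, band_fraction)

    return dist


def _candidates_from_groups(
    match_lists: Sequence[MatchList],
    query_pc: np.ndarray,
    data_pc: Mapping[str, np.ndarray],
    l: int,
    p: int,
    config: SearchConfig,
    measure,
) -> list[CandidateMTS]:
    matches: list[Match] = [m for ml in match_lists for m in ml]
    groups = group_matches(matches, l)
    surviving = delete_isolated(groups, p)
    if not surviving and groups:
        # every group is isolated; keep the best-covered ones so the search
        # (and 1NN classification built on it) still returns an answer
        best = max(len(g.members) for g in groups)
        surviving = [g for g in groups if len(g.members) == best]
        warn_once(
            "all groups isolated; falling back to the "
            f"{len(surviving)} best-covered group(s)"
        )
    candidates = []
    for g in surviving:
        cand = align_group(g, query_pc, data_pc, measure, config.recompute_all)
        if cand is not None:
            candidates.append(cand)
    return candidates


def _rank_candidates(
    candidates: list[CandidateMTS],
    weights: WeightVector,
    p: int,
    config: SearchConfig,
) -> list[ScoredCandidate]:
    if config.measure == "wborda":
        return s_wborda_rank(candidates, weights, config.k)
    by_key = {c.key: c for c in candidates}
    rankings = [
        Ranking(j, [c.key for c in order])
        for j, order in enumerate(reorder_candidates(candidates))
    ]
    scored = s_borda_rank(
        rankings,
        p,
        config.k,
        tiebreak=lambda key: (by_key[key].start, key),
    )
    return [
        ScoredCandidate(by_key[s.candidate], s.score, s.votes) for s in scored
    ]


def _results(scored: list[ScoredCandidate], labels: Mapping[str, str | None]):
    return [
        SearchResult(
            rank,
            s.candidate.source_id,
            s.candidate.start,
            s.candidate.length,
            s.score,
            s.votes,
            labels.get(s.candidate.source_id),
            s.candidate.per_dim_distance,
        )
        for rank, s in enumerate(scored, start=1)
    ]


def _whole_search(
    query_id: str,
    query_pc: np.ndarray,
    items_pc: Mapping[str, np.ndarray],
    weights: WeightVector,
    config: SearchConfig,
    dist_fn: DistFn,
) -> list[ScoredCandidate]:
    """Whole-matching pipeline on pre-projected PC series."""
    p = query_pc.shape[1]
    n_items = len(items_pc) - (1 if query_id in items_pc else 0)
    kprime = min(config.resolved_kprime(), n_items)

    def pair(dim, sid):
        return dist_fn(dim, query_id, query_pc[:, dim], sid, items_pc[sid][:, dim])

    match_lists = []
    for dim in range(p):
        ranked = sorted(
            (
                Match(dim, sid, 0, int(items_pc[sid].shape[0]), pair(dim, sid))
                for sid in items_pc
                if sid != query_id
            ),
            key=lambda m: (m.distance, m.start, m.source_id),
        )
        if kprime > len(ranked):
            raise ValueError(f"kprime={kprime} exceeds {len(ranked)} items")
        match_lists.append(MatchList(dim, ranked[:kprime], kprime))

    def measure(q_series, s_series):
        return dtw_distance(q_series, s_series, config.band_fraction)

    candidates = _candidates_from_groups(
        match_lists, query_pc, items_pc, query_pc.shape[0], p, config, measure
    )
    return _rank_candidates(candidates, weights, p, config)


def _search_dataset(
    query: MTSItem, corpus: MTSDataset, config: SearchConfig, dist_fn: DistFn | None
) -> list[SearchResult]:
    pcas = {item.id: fit_pca(item) for item in corpus if item.id != query.id}
    q_pca = fit_pca(query)
    eigvals = [pcas[sid].eigenvalues for sid in pcas]
    p = config.p or choose_num_components(eigvals, config.pca_threshold)
    weights = compute_weights(eigvals, p, config.strategy, config.normalize)
    items_pc = {
        sid: project(corpus.get(sid), pcas[sid], p) for sid in pcas
    }
    query_pc = project(query, q_pca, p)
    if dist_fn is None:
        dist_fn = _default_dist(config.band_fraction)
    scored = _whole_search(query.id, query_pc, items_pc, weights, config, dist_fn)
    labels = {item.id: item.label for item in corpus}
    return _results(scored, labels)


def _search_long(
    query: MTSItem,
    corpus: LongSeries,
    config: SearchConfig,
    query_start: int | None,
) -> list[SearchResult]:
    long_item = MTSItem(corpus.id, corpus.values)
    pca = fit_pca(long_item)
    p = config.p or choose_num_components([pca.eigenvalues], config.pca_threshold)
    weights = compute_weights([pca.eigenvalues], p, config.strategy, config.normalize)
    long_pc = project(long_item, pca, p)
    query_pc = (query.values - pca.mean) @ pca.eigenvectors[:, :p]
    l = query.m
    kprime = config.resolved_kprime()
    ez = config.exclusion_zone if config.exclusion_zone is not None else l / 2
    match_lists = [
        knn_subsequence(
            query_pc[:, dim],
            long_pc[:, dim],
            kprime,
            config.band_fraction,
            ez,
            source_id=corpus.id,
            dim=dim,
            query_start=query_start,
        )
        for dim in range(p)
    ]

    def measure(q_series, s_series):
        return dtw_distance(q_series, s_series, config.band_fraction)

    candidates = _candidates_from_groups(
        match_lists, query_pc, {corpus.id: long_pc}, l, p, config, measure
    )
    scored = _rank_candidates(candidates, weights, p, config)
    return _results(scored, {corpus.id: None})


def knn_search(
    query: MTSItem,
    corpus: MTSDataset | LongSeries,
    config: SearchConfig | None = None,
    dist_fn: DistFn | None = None,
    query_start: int | None = None,
) -> list[SearchResult]:
    """Top-k multivariate neighbors of ``query`` in ``corpus``.

    Whole matching when ``corpus`` is a dataset of items (the query item, if
    present, is excluded); subsequence matching when ``corpus`` is a long
    series (``query_start`` marks the query's own position to skip when the
    query was cut from the series).  ``dist_fn`` lets callers inject a cached
    pairwise distance (used by repeated cross-validation).
    """
    config = config or SearchConfig()
    if isinstance(corpus, LongSeries):
        return _search_long(query, corpus, config, query_start)
    return _search_dataset(query, corpus, config, dist_fn)
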