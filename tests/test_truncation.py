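import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wborda import (
    Match,
    align_group,
    delete_isolated,
    dtw_distance,
    group_matches,
    reorder_candidates,
)


def _memberships(groups):
    return sorted(
        tuple(sorted((m.dim, m.start) for m in g.members)) for g in groups
    )


class TestGrouping:
    def test_three_dimension_scenario_yields_five_groups(self, figure_matches):
        groups = group_matches(figure_matches, l=20)
        assert len(groups) == 5
        assert _memberships(groups) == sorted(
            [
                tuple(sorted([(0, 100), (1, 108), (2, 116)])),
                ((2, 300),),
                tuple(sorted([(0, 400), (1, 409)])),
                tuple(sorted([(0, 500), (2, 507)])),
                ((1, 600),),
            ]
        )

    def test_exactly_half_overlap_stays_separate(self):
        matches = [Match(0, "s", 0, 10, 0.1), Match(1, "s", 5, 10, 0.2)]
        assert len(group_matches(matches, l=10)) == 2

    def test_transitive_chain_forms_one_group(self):
        matches = [
            Match(0, "s", 0, 10, 0.1),
            Match(1, "s", 4, 10, 0.2),
            Match(2, "s", 8, 10, 0.3),
        ]
        groups = group_matches(matches, l=10)
        assert len(groups) == 1
        assert len(groups[0].members) == 3

    def test_different_sources_never_overlap(self):
        matches = [Match(0, "a", 0, 10, 0.1), Match(1, "b", 0, 10, 0.2)]
        assert len(group_matches(matches, l=10)) == 2

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 60), min_size=1, max_size=10))
    def test_grouping_is_a_partition(self, starts):
        matches = [Match(i % 3, "s", t, 12, 0.1 * i) for i, t in enumerate(starts)]
        groups = group_matches(matches, l=12)
        regrouped = sorted(
            (m.dim, m.start, m.distance) for g in groups for m in g.members
        )
        assert regrouped == sorted((m.dim, m.start, m.distance) for m in matches)


class TestIsolation:
    def test_singletons_deleted_in_three_dimensions(self, figure_matches):
        groups = group_matches(figure_matches, l=20)
        surviving = delete_isolated(groups, n_dims=3)
        assert len(surviving) == 3
        assert all(len(g.members) >= 2 for g in surviving)

    @pytest.mark.parametrize(
        "n_dims,size,kept",
        [(3, 2, True), (3, 1, False), (4, 2, True), (4, 1, False), (1, 1, True)],
    )
    def test_half_dimension_threshold(self, n_dims, size, kept):
        groups = group_matches(
            [Match(d, "s", d, 10, 0.1) for d in range(size)], l=10
        )
        assert len(groups) == 1
        assert bool(delete_isolated(groups, n_dims)) is kept

    def test_deletion_monotone_in_dimension_count(self, figure_matches):
        groups = group_matches(figure_matches, l=20)
        counts = [len(delete_isolated(groups, n)) for n in range(1, 7)]
        assert counts == sorted(counts, reverse=True)


class TestAlignment:
    def _measure(self, q, s):
        return dtw_distance(q, s, 1.0)

    def test_common_start_and_distance_reuse(self, rng):
        data = {"s": rng.normal(size=(100, 2))}
        q = rng.normal(size=(10, 2))
        matches = [Match(0, "s", 40, 10, 0.11), Match(1, "s", 40, 10, 0.22)]
        group = group_matches(matches, l=10)[0]
        cand = align_group(group, q, data, self._measure)
        assert cand.start == 40
        np.testing.assert_array_equal(cand.per_dim_distance, [0.11, 0.22])

    def test_uncovered_dimension_recomputed(self, rng):
        data = {"s": rng.normal(size=(100, 3))}
        q = rng.normal(size=(10, 3))
        matches = [Match(0, "s", 40, 10, 0.11), Match(1, "s", 42, 10, 0.22)]
        group = group_matches(matches, l=10)[0]
        cand = align_group(group, q, data, self._measure)
        assert cand.start == 41
        assert cand.per_dim_distance[2] == pytest.approx(
            self._measure(q[:, 2], data["s"][41:51, 2])
        )

    def test_mean_start_rounds_half_up(self, rng):
        from wborda import MatchGroup

        data = {"s": rng.normal(size=(60, 1))}
        q = rng.normal(size=(12, 1))
        group = MatchGroup(
            1, [Match(0, "s", 10, 12, 0.1), Match(0, "s", 20, 12, 0.2)]
        )
        cand = align_group(group, q, data, self._measure)
        assert cand.start == 15
        assert cand.length == 12

    def test_window_past_series_end_drops_group(self, rng):
        data = {"s": rng.normal(size=(30, 1))}
        q = rng.normal(size=(10, 1))
        matches = [Match(0, "s", 22, 10, 0.1), Match(0, "s", 28, 10, 0.2)]
        group = group_matches(matches, l=10)[0]
        with pytest.warns(RuntimeWarning, match="dropped"):
            assert align_group(group, q, data, self._measure) is None

    def test_recompute_all_overrides_stored(self, rng):
        data = {"s": rng.normal(size=(50, 1))}
        q = rng.normal(size=(10, 1))
        matches = [Match(0, "s", 20, 10, 123.0)]
        group = group_matches(matches, l=10)[0]
        cand = align_group(group, q, data, self._measure, recompute_all=True)
        assert cand.per_dim_distance[0] == pytest.approx(
            self._measure(q[:, 0], data["s"][20:30, 0])
        )


class TestReorder:
    def _candidates(self, dists, starts=None):
        from wborda import CandidateMTS

        starts = starts or list(range(len(dists)))
        return [
            CandidateMTS("s", starts[i], 10, np.asarray(d, dtype=float), i + 1, len(d))
            for i, d in enumerate(dists)
        ]

    def test_orders_by_per_dimension_distance(self):
        cands = self._candidates([[0.3], [0.1], [0.2]])
        order = reorder_candidates(cands)[0]
        assert [c.group_id for c in order] == [2, 3, 1]

    def test_ties_break_on_earlier_start(self):
        cands = self._candidates([[0.5], [0.5]], starts=[9, 3])
        order = reorder_candidates(cands)[0]
        assert [c.start for c in order] == [3, 9]

    def test_matches_exhaustive_sort(self, rng):
        dists = rng.uniform(size=(6, 3))
        cands = self._candidates(dists.tolist())
        for dim, order in enumerate(reorder_candidates(cands)):
            expected = sorted(
                cands, key=lambda c: (c.per_dim_distance[dim], c.start, c.group_id)
            )
            assert [c.group_id for c in order] == [c.group_id for c in expected]
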