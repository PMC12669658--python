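"""Overlap graph construction, pruning and event-type classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spark3d.events import (Event, OverlapRecord, build_components,
                            classify_component, classify_events,
                            compute_overlaps, select_overlaps)
from spark3d.io import AnalysisConfig
from spark3d.segment import Focus, LabelVolume


def _lv(arr, channel="edu"):
    return LabelVolume(np.asarray(arr, dtype=np.int32), 0.04, channel)


def _focus(fid, channel, nucleus=1):
    return Focus(fid, channel, nucleus, 60, 60 * 0.04 ** 3,
                 (0.1 * fid, 0.2, 0.3), 100.0, 1.0)


class TestComputeOverlaps:
    def test_disjoint_labels_empty(self):
        a = np.zeros((2, 4, 4)); a[0, :2, :2] = 1
        b = np.zeros((2, 4, 4)); b[1, 2:, 2:] = 1
        assert compute_overlaps(_lv(a), _lv(b, "dutp")) == []

    def test_identical_volumes_full_overlap(self):
        a = np.zeros((4, 5, 5)); a[:, 1:4, 1:4] = 1  # 36 voxels
        recs = compute_overlaps(_lv(a), _lv(a.copy(), "dutp"))
        assert len(recs) == 1
        assert recs[0].overlap_voxels == 36

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            a = rng.integers(0, 4, (3, 6, 6))
            b = rng.integers(0, 4, (3, 6, 6))
            recs = compute_overlaps(_lv(a), _lv(b, "dutp"))
            got = {(r.focus_a, r.focus_b): r.overlap_voxels for r in recs}
            want = {}
            for idx in np.ndindex(a.shape):
                if a[idx] > 0 and b[idx] > 0:
                    key = (int(a[idx]), int(b[idx]))
                    want[key] = want.get(key, 0) + 1
            assert got == want

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_overlaps(_lv(np.zeros((2, 4, 4))),
                             _lv(np.zeros((2, 4, 5)), "dutp"))


class TestSelectOverlaps:
    def test_twenty_percent_of_max_rule(self):
        # one EdU focus with overlaps of 100, 25, 10 voxels; each dUTP
        # partner has only this overlap, so only the EdU perspective limits
        recs = [OverlapRecord(1, 1, 100), OverlapRecord(1, 2, 25),
                OverlapRecord(1, 3, 10)]
        out = {r.focus_b: r.kept for r in select_overlaps(recs)}
        assert out == {1: True, 2: True, 3: False}  # 25% kept, 10% dropped

    def test_single_overlap_always_kept(self):
        out = select_overlaps([OverlapRecord(3, 7, 1)])
        assert out[0].kept and out[0].rel_score_a == 1.0

    def test_exactly_twenty_percent_dropped(self):
        recs = [OverlapRecord(1, 1, 100), OverlapRecord(1, 2, 20)]
        out = {r.focus_b: r.kept for r in select_overlaps(recs)}
        assert out == {1: True, 2: False}  # strict greater-than

    def test_tied_maxima_both_kept(self):
        recs = [OverlapRecord(1, 1, 50), OverlapRecord(1, 2, 50)]
        out = select_overlaps(recs)
        assert all(r.kept and r.rel_score_a == 1.0 for r in out)

    def test_and_rule_requires_both_endpoints(self):
        # overlap (1,1): 30 voxels is 100% of EdU1's max but only 15% of
        # dUTP1's max (200) -> dropped under "and", kept under "or"
        recs = [OverlapRecord(1, 1, 30), OverlapRecord(2, 1, 200)]
        kept_and = {(r.focus_a, r.focus_b): r.kept for r in select_overlaps(recs)}
        kept_or = {(r.focus_a, r.focus_b): r.kept
                   for r in select_overlaps(recs, rule="or")}
        assert kept_and[(1, 1)] is False
        assert kept_or[(1, 1)] is True


class TestSelectOverlapsProperties:
    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4),
                              st.integers(1, 500)),
                    min_size=1, max_size=12))
    def test_invariants_hold_on_arbitrary_records(self, triples):
        recs = [OverlapRecord(a, b, v) for a, b, v in triples]
        out = select_overlaps(recs)
        for r in out:
            assert 0 < r.rel_score_a <= 1 and 0 < r.rel_score_b <= 1
            # a focus's own maximum overlap always passes the >20% rule
            if r.rel_score_a == 1.0 and r.rel_score_b == 1.0:
                assert r.kept
            # symmetric AND rule: kept implies both endpoints pass
            if r.kept:
                assert r.rel_score_a > 0.2 and r.rel_score_b > 0.2

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(1, 4), st.integers(1, 4),
                              st.integers(1, 500)),
                    min_size=1, max_size=12))
    def test_and_rule_symmetric_under_channel_swap(self, triples):
        recs = [OverlapRecord(a, b, v) for a, b, v in triples]
        fwd = {(r.focus_a, r.focus_b): r.kept for r in select_overlaps(recs)}
        swp = [OverlapRecord(b, a, v) for a, b, v in triples]
        rev = {(r.focus_b, r.focus_a): r.kept for r in select_overlaps(swp)}
        assert fwd == rev


class TestComponents:
    def test_isolated_foci_are_singletons(self):
        comps = build_components([1, 2, 3], [1, 2], [])
        assert len(comps) == 5
        assert all(len(e) + len(d) == 1 for e, d, _ in comps)

    def test_chain_is_one_component(self):
        recs = [OverlapRecord(1, 1, 10), OverlapRecord(2, 1, 10)]
        comps = build_components([1, 2], [1], recs)
        assert len(comps) == 1
        assert comps[0][0] == {1, 2} and comps[0][1] == {1}

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_e, n_d = rng.integers(1, 5), rng.integers(1, 5)
            edges = [(int(a) + 1, int(b) + 1)
                     for a in range(n_e) for b in range(n_d)
                     if rng.random() < 0.4]
            recs = [OverlapRecord(a, b, 10) for a, b in edges]
            comps = build_components(range(1, n_e + 1), range(1, n_d + 1), recs)
            # brute-force union-find over node tuples
            parent = {("e", i): ("e", i) for i in range(1, n_e + 1)}
            parent.update({("d", i): ("d", i) for i in range(1, n_d + 1)})

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for a, b in edges:
                parent[find(("e", a))] = find(("d", b))
            groups = {}
            for node in parent:
                groups.setdefault(find(node), set()).add(node)
            want = sorted(
                (frozenset(i for s, i in g if s == "e"),
                 frozenset(i for s, i in g if s == "d"))
                for g in groups.values())
            got = sorted((e, d) for e, d, _ in comps)
            assert got == want

    def test_dangling_focus_id_rejected(self):
        with pytest.raises(ValueError):
            build_components([1], [1], [OverlapRecord(2, 1, 5)])


class TestClassifyComponent:
    @pytest.mark.parametrize("edu,dutp,edges,expected", [
        ({1}, set(), set(), "single_colour"),
        (set(), {1}, set(), "single_colour"),
        ({1}, {1}, {(1, 1)}, "ongoing"),
        ({1}, {1, 2}, {(1, 1), (1, 2)}, "initiation"),
        ({1, 2}, {1}, {(1, 1), (2, 1)}, "termination"),
        ({1, 2}, {1, 2}, {(1, 1), (2, 1), (2, 2)}, "crowded"),  # 4-focus chain
        ({1, 2}, {1}, {(1, 1), (2, 1), (1, 1)}, "termination"),
    ])
    def test_taxonomy(self, edu, dutp, edges, expected):
        assert classify_component(frozenset(edu), frozenset(dutp),
                                  frozenset(edges)) == expected

    def test_empty_component_rejected(self):
        with pytest.raises(ValueError):
            classify_component(frozenset(), frozenset(), frozenset())

    def test_exhaustive_small_graphs_match_rule_checker(self):
        """All bipartite graphs up to 3+3 foci match a brute-force checker."""
        checked = 0
        for n_e in range(0, 4):
            for n_d in range(0, 4):
                if n_e + n_d == 0:
                    continue
                cells = [(a, b) for a in range(1, n_e + 1)
                         for b in range(1, n_d + 1)]
                for bits in itertools.product([0, 1], repeat=len(cells)):
                    edges = {c for c, bit in zip(cells, bits) if bit}
                    # restrict to connected components (classifier precondition)
                    if not _is_connected(n_e, n_d, edges):
                        continue
                    got = classify_component(
                        frozenset(range(1, n_e + 1)),
                        frozenset(range(1, n_d + 1)), frozenset(edges))
                    assert got == _rule_checker(n_e, n_d, edges)
                    checked += 1
        assert checked >= 200


def _is_connected(n_e, n_d, edges):
    nodes = {("e", i) for i in range(1, n_e + 1)} | \
            {("d", i) for i in range(1, n_d + 1)}
    if len(nodes) == 1:
        return True
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[("e", a)].add(("d", b))
        adj[("d", b)].add(("e", a))
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n])
    return seen == nodes


def _rule_checker(n_e, n_d, edges):
    """Literal transcription of the verbal classification rules."""
    if n_e + n_d == 1:
        return "single_colour"
    if n_e + n_d > 3:
        return "crowded"
    deg_e = {i: sum(1 for a, _ in edges if a == i) for i in range(1, n_e + 1)}
    deg_d = {i: sum(1 for _, b in edges if b == i) for i in range(1, n_d + 1)}
    if n_e == 1 and n_d == 1 and edges == {(1, 1)}:
        return "ongoing"
    if n_e == 1 and n_d == 2 and all(deg_d[i] == 1 for i in deg_d) \
            and deg_e[1] == 2:
        return "initiation"
    if n_e == 2 and n_d == 1 and all(deg_e[i] == 1 for i in deg_e) \
            and deg_d[1] == 2:
        return "termination"
    return "crowded"


class TestClassifyEvents:
    def test_all_isolated_zero_retention(self):
        foci_e = [_focus(i, "edu") for i in (1, 2)]
        foci_d = [_focus(i, "dutp") for i in (1, 2, 3)]
        events, retention = classify_events(foci_e, foci_d, [])
        assert len(events) == 5
        assert all(ev.type == "single_colour" for ev in events)
        assert retention.fraction() == 0.0

    def test_partition_every_focus_in_exactly_one_event(self):
        rng = np.random.default_rng(3)
        foci_e = [_focus(i, "edu") for i in range(1, 6)]
        foci_d = [_focus(i, "dutp") for i in range(1, 6)]
        recs = [OverlapRecord(int(a) + 1, int(b) + 1, int(v) + 1)
                for a, b, v in zip(rng.integers(0, 5, 8),
                                   rng.integers(0, 5, 8),
                                   rng.integers(0, 100, 8))]
        events, _ = classify_events(foci_e, foci_d, recs)
        seen_e = [i for ev in events for i in ev.edu_focus_ids]
        seen_d = [i for ev in events for i in ev.dutp_focus_ids]
        assert sorted(seen_e) == [1, 2, 3, 4, 5]
        assert sorted(seen_d) == [1, 2, 3, 4, 5]

    def test_pure_ongoing_retention_one(self):
        foci_e = [_focus(i, "edu") for i in (1, 2)]
        foci_d = [_focus(i, "dutp") for i in (1, 2)]
        recs = [OverlapRecord(1, 1, 40), OverlapRecord(2, 2, 55)]
        events, retention = classify_events(foci_e, foci_d, recs)
        assert {ev.type for ev in events} == {"ongoing"}
        assert retention.fraction() == 1.0

    def test_channel_swap_maps_initiation_to_termination(self):
        """Swapping the channels turns each initiation into a termination
        and vice versa, leaving ongoing/single/crowded counts unchanged."""
        rng = np.random.default_rng(11)
        foci_e = [_focus(i, "edu") for i in range(1, 8)]
        foci_d = [_focus(i, "dutp") for i in range(1, 8)]
        recs = [OverlapRecord(int(a) + 1, int(b) + 1, int(v) + 1)
                for a, b, v in zip(rng.integers(0, 7, 12),
                                   rng.integers(0, 7, 12),
                                   rng.integers(0, 200, 12))]
        fwd, _ = classify_events(foci_e, foci_d, recs)
        swapped = [OverlapRecord(r.focus_b, r.focus_a, r.overlap_voxels)
                   for r in recs]
        rev, _ = classify_events(foci_d, foci_e, swapped)

        def counts(evs):
            out = {}
            for e in evs:
                out[e.type] = out.get(e.type, 0) + 1
            return out

        cf, cr = counts(fwd), counts(rev)
        assert cf.get("initiation", 0) == cr.get("termination", 0)
        assert cf.get("termination", 0) == cr.get("initiation", 0)
        for t in ("ongoing", "single_colour", "crowded"):
            assert cf.get(t, 0) == cr.get(t, 0)
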