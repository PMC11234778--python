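"""Unit and property tests of the signal-summing consensus merge."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from consensv.merge import (
    MergeParams,
    SignalTrack,
    backtrack,
    build_class_signal,
    compute_maxsup,
    gap_merge,
    merge_all,
    resolve_weight,
    sweep_min_callers,
    threshold_segments,
)
from consensv.model import ConsensvError, GenomeInfo, SVCall

from conftest import random_merge_instance


def track(values, sv_class="DEL"):
    return SignalTrack("c1", sv_class, np.asarray(values))


def union_length(intervals):
    covered = set()
    for s, e in intervals:
        covered.update(range(s, e))
    return len(covered)


class TestBuildClassSignal:
    def test_single_call_is_binary(self):
        t = build_class_signal([SVCall("a", "c1", "DEL", 100, 200)], 1000)
        assert t.values[100:200].tolist() == [1] * 100
        assert t.values.sum() == 100

    def test_three_concordant_callers_sum_to_three(self):
        calls = [SVCall(c, "c1", "DEL", 100, 200) for c in "abc"]
        t = build_class_signal(calls, 1000)
        assert set(t.values[100:200]) == {3}
        assert t.values.sum() == 300

    def test_same_caller_overlaps_count_once(self):
        calls = [SVCall("a", "c1", "DEL", 100, 200), SVCall("a", "c1", "DEL", 150, 250)]
        t = build_class_signal(calls, 1000)
        assert t.values.max() == 1
        assert t.values[100:250].tolist() == [1] * 150

    def test_weighted_insertion_specialist(self):
        t = build_class_signal(
            [SVCall("insurveyor", "c1", "INS", 499, 500)], 1000, {"insurveyor": {"INS": 2}}
        )
        assert t.values[499] == 2
        assert t.values.sum() == 2

    def test_signal_conservation_identity(self):
        # sum(signal) == sum over callers of weight * |union of its intervals|
        rng = np.random.default_rng(11)
        for _ in range(30):
            n_callers = int(rng.integers(1, 5))
            calls, expected = [], 0
            weights = {"caller0": 2}
            for i in range(n_callers):
                caller = f"caller{i}"
                ivs = []
                for _ in range(int(rng.integers(1, 8))):
                    s = int(rng.integers(0, 900))
                    e = int(rng.integers(s + 1, min(s + 200, 1000) + 1))
                    ivs.append((s, e))
                calls += [SVCall(caller, "c1", "DUP", s, e) for s, e in ivs]
                expected += resolve_weight(weights, caller, "DUP") * union_length(ivs)
            t = build_class_signal(calls, 1000, weights)
            assert int(t.values.sum()) == expected

    def test_mixed_classes_rejected(self):
        with pytest.raises(ConsensvError):
            build_class_signal(
                [SVCall("a", "c1", "DEL", 0, 10), SVCall("a", "c1", "DUP", 0, 10)], 100
            )


class TestThresholdSegments:
    def test_by_inspection(self):
        assert threshold_segments(track([0, 0, 2, 2, 1, 3, 3, 0]), 2) == [(2, 4), (5, 7)]

    def test_all_zero(self):
        assert threshold_segments(track([0] * 10), 1) == []

    def test_threshold_one_equals_interval_union(self):
        intervaltree = pytest.importorskip("intervaltree")
        rng = np.random.default_rng(3)
        for _ in range(200):
            calls = []
            tree = intervaltree.IntervalTree()
            for i in range(int(rng.integers(1, 15))):
                s = int(rng.integers(0, 450))
                e = int(rng.integers(s + 1, min(s + 80, 500) + 1))
                calls.append(SVCall(f"c{i % 4}", "c1", "INV", s, e))
                tree[s:e] = True
            tree.merge_overlaps(strict=False)
            expected = sorted((iv.begin, iv.end) for iv in tree)
            t = build_class_signal(calls, 500)
            assert threshold_segments(t, 1) == expected


class TestGapMerge:
    def test_examples(self):
        assert gap_merge([(2, 4), (5, 7)], 1) == [(2, 7)]
        assert gap_merge([(2, 4), (5, 7)], 0) == [(2, 4), (5, 7)]
        assert gap_merge([], 10) == []

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 500), st.integers(1, 40)), max_size=15),
        st.integers(0, 50),
    )
    def test_fixpoint_oracle(self, raw, max_gap):
        # disjoint sorted segments from raw (start, width) pairs
        segments = []
        for s, w in sorted(raw):
            if not segments or s > segments[-1][1]:
                segments.append((s, s + w))
        result = gap_merge(segments, max_gap)
        # brute force: repeatedly fuse any qualifying pair until fixpoint
        expected = [list(seg) for seg in segments]
        changed = True
        while changed:
            changed = False
            for i in range(len(expected) - 1):
                if expected[i + 1][0] - expected[i][1] <= max_gap:
                    expected[i][1] = max(expected[i][1], expected[i + 1][1])
                    del expected[i + 1]
                    changed = True
                    break
        assert result == [tuple(seg) for seg in expected]
        assert all(b[0] - a[1] > max_gap for a, b in zip(result, result[1:]))


class TestComputeMaxsup:
    def test_unique_peak(self):
        assert compute_maxsup(track([1, 2, 3, 3, 2, 1]), (0, 6)) == (2, 4, 3)

    def test_uniform_signal_spans_whole(self):
        assert compute_maxsup(track([2] * 6), (0, 6)) == (0, 6, 2)

    def test_longest_run_wins_then_leftmost(self):
        # two peak runs: lengths 3 and 5 -> the length-5 run
        values = [3, 3, 3, 1, 3, 3, 3, 3, 3, 1]
        assert compute_maxsup(track(values), (0, 10)) == (4, 9, 3)
        # equal lengths -> leftmost
        values = [3, 3, 1, 3, 3]
        assert compute_maxsup(track(values), (0, 5)) == (0, 2, 3)

    def test_selection_rule_matches_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            values = rng.integers(0, 4, size=60)
            if values.max() == 0:
                continue
            t = track(values)
            ms, me, support = compute_maxsup(t, (0, 60))
            assert support == values.max()
            runs = []
            i = 0
            while i < 60:
                if values[i] == support:
                    j = i
                    while j < 60 and values[j] == support:
                        j += 1
                    runs.append((i, j))
                    i = j
                else:
                    i += 1
            best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
            assert (ms, me) == best

    def test_zero_span_is_contract_violation(self):
        with pytest.raises(ConsensvError):
            compute_maxsup(track([0, 0, 0]), (0, 3))


class TestBacktrack:
    def test_full_single_call(self):
        callers, sub, cov = backtrack((0, 100), [SVCall("A", "c1", "DEL", 0, 100)])
        assert callers == {"A"} and sub == {"A": 1} and cov == {"A": 1.0}

    def test_fragmented_caller_covers_ninety_percent(self):
        calls = [SVCall("B", "c1", "DEL", 0, 40), SVCall("B", "c1", "DEL", 50, 100)]
        _, sub, cov = backtrack((0, 100), calls)
        assert sub == {"B": 2}
        assert cov["B"] == pytest.approx(0.9)

    def test_clipping(self):
        _, _, cov = backtrack((0, 100), [SVCall("C", "c1", "DEL", 90, 150)])
        assert cov["C"] == pytest.approx(0.1)

    def test_non_overlapping_caller_absent(self):
        callers, sub, cov = backtrack((0, 100), [SVCall("D", "c1", "DEL", 200, 300)])
        assert callers == frozenset() and sub == {} and cov == {}


class TestMergeAll:
    def test_empty_input(self, small_genome):
        assert merge_all([], small_genome) == []

    def test_single_caller_idempotence(self, small_genome):
        calls = [
            SVCall("a", "chr1", "DEL", 100, 200),
            SVCall("a", "chr1", "DEL", 150, 300),
            SVCall("a", "chr1", "DEL", 500, 600),
            SVCall("a", "chr1", "INS", 900, 901),
        ]
        params = MergeParams(min_callers_cnv=1, min_callers_inv=1, min_callers_ins=1,
                             max_gap=0, weights={})
        merged = merge_all(calls, small_genome, params)
        spans = [(e.sv_class, e.start, e.end) for e in merged]
        assert spans == [("DEL", 100, 300), ("DEL", 500, 600), ("INS", 900, 901)]

    def test_long_event_with_fragmented_caller_both_gap_regimes(self, small_genome):
        # one long event by two callers plus fragmented short calls by a third
        calls = [
            SVCall("a", "chr1", "DEL", 1000, 2000),
            SVCall("b", "chr1", "DEL", 1000, 2000),
            SVCall("c", "chr1", "DEL", 1100, 1300),
            SVCall("c", "chr1", "DEL", 1500, 1700),
        ]
        # threshold 3: only where the fragmented caller stacks on the others
        params = MergeParams(min_callers_cnv=3, max_gap=0, weights={})
        merged = merge_all(calls, small_genome, params)
        assert [(e.start, e.end, e.support) for e in merged] == [
            (1100, 1300, 3), (1500, 1700, 3)]
        # large max_gap fuses the two high-support peaks into one event
        params = MergeParams(min_callers_cnv=3, max_gap=300, weights={})
        merged = merge_all(calls, small_genome, params)
        assert [(e.start, e.end, e.support) for e in merged] == [(1100, 1700, 3)]
        # threshold 2: a single long support-2 event with a support-3 peak
        params = MergeParams(min_callers_cnv=2, max_gap=0, weights={})
        merged = merge_all(calls, small_genome, params)
        assert len(merged) == 1
        e = merged[0]
        assert (e.start, e.end) == (1000, 2000)
        assert e.support == 3
        assert e.subevents == {"a": 1, "b": 1, "c": 2}
        assert e.coverage["c"] == pytest.approx(0.4)

    def test_classes_never_mix(self, small_genome):
        calls = [SVCall("a", "chr1", "DEL", 100, 200), SVCall("b", "chr1", "DUP", 100, 200)]
        params = MergeParams(min_callers_cnv=1, max_gap=100, weights={})
        merged = merge_all(calls, small_genome, params)
        assert {e.sv_class for e in merged} == {"DEL", "DUP"}
        assert all(e.n_callers == 1 for e in merged)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            calls, genome, params = random_merge_instance(rng)
            merged = merge_all(calls, genome, params)
            perm = list(calls)
            rng.shuffle(perm)
            assert merge_all(perm, genome, params) == merged

    def test_weight1_support_equals_distinct_caller_count(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            calls, genome, _ = random_merge_instance(rng)
            params = MergeParams(min_callers_cnv=1, min_callers_inv=1,
                                 min_callers_ins=1, max_gap=10, weights={})
            for e in merge_all(calls, genome, params):
                pos = e.maxsup_start  # any maxsup position carries peak support
                n = len({
                    c.caller for c in calls
                    if c.contig == e.contig and c.sv_class == e.sv_class
                    and c.start <= pos < c.end
                })
                assert e.support == n

    def test_event_invariants(self):
        rng = np.random.default_rng(29)
        for _ in range(25):
            calls, genome, params = random_merge_instance(rng)
            for e in merge_all(calls, genome, params):
                assert e.start <= e.maxsup_start < e.maxsup_end <= e.end
                assert e.support >= params.threshold_for(e.sv_class)
                assert set(e.subevents) == set(e.callers) == set(e.coverage)
                assert all(v >= 1 for v in e.subevents.values())
                assert all(0 < v <= 1 for v in e.coverage.values())


class TestSweep:
    def _concordant(self, small_genome):
        return [SVCall(c, "chr1", "DEL", 1000, 2000) for c in "abc"]

    def test_counts_non_increasing(self, small_genome):
        calls = self._concordant(small_genome)
        rows = sweep_min_callers(calls, small_genome, MergeParams(weights={}), "DEL", [1, 2, 3])
        counts = [n for _, n, _ in rows]
        assert counts == sorted(counts, reverse=True)

    def test_unanimous_threshold(self, small_genome):
        calls = self._concordant(small_genome) + [SVCall("a", "chr1", "DEL", 5000, 6000)]
        rows = sweep_min_callers(calls, small_genome, MergeParams(weights={}), "DEL", [3])
        _, _, events = rows[0]
        assert [(e.start, e.end) for e in events] == [(1000, 2000)]

    def test_threshold_above_weighted_support_errors(self, small_genome):
        with pytest.raises(ConsensvError, match="exceeds"):
            sweep_min_callers(self._concordant(small_genome), small_genome,
                              MergeParams(weights={}), "DEL", [4])

    def test_nesting_across_thresholds(self):
        rng = np.random.default_rng(31)
        checked = 0
        for _ in range(100):
            calls, genome, _ = random_merge_instance(rng)
            if not calls:
                continue
            params = MergeParams(max_gap=int(rng.choice([0, 10, 50])), weights={})
            n = len({c.caller for c in calls})
            if n < 2:
                continue
            rows = sweep_min_callers(calls, genome, params, "DEL", [1, 2])
            spans_k1 = [(e.start, e.end) for _, _, ev in rows[:1] for e in ev]
            for _, _, ev in rows[1:]:
                for e in ev:
                    assert any(s <= e.start and e.end <= t for s, t in spans_k1)
            checked += 1
        assert checked >= 30
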