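"""Tolerant-version stack: merge-on-pop, heap maintenance, full traversal."""

import numpy as np
import pytest

from helpers import (
    brute_tolerant_max,
    check_tolerant_record,
    index_reads,
    random_reads,
)
from sufpref.exact_overlap import find_overlaps_exact
from sufpref.tolerant_overlap import (
    AnswerState,
    HeapNode,
    TolerantStackElement,
    TopKHeap,
    find_overlaps_multi_k,
    find_overlaps_tolerant,
    harvest_tolerant,
    heap_offer,
    merge_on_pop,
    push_tolerant,
)


def _suffix_len_of(mapping):
    return lambda rank: mapping[rank]


class TestMergeOnPop:
    def test_best_by_smallest_tail_cut(self):
        # firsts [2,5,8], representative suffix lengths a=2, b=6, c=8;
        # LCP 4 pops b and c; cuts 2 vs 4 -> b wins, re-pushed at first=4
        stack = [
            TolerantStackElement(2, "a"),
            TolerantStackElement(5, "b"),
            TolerantStackElement(8, "c"),
        ]
        merge_on_pop(stack, 4, _suffix_len_of({"a": 2, "b": 6, "c": 8}))
        assert [(e.first, e.second) for e in stack] == [(2, "a"), (4, "b")]

    def test_lcp_zero_empties_stack(self):
        stack = [TolerantStackElement(3, "x")]
        merge_on_pop(stack, 0, _suffix_len_of({"x": 3}))
        assert stack == []

    def test_top_not_above_lcp_is_noop(self):
        stack = [TolerantStackElement(3, "x")]
        merge_on_pop(stack, 5, _suffix_len_of({"x": 3}))
        assert [(e.first, e.second) for e in stack] == [(3, "x")]

    def test_budget_excludes_over_cut_representatives(self):
        # with K=1 both cuts (2 and 4) bust the budget: nothing re-pushed
        stack = [
            TolerantStackElement(5, "b"),
            TolerantStackElement(8, "c"),
        ]
        merge_on_pop(stack, 4, _suffix_len_of({"b": 6, "c": 8}), K=1)
        assert stack == []

    def test_tie_keeps_most_recent(self):
        # equal cuts: the larger SA rank (more recent suffix) wins,
        # matching the replace-on-equal push rule
        stack = [TolerantStackElement(5, 10), TolerantStackElement(7, 30)]
        merge_on_pop(stack, 3, _suffix_len_of({10: 6, 30: 6}))
        assert [(e.first, e.second) for e in stack] == [(3, 30)]


class TestPushTolerant:
    owner = staticmethod(lambda rank: rank // 100)

    def test_push_replace_drop(self):
        stack = [TolerantStackElement(3, 100)]
        push_tolerant(stack, 5, 200, self.owner)
        assert [(e.first, e.second) for e in stack] == [(3, 100), (5, 200)]
        push_tolerant(stack, 5, 300, self.owner)
        assert [(e.first, e.second) for e in stack] == [(3, 100), (5, 300)]
        push_tolerant(stack, 2, 400, self.owner)
        assert len(stack) == 2

    def test_replace_records_shadow_of_other_owner(self):
        stack = [TolerantStackElement(4, 100)]
        push_tolerant(stack, 4, 200, self.owner)  # different owner displaced
        assert stack[0].second == 200 and stack[0].shadow == 100
        push_tolerant(stack, 4, 250, self.owner)  # same owner: shadow kept
        assert stack[0].second == 250 and stack[0].shadow == 100


class TestHeapOffer:
    def test_fills_below_capacity(self):
        h = TopKHeap(2)
        heap_offer(h, HeapNode(1, 5, 0))
        assert [n.matched_len for n in h.nodes] == [5]

    def test_replaces_worst_and_sifts(self):
        h = TopKHeap(2)
        for ln in (3, 8):
            heap_offer(h, HeapNode(0, ln, 0))
        heap_offer(h, HeapNode(0, 6, 0))
        assert sorted(n.matched_len for n in h.nodes) == [6, 8]
        assert h.top.matched_len == 6  # top is the worst kept answer

    def test_worse_than_worst_ignored(self):
        h = TopKHeap(2)
        for ln in (3, 8):
            heap_offer(h, HeapNode(0, ln, 0))
        heap_offer(h, HeapNode(0, 2, 0))
        assert sorted(n.matched_len for n in h.nodes) == [3, 8]

    def test_matches_sort_truncate_on_random_streams(self, rng):
        for _ in range(300):
            k = int(rng.integers(1, 6))
            stream = [int(x) for x in rng.integers(0, 50, size=rng.integers(1, 30))]
            h = TopKHeap(k)
            for j, ln in enumerate(stream):
                heap_offer(h, HeapNode(j, ln, 0))
            kept = sorted(n.matched_len for n in h.nodes)
            assert kept == sorted(stream, reverse=True)[:k][::-1]
            # heap order invariant
            for c in range(1, len(h.nodes)):
                assert h.nodes[(c - 1) // 2].matched_len <= h.nodes[c].matched_len


class TestHarvestTolerant:
    def _setup(self, reads, K=2):
        rs, si, b = index_reads(reads)
        return si, b, AnswerState(n=rs.n, K_cut=K, k_top=10)

    def test_first_candidate_always_wins(self):
        si, b, state = self._setup(["AAGT", "GTCC"])
        # rank of r2's full read; put a fake element for r1's "GT" suffix
        i = int(np.where(si.sa == b.fi[2])[0][0])
        gt_rank = int(np.where(si.sa == b.se[1] - 1)[0][0])
        stack = [TolerantStackElement(2, gt_rank)]
        harvest_tolerant(stack, state, i, b, si)
        assert state.len_best[2] == 2 and state.ans[2] == gt_rank

    def test_worse_candidate_no_update(self):
        si, b, state = self._setup(["AAGT", "GTCC"])
        state.len_best[2] = 9
        i = int(np.where(si.sa == b.fi[2])[0][0])
        gt_rank = int(np.where(si.sa == b.se[1] - 1)[0][0])
        harvest_tolerant([TolerantStackElement(2, gt_rank)], state, i, b, si)
        assert state.ans[2] == -1  # ANS untouched (but heap was offered)

    def test_self_top_falls_back_to_shadow(self):
        si, b, state = self._setup(["AAGT", "GTCC"])
        i = int(np.where(si.sa == b.fi[2])[0][0])
        own = int(np.where(si.sa == b.fi[2] + 2)[0][0])  # r2's own "CC" suffix
        other = int(np.where(si.sa == b.se[1] - 1)[0][0])  # r1's "GT"
        elem = TolerantStackElement(2, own, shadow=other)
        harvest_tolerant([elem], state, i, b, si)
        assert state.ans[2] == other


class TestFindOverlapsTolerant:
    def test_toy_end_error_trace(self):
        # the matching source suffix "CGTTG" ranks after every harvestable
        # target suffix, so the single pass reports the shorter h=1 match;
        # the brute-force cut oracle (4 here) is only an upper bound
        _, si, b = index_reads(["AAACGTTG", "CGTTCCAA"])
        recs = find_overlaps_tolerant(si, b, K=1)
        by_target = {r.target: r for r in recs if r.rank == 1}
        assert (by_target[2].source, by_target[2].overlap_len, by_target[2].head_cut) == (1, 1, 1)
        assert brute_tolerant_max("AAACGTTG", "CGTTCCAA", 1) == 4

    def test_single_read_no_records(self):
        _, si, b = index_reads(["ACGTACGT"])
        assert find_overlaps_tolerant(si, b, K=3) == []

    def test_k0_reduction_to_exact_rank1(self, rng):
        for _ in range(60):
            reads = random_reads(rng, 2, 15, 3, 30)
            _, si, b = index_reads(reads)
            exact1 = {
                r.target: (r.source, r.overlap_len)
                for r in find_overlaps_exact(si, b)
                if r.rank == 1
            }
            tol1 = {
                r.target: (r.source, r.overlap_len)
                for r in find_overlaps_tolerant(si, b, K=0)
                if r.rank == 1
            }
            assert exact1 == tol1

    def test_soundness_and_greedy_bound(self, rng):
        for _ in range(25):
            reads = random_reads(rng, 2, 10, 5, 25)
            K = int(rng.integers(0, 4))
            _, si, b = index_reads(reads)
            for rec in find_overlaps_tolerant(si, b, K=K):
                assert check_tolerant_record(rec, reads)
                assert rec.head_cut <= K and rec.tail_cut <= K
                assert rec.overlap_len <= brute_tolerant_max(
                    reads[rec.source - 1], reads[rec.target - 1], K
                )

    def test_engines_agree(self, rng):
        for _ in range(25):
            reads = random_reads(rng, 2, 12, 3, 25)
            K = int(rng.integers(0, 4))
            _, si, b = index_reads(reads)
            assert find_overlaps_tolerant(
                si, b, K=K, engine="numba"
            ) == find_overlaps_tolerant(si, b, K=K, engine="python")

    def test_records_in_input_read_order(self, rng):
        reads = random_reads(rng, 5, 10, 5, 20)
        _, si, b = index_reads(reads)
        recs = find_overlaps_tolerant(si, b, K=2)
        targets = [r.target for r in recs]
        assert targets == sorted(targets)

    def test_per_source_deduplication(self, rng):
        # top-k may harvest the same source repeatedly; emitted records
        # keep one per (target, source), the longest
        for _ in range(10):
            reads = random_reads(rng, 3, 8, 8, 25)
            _, si, b = index_reads(reads)
            recs = find_overlaps_tolerant(si, b, K=2, k_top=10)
            seen = set()
            for r in recs:
                assert (r.target, r.source) not in seen
                seen.add((r.target, r.source))

    def test_multi_k_keeps_per_pair_max(self, rng):
        reads = random_reads(rng, 4, 8, 8, 25)
        _, si, b = index_reads(reads)
        merged = find_overlaps_multi_k(si, b, Ks=[0, 1, 2])
        singles = {}
        for K in (0, 1, 2):
            for r in find_overlaps_tolerant(si, b, K=K):
                key = (r.target, r.source)
                singles[key] = max(singles.get(key, 0), r.overlap_len)
        assert {(r.target, r.source): r.overlap_len for r in merged} == singles

    def test_invalid_parameters_rejected(self):
        _, si, b = index_reads(["ACGT", "CGTA"])
        with pytest.raises(ValueError):
            find_overlaps_tolerant(si, b, K=-1)
        with pytest.raises(ValueError):
            find_overlaps_tolerant(si, b, K=0, k_top=0)
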