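"""End-tolerant suffix–prefix overlaps with cut budget K.

Long reads whose sequencing errors cluster at the two ends can still be
overlapped exactly in their clean interiors: up to K bases may be trimmed
from the source read's tail and up to K from the target read's head, and
the remaining flanks must match exactly.

The traversal reuses the monotonic-stack idea of the exact version with
two changes:

* **merge-on-pop** — when LCP(i) drops below the top, every element with
  ``first >= LCP(i)`` is popped and the best of them is pushed back with
  ``first = LCP(i)``.  "Best" means the smallest implied tail cut
  ``full_suffix_length - LCP(i)``; representatives whose cut would exceed
  the budget K are not eligible (a longer cut can never shrink later, so
  they are dead).  Ties prefer the most recent suffix, consistent with the
  replace-on-equal push rule.
* **harvest everywhere near a read head** — a suffix whose offset h within
  its read satisfies ``h <= K`` corresponds to the read's prefix with h
  bases cut; the stack top at that moment is its best previous match.  The
  per-read best is kept in the ANS/LEN arrays and every candidate is also
  offered to the read's min-heap of the k best answers (heap top = worst
  kept answer).

Each stack element stores one representative SA rank plus a *shadow*: the
previously displaced representative with a different owner.  The shadow
lets a harvest skip the target's own suffix without losing an equal-length
candidate from another read, which keeps the K=0 run equivalent to the
exact version.

As in the exact module, the granular operations are pure Python and a
fused numba kernel backs :func:`find_overlaps_tolerant`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import _kernels
from .exact_overlap import DEFAULT_TOP_K
from .seqio import OverlapRecord
from .suffix_index import Boundaries, SuffixIndex


@dataclass
class TolerantStackElement:
    first: int  # matched length shared with every later suffix so far
    second: int  # SA rank of the representative suffix
    shadow: int = -1  # displaced equal-length representative (other owner)


@dataclass
class HeapNode:
    sa_rank: int
    matched_len: int
    head_cut: int


class TopKHeap:
    """Min-heap on matched length; the top is the worst kept answer."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("heap capacity must be >= 1")
        self.capacity = capacity
        self.nodes: List[HeapNode] = []

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def top(self) -> Optional[HeapNode]:
        return self.nodes[0] if self.nodes else None


def heap_offer(heap: TopKHeap, cand: HeapNode) -> TopKHeap:
    """Insert-and-sift-up while below capacity; otherwise replace the top
    and sift down when the candidate beats the worst kept answer."""
    nodes = heap.nodes
    if len(nodes) < heap.capacity:
        nodes.append(cand)
        c = len(nodes) - 1
        while c > 0:
            p = (c - 1) // 2
            if nodes[p].matched_len > nodes[c].matched_len:
                nodes[p], nodes[c] = nodes[c], nodes[p]
                c = p
            else:
                break
    elif cand.matched_len > nodes[0].matched_len:
        nodes[0] = cand
        c = 0
        size = len(nodes)
        while True:
            l, r = 2 * c + 1, 2 * c + 2
            small = c
            if l < size and nodes[l].matched_len < nodes[small].matched_len:
                small = l
            if r < size and nodes[r].matched_len < nodes[small].matched_len:
                small = r
            if small == c:
                break
            nodes[c], nodes[small] = nodes[small], nodes[c]
            c = small
    return heap


@dataclass
class AnswerState:
    """Per-read best answer (ANS/LEN) plus the top-k min-heaps."""

    n: int
    K_cut: int
    k_top: int = DEFAULT_TOP_K
    ans: List[int] = field(default_factory=list)  # SA rank of best, -1 unset
    len_best: List[int] = field(default_factory=list)
    head_cut: List[int] = field(default_factory=list)
    heaps: List[TopKHeap] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.ans:
            self.ans = [-1] * (self.n + 1)
            self.len_best = [0] * (self.n + 1)
            self.head_cut = [-1] * (self.n + 1)
            self.heaps = [TopKHeap(self.k_top) for _ in range(self.n + 1)]


def merge_on_pop(
    stack: List[TolerantStackElement],
    lcp_i: int,
    suffix_len_of,
    K: Optional[int] = None,
) -> List[TolerantStackElement]:
    """Pop all elements with ``first >= lcp_i`` (when the top exceeds it)
    and push back the best survivor truncated to ``first = lcp_i``.

    ``suffix_len_of`` maps an SA rank to the full base length of its
    suffix.  The best popped element minimizes the tail cut
    ``suffix_len_of(rank) - lcp_i``; with a finite budget ``K`` only cuts
    of at most K are eligible.  Ties keep the most recent representative.
    Nothing is pushed back when ``lcp_i == 0`` or nothing is eligible.
    """
    if not stack or stack[-1].first <= lcp_i:
        return stack
    best: Optional[TolerantStackElement] = None
    best_cut = None
    while stack and stack[-1].first >= lcp_i:
        elem = stack.pop()
        cut = suffix_len_of(elem.second) - lcp_i
        if K is not None and cut > K:
            continue
        if (
            best_cut is None
            or cut < best_cut
            or (cut == best_cut and elem.second > best.second)
        ):
            best, best_cut = elem, cut
    if lcp_i > 0 and best is not None:
        stack.append(TolerantStackElement(lcp_i, best.second, best.shadow))
    return stack


def push_tolerant(
    stack: List[TolerantStackElement], suf_len: int, sa_rank: int, owner_of
) -> List[TolerantStackElement]:
    """Push the current suffix: append when strictly longer than the top,
    replace the top when equal (remembering a displaced representative of
    a different owner as the shadow), drop when shorter."""
    if not stack or suf_len > stack[-1].first:
        stack.append(TolerantStackElement(suf_len, sa_rank))
    elif suf_len == stack[-1].first:
        top = stack[-1]
        if owner_of(top.second) != owner_of(sa_rank):
            top.shadow = top.second
        top.second = sa_rank
    return stack


def harvest_tolerant(
    stack: List[TolerantStackElement],
    state: AnswerState,
    i: int,
    b: Boundaries,
    si: SuffixIndex,
) -> AnswerState:
    """Offer the best stack candidate to read DA(i), whose suffix at rank
    ``i`` starts ``h = SA(i) - Fi(DA(i)) <= K`` bases into the read.

    Walks down from the top skipping the read's own representatives
    (falling back to an element's shadow when its cut fits the budget);
    the first usable candidate updates ANS/LEN if longer and is offered to
    the read's heap with ``head_cut = h``.
    """
    r = int(si.da[i])
    h = int(si.sa[i]) - int(b.fi[r])
    if not (0 <= h <= state.K_cut):
        raise ValueError("harvest called outside the head-cut budget")
    cand_rank, cand_len = -1, 0
    for elem in reversed(stack):
        rep = elem.second
        if int(si.da[rep]) != r:
            cand_rank, cand_len = rep, elem.first
            break
        sh = elem.shadow
        if sh >= 0 and int(si.da[sh]) != r:
            sh_cut = _suffix_len(si, b, sh) - elem.first
            if sh_cut <= state.K_cut:
                cand_rank, cand_len = sh, elem.first
                break
    if cand_rank >= 0:
        if cand_len > state.len_best[r]:
            state.len_best[r] = cand_len
            state.ans[r] = cand_rank
            state.head_cut[r] = h
        heap_offer(state.heaps[r], HeapNode(cand_rank, cand_len, h))
    return state


def _suffix_len(si: SuffixIndex, b: Boundaries, rank: int) -> int:
    return int(b.se[int(si.da[rank])]) - int(si.sa[rank]) + 1


def _emit_records(
    per_read: Sequence[List[Tuple[int, int, int]]],
    si: SuffixIndex,
    b: Boundaries,
    K: int,
    min_overlap: int,
) -> List[OverlapRecord]:
    """Turn per-read candidate lists of (sa_rank, matched_len, head_cut)
    into deduplicated, ranked records in input-read order."""
    records: List[OverlapRecord] = []
    for r in range(1, b.n + 1):
        best: Dict[int, Tuple[int, int, int, int]] = {}
        for rank, ln, h in per_read[r]:
            src = int(si.da[rank])
            tail = _suffix_len(si, b, rank) - ln
            if src == r or ln < min_overlap or tail > K:
                continue
            key = (-ln, tail, h, rank)
            if src not in best or key < (
                -best[src][0],
                best[src][1],
                best[src][2],
                best[src][3],
            ):
                best[src] = (ln, tail, h, rank)
        ordered = sorted(
            best.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[1][2], kv[0])
        )
        for rk, (src, (ln, tail, h, rank)) in enumerate(ordered, start=1):
            records.append(
                OverlapRecord(
                    target=r,
                    source=src,
                    overlap_len=ln,
                    head_cut=h,
                    tail_cut=tail,
                    containment=ln + tail == int(b.length[src]),
                    rank=rk,
                )
            )
    return records


def find_overlaps_tolerant(
    si: SuffixIndex,
    b: Boundaries,
    K: int,
    k_top: int = DEFAULT_TOP_K,
    min_overlap: int = 1,
    engine: str = "numba",
) -> List[OverlapRecord]:
    """All-pairs overlaps allowing up to K bases cut from the source tail
    and the target head.

    Output is deferred until the pass completes and emitted in input-read
    order; per target, heap candidates are deduplicated per source (the
    longest match wins) and ranked by descending matched length.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if k_top < 1:
        raise ValueError("k_top must be >= 1")
    n = si.n
    per_read: List[List[Tuple[int, int, int]]] = [[] for _ in range(n + 1)]
    if engine == "numba":
        _, _, _, hp_rank, hp_len, hp_h, hp_size = _kernels.tolerant_traversal(
            si.sa, si.lcp, si.da, b.fi, b.se, n, K, k_top
        )
        for r in range(1, n + 1):
            for j in range(int(hp_size[r])):
                per_read[r].append(
                    (int(hp_rank[r, j]), int(hp_len[r, j]), int(hp_h[r, j]))
                )
    elif engine == "python":
        state = AnswerState(n=n, K_cut=K, k_top=k_top)
        stack: List[TolerantStackElement] = []
        suffix_len_of = lambda rank: _suffix_len(si, b, rank)
        owner_of = lambda rank: int(si.da[rank])
        for i in range(n + 1, si.L):
            merge_on_pop(stack, int(si.lcp[i]), suffix_len_of, K)
            r = int(si.da[i])
            h = int(si.sa[i]) - int(b.fi[r])
            if h <= K:
                harvest_tolerant(stack, state, i, b, si)
            push_tolerant(stack, _suffix_len(si, b, i), i, owner_of)
        for r in range(1, n + 1):
            per_read[r] = [
                (nd.sa_rank, nd.matched_len, nd.head_cut)
                for nd in state.heaps[r].nodes
            ]
    else:
        raise ValueError(f"unknown engine {engine!r}")
    return _emit_records(per_read, si, b, K, min_overlap)


def find_overlaps_multi_k(
    si: SuffixIndex,
    b: Boundaries,
    Ks: Sequence[int],
    k_top: int = DEFAULT_TOP_K,
    min_overlap: int = 1,
    engine: str = "numba",
) -> List[OverlapRecord]:
    """Convenience sweep over several cut budgets.

    Runs the tolerant pass once per K and merges results per (target,
    source) pair keeping the longest match (ties: the smaller K's record).
    Ranks are reassigned per target by descending overlap length.
    """
    best: Dict[Tuple[int, int], OverlapRecord] = {}
    for K in Ks:
        for rec in find_overlaps_tolerant(
            si, b, K, k_top=k_top, min_overlap=min_overlap, engine=engine
        ):
            key = (rec.target, rec.source)
            if key not in best or rec.overlap_len > best[key].overlap_len:
                best[key] = rec
    records: List[OverlapRecord] = []
    for r in range(1, b.n + 1):
        group = sorted(
            (rec for (t, _), rec in best.items() if t == r),
            key=lambda rec: (-rec.overlap_len, rec.tail_cut, rec.head_cut, rec.source),
        )
        for rk, rec in enumerate(group, start=1):
            rec.rank = rk
            records.append(rec)
    return records
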