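"""Exact suffix–prefix overlaps (the no-mismatch version).

One left-to-right pass over the suffix-array ranks maintains a monotonic
stack keyed by suffix length.  The keystone property is that the longest
common prefix of the suffixes ranked X < Y equals ``min(LCP[X+1..Y])``:
an element pushed with ``first`` equal to its full suffix length survives
to rank i exactly when every intervening LCP is at least ``first``, i.e.
when that whole suffix is a prefix of the rank-i suffix.  When rank i is a
*complete read*, every surviving element therefore records sources whose
entire suffix matches the read's prefix — a true suffix–prefix overlap.

Each stack element carries a fixed-capacity rolling queue of owner reads
(newest kept on eviction), so equal-length candidate suffixes from several
sources share one element.

The module exposes the individual stack operations in pure Python (these
are the testable unit contracts and the reference implementation) and a
fused numba kernel used by :func:`find_overlaps_exact` for real inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

from . import _kernels
from .seqio import OverlapRecord
from .suffix_index import Boundaries, SuffixIndex

DEFAULT_TOP_K = 10  # the first ten possible results are provided by default


class RollingQueue:
    """Fixed-capacity circular buffer of read indices; insertion when full
    evicts the oldest entry."""

    __slots__ = ("data", "head", "have", "size")

    def __init__(self, size: int, first_item: int | None = None):
        if size < 1:
            raise ValueError("queue capacity must be >= 1")
        self.size = size
        self.data = [0] * size
        self.head = 0
        self.have = 0
        if first_item is not None:
            self.push(first_item)

    def push(self, item: int) -> None:
        self.data[(self.head + self.have) % self.size] = item
        if self.have == self.size:
            self.head = (self.head + 1) % self.size
        else:
            self.have += 1

    def items_newest_first(self) -> List[int]:
        return [
            self.data[(self.head + self.have - 1 - t) % self.size]
            for t in range(self.have)
        ]

    def __len__(self) -> int:
        return self.have


@dataclass
class ExactStackElement:
    first: int  # suffix length shared by all queue members
    second: RollingQueue


def pop_expired(stack: List[ExactStackElement], lcp_i: int) -> List[ExactStackElement]:
    """Remove elements whose ``first`` exceeds ``lcp_i`` (they can no
    longer fully match any later suffix).  Mutates and returns the stack."""
    while stack and stack[-1].first > lcp_i:
        stack.pop()
    return stack


def push_or_merge(
    stack: List[ExactStackElement], suf_len: int, owner: int, k: int
) -> List[ExactStackElement]:
    """Add the current suffix: join the top element's queue when lengths
    are equal, otherwise push a fresh element.  ``pop_expired`` must
    already have run for the current LCP, so ``top.first <= suf_len``."""
    if stack and stack[-1].first > suf_len:
        raise RuntimeError("monotonicity violated: pop_expired not applied")
    if stack and stack[-1].first == suf_len:
        stack[-1].second.push(owner)
    else:
        stack.append(ExactStackElement(suf_len, RollingQueue(k, owner)))
    return stack


def harvest(
    stack: List[ExactStackElement],
    target: int,
    k: int,
    min_overlap: int = 1,
    top_only: bool = False,
) -> List[Tuple[int, int]]:
    """Collect up to ``k`` (source, overlap_len) candidates for ``target``.

    Walks from the top of the stack downward, emitting queue members
    newest-first and skipping the target's own suffixes; deeper elements
    are shorter (still valid) candidates.  ``top_only`` restricts the walk
    to the top element.
    """
    out: List[Tuple[int, int]] = []
    for elem in reversed(stack):
        if elem.first < min_overlap:
            break
        for src in elem.second.items_newest_first():
            if src != target:
                out.append((src, elem.first))
                if len(out) >= k:
                    return out
        if top_only:
            break
    return out


def _records_from_arrays(out_t, out_s, out_len, out_rank, b: Boundaries):
    recs = []
    for t, s, ln, rk in zip(out_t, out_s, out_len, out_rank):
        recs.append(
            OverlapRecord(
                target=int(t),
                source=int(s),
                overlap_len=int(ln),
                head_cut=0,
                tail_cut=0,
                containment=int(ln) == int(b.length[int(s)]),
                rank=int(rk),
            )
        )
    return recs


def find_overlaps_exact(
    si: SuffixIndex,
    b: Boundaries,
    k: int = DEFAULT_TOP_K,
    min_overlap: int = 1,
    queue_size: int | None = None,
    top_only: bool = False,
    engine: str = "numba",
) -> List[OverlapRecord]:
    """All-pairs exact suffix–prefix overlaps.

    Single pass over SA ranks n+1 .. L-1: pop expired elements with the
    current LCP; if the suffix is a complete read, harvest up to ``k``
    candidates for it; then push/merge the suffix.  Records shorter than
    ``min_overlap`` are dropped; results are streamed in the order targets
    are encountered during the traversal.

    ``queue_size`` (default ``k``) caps how many equal-length sources one
    stack element remembers; set it to at least n to disable eviction.
    ``engine`` is ``"numba"`` or ``"python"`` (reference implementation).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    queue_size = k if queue_size is None else queue_size
    if engine == "numba":
        m, out_t, out_s, out_len, out_rank = _kernels.exact_traversal(
            si.sa,
            si.lcp,
            si.da,
            b.fi,
            b.se,
            si.n,
            queue_size,
            k,
            min_overlap,
            top_only,
        )
        return _records_from_arrays(out_t, out_s, out_len, out_rank, b)
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    stack: List[ExactStackElement] = []
    records: List[OverlapRecord] = []
    n, L = si.n, si.L
    for i in range(n + 1, L):
        pop_expired(stack, int(si.lcp[i]))
        owner = int(si.da[i])
        pos = int(si.sa[i])
        if pos == int(b.fi[owner]):
            for rk, (src, ln) in enumerate(
                harvest(stack, owner, k, min_overlap, top_only), start=1
            ):
                records.append(
                    OverlapRecord(
                        target=owner,
                        source=src,
                        overlap_len=ln,
                        containment=ln == int(b.length[src]),
                        rank=rk,
                    )
                )
        push_or_merge(stack, int(b.se[owner]) - pos + 1, owner, queue_size)
    return records
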