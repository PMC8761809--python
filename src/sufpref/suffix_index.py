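"""Generalized suffix array, LCP array and document array.

The index is built over the integer-coded concatenated text from
:mod:`sufpref.seqio`.  Because every separator occurrence has a distinct
code ordered by position, an ordinary suffix sort of the code sequence *is*
the generalized suffix sort: the first n+1 ranks are exactly the sentinel
positions, and no common prefix ever crosses a sentinel.

Two constructions are provided:

* :func:`build_index` — vectorized prefix-doubling (Manber–Myers) suffix
  sort in numpy plus a Kasai LCP kernel; O(L log D) where D is the longest
  repeated prefix (bounded by the read length), fast enough for tens of
  millions of symbols.
* :func:`naive_index` — an explicit comparison sort used as the test
  oracle; quadratic-ish, intended for small texts only.

Conformance of any backend is defined solely by the invariants checked in
the test suite (permutation, strict suffix order, sentinel-aware LCP,
document ownership).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .seqio import ConcatText


@dataclass
class SuffixIndex:
    """SA / LCP / DA triplet over a concatenated text.

    ``sa[i]`` is the start of the rank-i suffix; ``lcp[i]`` the longest
    common prefix with the rank-(i-1) suffix (``lcp[0] = 0``); ``da[i]``
    the 1-based read owning position ``sa[i]`` (separators belong to the
    read they follow, the terminator to pseudo-read n+1).
    """

    sa: np.ndarray
    lcp: np.ndarray
    da: np.ndarray
    n: int

    @property
    def L(self) -> int:
        return int(self.sa.size)


@dataclass
class Boundaries:
    """Per-read intervals in the concatenated text (1-based read index).

    ``fi[x]``/``se[x]`` are the first and last *base* positions of read x;
    ``length[x] = se[x] - fi[x] + 1`` is its base length (the separator is
    not counted).  Index 0 is unused.
    """

    fi: np.ndarray
    se: np.ndarray
    length: np.ndarray
    n: int


def _suffix_sort_doubling(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix sort on an integer sequence.

    Terminates as soon as all ranks are distinct, which for sentinel-
    separated read sets happens once the window exceeds the longest read.
    """
    L = codes.size
    key = codes.astype(np.int64)
    order = np.argsort(key, kind="stable")
    rank = np.empty(L, dtype=np.int64)
    rank[order] = np.concatenate(
        ([0], np.cumsum(key[order][1:] != key[order][:-1]))
    )
    k = 1
    while rank[order[-1]] != L - 1:
        key2 = np.full(L, -1, dtype=np.int64)
        key2[: L - k] = rank[k:]
        order = np.lexsort((key2, rank))
        changed = (rank[order][1:] != rank[order][:-1]) | (
            key2[order][1:] != key2[order][:-1]
        )
        new_rank = np.empty(L, dtype=np.int64)
        new_rank[order] = np.concatenate(([0], np.cumsum(changed)))
        rank = new_rank
        k *= 2
    return order.astype(np.int64)


def _document_array(sa: np.ndarray, ct: ConcatText) -> np.ndarray:
    """DA by locating each suffix start within the read intervals."""
    sent_pos = np.sort(sa[: ct.n + 1])  # sentinel positions, ascending
    return (np.searchsorted(sent_pos, sa, side="left") + 1).astype(np.int64)


def build_index(ct: ConcatText, validate: bool = True) -> SuffixIndex:
    """Build SA, LCP and DA over the concatenated text."""
    sa = _suffix_sort_doubling(ct.codes)
    rank = np.empty(ct.L, dtype=np.int64)
    rank[sa] = np.arange(ct.L, dtype=np.int64)
    lcp = _kernels.kasai_lcp(ct.codes.astype(np.int64), sa, rank)
    da = _document_array(sa, ct)
    si = SuffixIndex(sa=sa, lcp=lcp, da=da, n=ct.n)
    if validate:
        head = ct.codes[sa[: ct.n + 1]]
        if not np.all(head <= ct.n):
            raise RuntimeError("index corruption: first n+1 ranks are not sentinels")
    return si


def naive_index(ct: ConcatText) -> SuffixIndex:
    """Oracle construction by explicit sentinel-aware suffix comparison.

    Limited to small texts (L up to ~20,000 and n <= 250: suffixes are
    compared as byte strings, so every code must fit one byte).
    """
    L = ct.L
    if ct.n + 5 > 255:
        raise ValueError("naive_index supports at most 250 reads")
    buf = ct.codes.astype(np.uint8).tobytes()
    sa = np.array(sorted(range(L), key=lambda p: buf[p:]), dtype=np.int64)
    lcp = np.zeros(L, dtype=np.int64)
    for r in range(1, L):
        a, b = sa[r - 1], sa[r]
        h = 0
        while a + h < L and b + h < L and buf[a + h] == buf[b + h]:
            h += 1
        lcp[r] = h
    # ownership scan: separators codes 1..n mark read ends
    owner_of = np.empty(L, dtype=np.int64)
    x = 1
    for p in range(L):
        c = int(ct.codes[p])
        if c == 0:
            owner_of[p] = ct.n + 1
        else:
            owner_of[p] = x
            if 1 <= c <= ct.n:
                x += 1
    da = owner_of[sa]
    return SuffixIndex(sa=sa, lcp=lcp, da=da, n=ct.n)


def derive_boundaries(si: SuffixIndex, ct: ConcatText) -> Boundaries:
    """Fi/Se/LEN from the sorted sentinel positions of the first n+1 ranks.

    This derivation is independent of the backend's convention for
    ordering the sentinel suffixes among themselves.
    """
    n = si.n
    sent = np.sort(si.sa[: n + 1])
    if not np.all(ct.codes[sent] <= n):
        raise RuntimeError("index corruption: sentinel count mismatch")
    if sent[-1] != ct.L - 1:
        raise RuntimeError("index corruption: terminator is not the last symbol")
    seps = sent[:-1]  # separator after read x, ascending = reads in order
    fi = np.empty(n + 1, dtype=np.int64)
    se = np.empty(n + 1, dtype=np.int64)
    fi[0] = se[0] = 0
    fi[1] = 0
    fi[2:] = seps[:-1] + 1
    se[1:] = seps - 1
    length = np.empty(n + 1, dtype=np.int64)
    length[0] = 0
    length[1:] = se[1:] - fi[1:] + 1
    if np.any(length[1:] < 1):
        raise RuntimeError("index corruption: empty read interval")
    return Boundaries(fi=fi, se=se, length=length, n=n)


def suffix_length(pos: int, b: Boundaries, owner: int) -> int:
    """Number of bases from ``pos`` to the end of its read (inclusive)."""
    if not (b.fi[owner] <= pos <= b.se[owner]):
        raise ValueError(
            f"position {pos} is not a base of read {owner} "
            f"[{int(b.fi[owner])}, {int(b.se[owner])}]"
        )
    return int(b.se[owner] - pos + 1)
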