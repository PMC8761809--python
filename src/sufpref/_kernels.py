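"""Numba kernels for the hot loops.

Everything here operates on plain int64 numpy arrays so the same code path
serves toy examples and multi-megabase concatenated texts.  The kernels
mirror, instruction for instruction, the pure-Python reference
implementations in :mod:`sufpref.exact_overlap` and
:mod:`sufpref.tolerant_overlap`; the test suite asserts the equivalence.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def kasai_lcp(codes, sa, rank):
    """Kasai's algorithm: LCP[r] = lcp(suffix SA[r-1], suffix SA[r]).

    Separator symbols are pairwise-distinct codes, so a common prefix can
    never extend across a sentinel and the LCP automatically counts base
    symbols only.
    """
    L = sa.size
    lcp = np.zeros(L, np.int64)
    h = 0
    for p in range(L):
        r = rank[p]
        if r > 0:
            q = sa[r - 1]
            while p + h < L and q + h < L and codes[p + h] == codes[q + h]:
                h += 1
            lcp[r] = h
            if h > 0:
                h -= 1
        else:
            h = 0
    return lcp


@njit(cache=False)
def exact_traversal(sa, lcp, da, fi, se, n, queue_size, k_top, min_overlap, top_only):
    """Single pass of the exact (no-mismatch) version.

    Monotonic stack elements carry the shared suffix length (``first``) and
    a rolling queue of up to ``queue_size`` owner reads.  At a full-read
    suffix the stack is harvested for up to ``k_top`` candidate sources.

    Returns (m, out_target, out_source, out_len, out_rank).
    """
    L = sa.size
    # max read length bounds the stack depth (firsts are strictly increasing
    # positive suffix lengths)
    maxlen = 0
    for x in range(1, n + 1):
        ln = se[x] - fi[x] + 1
        if ln > maxlen:
            maxlen = ln
    depth = maxlen + 2
    st_first = np.empty(depth, np.int64)
    st_q = np.empty((depth, queue_size), np.int64)
    st_head = np.empty(depth, np.int64)
    st_have = np.empty(depth, np.int64)
    top = -1

    cap = n * k_top
    out_t = np.empty(cap, np.int64)
    out_s = np.empty(cap, np.int64)
    out_len = np.empty(cap, np.int64)
    out_rank = np.empty(cap, np.int64)
    m = 0

    for i in range(n + 1, L):
        cur = lcp[i]
        # pop expired: strictly longer suffixes can no longer fully match
        while top >= 0 and st_first[top] > cur:
            top -= 1
        owner = da[i]
        pos = sa[i]
        if pos == fi[owner]:
            # complete read: harvest from the top of the stack downward
            cnt = 0
            j = top
            while j >= 0 and cnt < k_top:
                f = st_first[j]
                if f < min_overlap:
                    break
                have = st_have[j]
                head = st_head[j]
                for t in range(have):
                    src = st_q[j, (head + have - 1 - t) % queue_size]
                    if src != owner:
                        out_t[m] = owner
                        out_s[m] = src
                        out_len[m] = f
                        cnt += 1
                        out_rank[m] = cnt
                        m += 1
                        if cnt >= k_top:
                            break
                if top_only:
                    break
                j -= 1
        # push or merge the current suffix
        suf = se[owner] - pos + 1
        if top >= 0 and st_first[top] == suf:
            head = st_head[top]
            have = st_have[top]
            st_q[top, (head + have) % queue_size] = owner
            if have == queue_size:
                st_head[top] = (head + 1) % queue_size
            else:
                st_have[top] = have + 1
        else:
            top += 1
            st_first[top] = suf
            st_q[top, 0] = owner
            st_head[top] = 0
            st_have[top] = 1
    return m, out_t[:m], out_s[:m], out_len[:m], out_rank[:m]


@njit(cache=False)
def tolerant_traversal(sa, lcp, da, fi, se, n, K, k_top):
    """Single pass of the end-tolerant version with cut budget ``K``.

    Stack elements are (matched length, representative SA rank, previous
    distinct-owner representative).  ``merge_on_pop`` keeps, among popped
    elements, the representative with the smallest tail cut not exceeding
    K (ties -> most recent).  Harvest happens at suffixes whose head offset
    within their read is at most K; the per-read best (ANS/LEN) and a
    min-heap of the k best candidates are maintained.

    Returns (ans_rank, ans_len, ans_h, hp_rank, hp_len, hp_h, hp_size).
    """
    L = sa.size
    maxlen = 0
    for x in range(1, n + 1):
        ln = se[x] - fi[x] + 1
        if ln > maxlen:
            maxlen = ln
    depth = maxlen + 2
    st_first = np.empty(depth, np.int64)
    st_rank = np.empty(depth, np.int64)
    st_shadow = np.empty(depth, np.int64)
    top = -1

    ans_rank = np.full(n + 1, -1, np.int64)
    ans_len = np.zeros(n + 1, np.int64)
    ans_h = np.full(n + 1, -1, np.int64)
    hp_rank = np.empty((n + 1, k_top), np.int64)
    hp_len = np.empty((n + 1, k_top), np.int64)
    hp_h = np.empty((n + 1, k_top), np.int64)
    hp_size = np.zeros(n + 1, np.int64)

    for i in range(n + 1, L):
        cur = lcp[i]
        if top >= 0 and st_first[top] > cur:
            # merge-on-pop: pop everything with first >= LCP(i), keep the
            # best representative (smallest tail cut, within budget K)
            best_cut = np.int64(1) << 60
            best_rank = np.int64(-1)
            best_shadow = np.int64(-1)
            while top >= 0 and st_first[top] >= cur:
                r = st_rank[top]
                cut = (se[da[r]] - sa[r] + 1) - cur
                if cut <= K and (cut < best_cut or (cut == best_cut and r > best_rank)):
                    best_cut = cut
                    best_rank = r
                    best_shadow = st_shadow[top]
                top -= 1
            if cur > 0 and best_rank >= 0:
                top += 1
                st_first[top] = cur
                st_rank[top] = best_rank
                st_shadow[top] = best_shadow
        owner = da[i]
        pos = sa[i]
        h = pos - fi[owner]
        if h <= K:
            # harvestable suffix: the top of the stack is the best match
            # for the read's prefix cut at h; skip self-owned entries
            cand_rank = np.int64(-1)
            cand_len = np.int64(0)
            j = top
            while j >= 0:
                f = st_first[j]
                r1 = st_rank[j]
                if da[r1] != owner:
                    cand_rank = r1
                    cand_len = f
                    break
                r2 = st_shadow[j]
                if r2 >= 0 and da[r2] != owner and (se[da[r2]] - sa[r2] + 1) - f <= K:
                    cand_rank = r2
                    cand_len = f
                    break
                j -= 1
            if cand_rank >= 0:
                if cand_len > ans_len[owner]:
                    ans_len[owner] = cand_len
                    ans_rank[owner] = cand_rank
                    ans_h[owner] = h
                # offer to the read's min-heap of top-k candidates
                sz = hp_size[owner]
                if sz < k_top:
                    # sift up
                    c = sz
                    hp_rank[owner, c] = cand_rank
                    hp_len[owner, c] = cand_len
                    hp_h[owner, c] = h
                    hp_size[owner] = sz + 1
                    while c > 0:
                        p = (c - 1) // 2
                        if hp_len[owner, p] > hp_len[owner, c]:
                            hp_len[owner, p], hp_len[owner, c] = (
                                hp_len[owner, c],
                                hp_len[owner, p],
                            )
                            hp_rank[owner, p], hp_rank[owner, c] = (
                                hp_rank[owner, c],
                                hp_rank[owner, p],
                            )
                            hp_h[owner, p], hp_h[owner, c] = (
                                hp_h[owner, c],
                                hp_h[owner, p],
                            )
                            c = p
                        else:
                            break
                elif cand_len > hp_len[owner, 0]:
                    # replace the worst kept answer, sift down
                    hp_rank[owner, 0] = cand_rank
                    hp_len[owner, 0] = cand_len
                    hp_h[owner, 0] = h
                    c = np.int64(0)
                    while True:
                        l = 2 * c + 1
                        r = 2 * c + 2
                        small = c
                        if l < k_top and hp_len[owner, l] < hp_len[owner, small]:
                            small = l
                        if r < k_top and hp_len[owner, r] < hp_len[owner, small]:
                            small = r
                        if small == c:
                            break
                        hp_len[owner, small], hp_len[owner, c] = (
                            hp_len[owner, c],
                            hp_len[owner, small],
                        )
                        hp_rank[owner, small], hp_rank[owner, c] = (
                            hp_rank[owner, c],
                            hp_rank[owner, small],
                        )
                        hp_h[owner, small], hp_h[owner, c] = (
                            hp_h[owner, c],
                            hp_h[owner, small],
                        )
                        c = small
        # push the current suffix
        suf = se[owner] - pos + 1
        if top < 0 or suf > st_first[top]:
            top += 1
            st_first[top] = suf
            st_rank[top] = i
            st_shadow[top] = -1
        elif suf == st_first[top]:
            if da[st_rank[top]] != owner:
                st_shadow[top] = st_rank[top]
            st_rank[top] = i
        # suf < top.first cannot happen after merge (first <= LCP <= suf)
    return ans_rank, ans_len, ans_h, hp_rank, hp_len, hp_h, hp_size
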