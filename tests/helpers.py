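"""Independent oracles and small utilities shared by the tests.

The overlap oracles never touch the suffix-array/monotonic-stack code
path: the fast one runs a KMP prefix-function over ``target # source``
(all suffix-prefix match lengths are the borders of that string), and a
tiny quadratic slicer cross-checks the KMP oracle itself on small inputs.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from numba import njit

from sufpref import ReadSet, build_index, concatenate, derive_boundaries


@njit(cache=False)
def _borders(src: np.ndarray, tgt: np.ndarray) -> np.ndarray:
    """All l (descending) with src[-l:] == tgt[:l], via the KMP prefix
    function of ``tgt + sentinel + src``."""
    m = tgt.size
    n = src.size
    w = np.empty(m + 1 + n, np.uint8)
    w[:m] = tgt
    w[m] = 0  # sentinel byte, never occurs in ACGTN
    w[m + 1 :] = src
    pi = np.zeros(w.size, np.int64)
    k = 0
    for i in range(1, w.size):
        while k > 0 and w[i] != w[k]:
            k = pi[k - 1]
        if w[i] == w[k]:
            k += 1
        pi[i] = k
    out = np.empty(m + 1, np.int64)
    c = 0
    l = pi[-1]
    while l > 0:
        out[c] = l
        c += 1
        l = pi[l - 1]
    return out[:c]


def _bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def overlap_lengths(source: str, target: str) -> List[int]:
    """All suffix(source)==prefix(target) match lengths, descending."""
    return [int(l) for l in _borders(_bytes(source), _bytes(target))]


def longest_overlap(source: str, target: str) -> int:
    ls = overlap_lengths(source, target)
    return ls[0] if ls else 0


def longest_overlap_quadratic(source: str, target: str) -> int:
    """Slow direct-slicing oracle used to validate the KMP oracle."""
    for l in range(min(len(source), len(target)), 0, -1):
        if source[-l:] == target[:l]:
            return l
    return 0


def brute_best_per_target(reads: List[str]) -> Dict[int, Tuple[int, int]]:
    """Per 1-based target: (argmax source, max overlap length), ties to the
    smallest source index; targets with no overlap are absent."""
    best: Dict[int, Tuple[int, int]] = {}
    for t in range(1, len(reads) + 1):
        for s in range(1, len(reads) + 1):
            if s == t:
                continue
            l = longest_overlap(reads[s - 1], reads[t - 1])
            if l > 0 and (t not in best or l > best[t][1]):
                best[t] = (s, l)
    return best


def brute_tolerant_max(source: str, target: str, K: int) -> int:
    """Upper-bound oracle for the tolerant version: the longest l such that
    suffix(source minus c bases) == prefix(target minus h bases) for some
    head cut h <= K and tail cut c <= K."""
    best = 0
    for h in range(min(K, len(target) - 1) + 1):
        for c in range(min(K, len(source) - 1) + 1):
            l = longest_overlap(source[: len(source) - c], target[h:])
            if l > best:
                best = l
    return best


def random_reads(rng: np.random.Generator, n_lo, n_hi, len_lo, len_hi) -> List[str]:
    n = int(rng.integers(n_lo, n_hi + 1))
    return [
        "".join(rng.choice(list("ACGT"), size=int(rng.integers(len_lo, len_hi + 1))))
        for _ in range(n)
    ]


def index_reads(reads: List[str]):
    """Build (ReadSet, SuffixIndex, Boundaries) for a list of sequences."""
    rs = ReadSet(reads=list(reads), ids=[f"r{i + 1}" for i in range(len(reads))])
    ct = concatenate(rs)
    si = build_index(ct)
    b = derive_boundaries(si, ct)
    return rs, si, b


def check_exact_record(rec, reads: List[str]) -> bool:
    """String-check: the source's suffix of overlap_len equals the
    target's prefix."""
    src = reads[rec.source - 1]
    tgt = reads[rec.target - 1]
    l = rec.overlap_len
    return l <= min(len(src), len(tgt)) and src[-l:] == tgt[:l]


def check_tolerant_record(rec, reads: List[str]) -> bool:
    """String-check the cut-adjusted match of a tolerant record."""
    src = reads[rec.source - 1]
    tgt = reads[rec.target - 1]
    l, h, c = rec.overlap_len, rec.head_cut, rec.tail_cut
    if l + c > len(src) or h + l > len(tgt):
        return False
    return src[len(src) - c - l : len(src) - c] == tgt[h : h + l]
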