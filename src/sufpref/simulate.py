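"""Read simulation with ground-truth coordinates and accuracy scoring.

The simulator emulates the accuracy protocol used to validate the overlap
finder: draw a uniform-random reference, sample reads as substrings with
their origin interval recorded in a *check file*, optionally corrupt the
two end flanks (each flank base substituted independently, the central
core left untouched), run the finder, and score each reported overlap of
at least ``min_overlap`` bases as correct when the two reads' true
reference intervals intersect.

Errors are substitutions only, so read lengths and hence check intervals
are exact.  All randomness flows through explicit seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .seqio import OverlapRecord, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CheckRecord:
    """Ground truth for one read: 0-based half-open origin interval."""

    read: int  # 1-based read index
    ref_start: int
    ref_end: int


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``flank_accuracy = 0.8`` and ``core_fraction = 0.5`` reproduce the
    three-part read model of the tolerant version's validation: 80%%
    accurate flanks around an error-free core covering at least half the
    read.  ``read_len_spread`` draws lengths uniformly in
    ``mean ± spread`` (default fixed length).
    """

    ref_len: int = 500_000
    n_reads: int = 2_000
    read_len_mean: int = 5_000
    read_len_spread: int = 0
    flank_accuracy: float = 0.8
    core_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ref_len, self.n_reads, self.read_len_mean) < 1:
            raise ValueError("sizes must be positive")
        if not (0 < self.flank_accuracy <= 1):
            raise ValueError("flank_accuracy must be in (0, 1]")
        if not (0 <= self.core_fraction <= 1):
            raise ValueError("core_fraction must be in [0, 1]")

    def flank_len(self, read_len: int) -> int:
        """Length of each errored end flank for a read of ``read_len``."""
        return int((1 - self.core_fraction) / 2 * read_len)


def generate_reference(ref_len: int, seed: int) -> str:
    """Uniform i.i.d. A/C/G/T reference sequence."""
    if ref_len < 1:
        raise ValueError("ref_len must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=ref_len)].tobytes().decode("ascii")


def sample_reads(ref: str, cfg: SimConfig) -> Tuple[ReadSet, List[CheckRecord]]:
    """Sample reads as substrings at uniform random start positions."""
    rng = np.random.default_rng(cfg.seed)
    lo = cfg.read_len_mean - cfg.read_len_spread
    hi = cfg.read_len_mean + cfg.read_len_spread
    if lo < 1 or hi > len(ref):
        raise ValueError("read lengths must lie in [1, ref_len]")
    reads: List[str] = []
    checks: List[CheckRecord] = []
    for j in range(cfg.n_reads):
        ln = int(rng.integers(lo, hi + 1)) if cfg.read_len_spread else lo
        s = int(rng.integers(0, len(ref) - ln + 1))
        reads.append(ref[s : s + ln])
        checks.append(CheckRecord(read=j + 1, ref_start=s, ref_end=s + ln))
    ids = [f"read{j + 1}" for j in range(cfg.n_reads)]
    return ReadSet(reads=reads, ids=ids), checks


def inject_end_errors(rs: ReadSet, cfg: SimConfig, seed: int) -> ReadSet:
    """Substitute flank bases with probability ``1 - flank_accuracy``.

    Each read is split into three parts: two flanks of
    ``floor((1 - core_fraction)/2 * len)`` bases and an untouched central
    core of at least ``core_fraction * len`` bases.  A substituted base is
    replaced by a uniformly chosen *different* base; lengths never change.
    """
    rng = np.random.default_rng(seed)
    p_err = 1.0 - cfg.flank_accuracy
    lut = np.full(256, -1, dtype=np.int64)
    for v, ch in enumerate(b"ACGT"):
        lut[ch] = v
    out: List[str] = []
    for read in rs.reads:
        fl = cfg.flank_len(len(read))
        if fl == 0 or p_err == 0:
            out.append(read)
            continue
        arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8).copy()
        idx = np.concatenate([np.arange(fl), np.arange(len(read) - fl, len(read))])
        hit = idx[rng.random(idx.size) < p_err]
        if hit.size:
            # add 1..3 mod 4: uniformly one of the three other bases
            codes = lut[arr[hit]]
            if codes.min() < 0:
                raise ValueError("error injection requires A/C/G/T reads")
            arr[hit] = _BASES[(codes + rng.integers(1, 4, size=hit.size)) % 4]
        out.append(arr.tobytes().decode("ascii"))
    return ReadSet(reads=out, ids=list(rs.ids))


def write_check_file(checks: Sequence[CheckRecord], rs: ReadSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tref_start\tref_end\n")
        for rec in checks:
            fh.write(f"{rs.ids[rec.read - 1]}\t{rec.ref_start}\t{rec.ref_end}\n")


def read_check_file(path) -> Tuple[List[str], List[CheckRecord]]:
    """Returns (read ids in file order, check records with 1-based indices)."""
    ids: List[str] = []
    checks: List[CheckRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "read_id\tref_start\tref_end":
            raise ValueError(f"{path}: unrecognized check file header")
        for line in fh:
            if not line.strip():
                continue
            name, s, e = line.rstrip("\n").split("\t")
            ids.append(name)
            checks.append(CheckRecord(read=len(ids), ref_start=int(s), ref_end=int(e)))
    return ids, checks


def write_fasta(rs: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for name, read in zip(rs.ids, rs.reads):
            fh.write(f">{name}\n{read}\n")


def evaluate_accuracy(
    records: Iterable[OverlapRecord],
    checks: Sequence[CheckRecord],
    min_overlap: int = 100,
) -> float:
    """Interval-intersection accuracy over evaluable records.

    Records with ``overlap_len < min_overlap`` are invalid data and are
    discarded from numerator and denominator alike.  A surviving record is
    correct when the source and target reads' true reference intervals
    share at least one position.  Raises when nothing survives (a vacuous
    1.0 would be meaningless).
    """
    by_read = {c.read: c for c in checks}
    total = correct = 0
    for rec in records:
        if rec.overlap_len < min_overlap:
            continue
        s = by_read[rec.source]
        t = by_read[rec.target]
        total += 1
        if s.ref_start < t.ref_end and t.ref_start < s.ref_end:
            correct += 1
    if total == 0:
        raise ValueError("no evaluable records (all below min_overlap)")
    return correct / total


def expected_true_overlap_pairs(cfg: SimConfig, min_overlap: int = 100) -> float:
    """Expected number of ordered read pairs with >= min_overlap bases of
    true interval overlap, under uniform start positions (occupancy
    computation; used as a sanity bound in tests)."""
    span = cfg.ref_len - cfg.read_len_mean
    if span <= 0:
        return float(cfg.n_reads * (cfg.n_reads - 1))
    window = max(cfg.read_len_mean - min_overlap, 0)
    p = min(window / span, 1.0)
    return cfg.n_reads * (cfg.n_reads - 1) * p
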