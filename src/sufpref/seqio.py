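"""Read-set I/O and construction of the concatenated text.

A :class:`ReadSet` holds the input reads (FASTA or FASTQ, forward strand
only).  For indexing, the reads are stitched into a single "original
string": each read is followed by a separator symbol and the whole text
ends with a terminator.  Internally every symbol is remapped to a small
integer so that

    terminator < separator(1) < ... < separator(n) < A < C < G < T < N

i.e. every separator occurrence gets its own rank, ordered by position.
This makes the generalized suffix order unambiguous (no two distinct
suffixes share a prefix across a sentinel) independent of the suffix-array
backend.  In the byte representation of the text the separators are all
ASCII 1 and the terminator is ASCII 0.

Overlap results are serialized as a TSV edge list (one line per directed
suffix->prefix overlap), with an optional PAF export for interoperability
with standard long-read tooling.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np
from Bio import SeqIO

# Base ranks *within* the base alphabet; the concrete integer code of a base
# in a ConcatText is n + rank so that all n separators sort below it.
_BASE_RANK = {"A": 1, "C": 2, "G": 3, "T": 4, "N": 5}
N_BASES = 5

OVERLAP_HEADER = (
    "target_id\tsource_id\toverlap_len\thead_cut\ttail_cut\tcontainment\trank"
)


@dataclass
class ReadSet:
    """Ordered collection of reads with parallel identifiers.

    Read indices used throughout the package are 1-based, matching the
    document-array convention (read x owns document x).
    """

    reads: List[str]
    ids: List[str]

    def __post_init__(self) -> None:
        if len(self.reads) == 0:
            raise ValueError("a ReadSet must contain at least one read")
        if len(self.ids) != len(self.reads):
            raise ValueError("ids and reads must be parallel")
        self.reads = [r.upper() for r in self.reads]
        for j, r in enumerate(self.reads):
            if len(r) == 0:
                raise ValueError(f"read {j + 1} ({self.ids[j]!r}) is empty")
        self.ids = _dedup_ids(self.ids)

    @property
    def n(self) -> int:
        return len(self.reads)

    def length(self, x: int) -> int:
        """Base length of read x (1-based)."""
        return len(self.reads[x - 1])

    def __len__(self) -> int:
        return len(self.reads)


def _dedup_ids(ids: Sequence[str]) -> List[str]:
    """Make identifiers unique by suffixing duplicates with ``_dupJ``."""
    seen: dict = {}
    out: List[str] = []
    for name in ids:
        if name not in seen:
            seen[name] = 0
            out.append(name)
        else:
            seen[name] += 1
            new = f"{name}_dup{seen[name]}"
            while new in seen:
                seen[name] += 1
                new = f"{name}_dup{seen[name]}"
            seen[new] = 0
            out.append(new)
    return out


def read_sequences(path, fmt: str = "auto") -> ReadSet:
    """Parse FASTA or FASTQ into a :class:`ReadSet`.

    ``fmt="auto"`` infers the format from the first non-blank character
    ('>' FASTA, '@' FASTQ).  Sequences are uppercased; FASTQ qualities are
    discarded.  Malformed records raise :class:`ValueError` naming the
    record index.
    """
    path = Path(path)
    if fmt == "auto":
        with open(path) as fh:
            head = ""
            for line in fh:
                if line.strip():
                    head = line.lstrip()[0]
                    break
        if head == ">":
            fmt = "fasta"
        elif head == "@":
            fmt = "fastq"
        else:
            raise ValueError(
                f"{path}: cannot infer format (first record starts with {head!r})"
            )
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {fmt!r}")

    reads: List[str] = []
    ids: List[str] = []
    with open(path) as fh:
        it = SeqIO.parse(fh, fmt)
        idx = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as exc:  # malformed record
                raise ValueError(f"{path}: malformed {fmt} record {idx + 1}: {exc}")
            idx += 1
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"{path}: record {idx} ({rec.id!r}) has empty sequence")
            reads.append(seq)
            ids.append(rec.id)
    if not reads:
        raise ValueError(f"{path}: no records found")
    return ReadSet(reads=reads, ids=ids)


@dataclass
class ConcatText:
    """The "original string": reads joined with sentinels, as integer codes.

    ``codes[p]`` is 0 for the terminator (last position), x in 1..n for the
    separator following read x, and n + rank(base) for bases.  ``sep_code``
    and ``term_code`` are the ASCII identities (1 and 0) used in the byte
    representation.
    """

    codes: np.ndarray
    n: int
    sep_code: int = 1
    term_code: int = 0

    @property
    def L(self) -> int:
        return int(self.codes.size)

    @property
    def base_offset(self) -> int:
        """Codes strictly greater than this are bases."""
        return self.n

    def is_base(self, pos: int) -> bool:
        return int(self.codes[pos]) > self.n

    def to_bytes(self) -> bytes:
        """Literal byte form: bases as ASCII letters, separators ASCII 1,
        terminator ASCII 0."""
        inv = {v: k for k, v in _BASE_RANK.items()}
        out = bytearray()
        for c in self.codes:
            c = int(c)
            if c == 0:
                out.append(self.term_code)
            elif c <= self.n:
                out.append(self.sep_code)
            else:
                out.append(ord(inv[c - self.n]))
        return bytes(out)


def concatenate(rs: ReadSet) -> ConcatText:
    """Stitch all reads into the original string ``r1·SEP·…·rn·SEP·TERM``.

    Total length is ``sum(len) + n + 1``.  A read containing a symbol
    outside {A,C,G,T,N} (which would collide with the sentinel encoding)
    raises :class:`ValueError`.
    """
    n = rs.n
    L = sum(len(r) for r in rs.reads) + n + 1
    lut = np.full(256, -1, dtype=np.int32)
    for ch, rank in _BASE_RANK.items():
        lut[ord(ch)] = rank
    codes = np.zeros(L, dtype=np.int32)
    p = 0
    for x, read in enumerate(rs.reads, start=1):
        arr = np.frombuffer(read.encode("ascii"), dtype=np.uint8)
        ranks = lut[arr]
        if ranks.min() < 0:
            bad = read[int(np.argmax(ranks < 0))]
            raise ValueError(
                f"read {x} ({rs.ids[x - 1]!r}) contains unsupported symbol {bad!r}"
            )
        codes[p : p + arr.size] = n + ranks
        p += arr.size
        codes[p] = x  # separator after read x, ranked by position
        p += 1
    codes[p] = 0  # terminator
    return ConcatText(codes=codes, n=n)


@dataclass
class OverlapRecord:
    """One directed suffix->prefix overlap: ``source``'s (possibly
    tail-cut) suffix equals ``target``'s (possibly head-cut) prefix.

    ``source`` and ``target`` are 1-based read indices.  ``containment`` is
    True when the overlap consumes the source read entirely.  ``rank`` is
    the 1-based position among the target's top-k candidates.
    """

    target: int
    source: int
    overlap_len: int
    head_cut: int = 0
    tail_cut: int = 0
    containment: bool = False
    rank: int = 1

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-overlap records are not allowed")
        if self.overlap_len < 1 or self.head_cut < 0 or self.tail_cut < 0:
            raise ValueError("invalid overlap geometry")


def write_overlaps(records: Iterable[OverlapRecord], rs: ReadSet, path) -> None:
    """Write records as TSV, one per line, in the order given.

    The drivers hand records over already grouped by target (exact mode in
    encounter order, tolerant mode in input-read order); the writer
    preserves that order so output is deterministic byte-for-byte.
    """
    with open(path, "w") as fh:
        fh.write(OVERLAP_HEADER + "\n")
        for rec in records:
            fh.write(
                f"{rs.ids[rec.target - 1]}\t{rs.ids[rec.source - 1]}\t"
                f"{rec.overlap_len}\t{rec.head_cut}\t{rec.tail_cut}\t"
                f"{int(rec.containment)}\t{rec.rank}\n"
            )


def read_overlaps(path, rs: ReadSet) -> List[OverlapRecord]:
    """Parse a TSV written by :func:`write_overlaps` back into records."""
    idx = {name: j + 1 for j, name in enumerate(rs.ids)}
    out: List[OverlapRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != OVERLAP_HEADER:
            raise ValueError(f"{path}: unrecognized overlap file header")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns")
            tgt, src, olen, hc, tc, cont, rank = parts
            out.append(
                OverlapRecord(
                    target=idx[tgt],
                    source=idx[src],
                    overlap_len=int(olen),
                    head_cut=int(hc),
                    tail_cut=int(tc),
                    containment=bool(int(cont)),
                    rank=int(rank),
                )
            )
    return out


def write_paf(records: Iterable[OverlapRecord], rs: ReadSet, path) -> None:
    """PAF export: the source read is the query, the target the subject.

    The matched block (overlap_len) maps to both the number of matches and
    the alignment block length; coordinates account for head/tail cuts.
    """
    with open(path, "w") as fh:
        for rec in records:
            qlen = rs.length(rec.source)
            tlen = rs.length(rec.target)
            qend = qlen - rec.tail_cut
            qstart = qend - rec.overlap_len
            tstart = rec.head_cut
            tend = tstart + rec.overlap_len
            fh.write(
                f"{rs.ids[rec.source - 1]}\t{qlen}\t{qstart}\t{qend}\t+\t"
                f"{rs.ids[rec.target - 1]}\t{tlen}\t{tstart}\t{tend}\t"
                f"{rec.overlap_len}\t{rec.overlap_len}\t255\n"
            )
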