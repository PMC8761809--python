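"""Edge-weighted overlap graph for downstream layout/contig construction.

Nodes are reads (every read appears, even when isolated); a directed edge
source -> target carries the overlap length as its weight plus the cut and
containment bookkeeping.  Duplicate (source, target) records collapse to
the longest overlap.  Serializations: a deterministic edge-list TSV and an
optional GFA-1 export where each overlap becomes an L-line with a
``<len>M`` overlap CIGAR.
"""

from __future__ import annotations

from typing import Iterable, List

import networkx as nx

from .seqio import OverlapRecord, ReadSet

GRAPH_HEADER = "source_id\ttarget_id\toverlap_len\thead_cut\ttail_cut\tcontainment"


def build_graph(records: Iterable[OverlapRecord], rs: ReadSet) -> nx.DiGraph:
    """Directed graph with one node per read and at most one edge per
    (source, target) pair (maximum overlap length kept)."""
    g = nx.DiGraph()
    for x, name in enumerate(rs.ids, start=1):
        g.add_node(x, id=name, length=rs.length(x))
    for rec in records:
        if rec.source < 1 or rec.source > rs.n or rec.target < 1 or rec.target > rs.n:
            raise ValueError(
                f"record references unknown read {rec.source}->{rec.target}"
            )
        if g.has_edge(rec.source, rec.target):
            if rec.overlap_len <= g[rec.source][rec.target]["weight"]:
                continue
        g.add_edge(
            rec.source,
            rec.target,
            weight=rec.overlap_len,
            head_cut=rec.head_cut,
            tail_cut=rec.tail_cut,
            containment=rec.containment,
            rank=rec.rank,
        )
    return g


def write_graph(g: nx.DiGraph, rs: ReadSet, path) -> None:
    """Edge-list TSV preceded by node lines, nodes in input-read order."""
    with open(path, "w") as fh:
        fh.write(GRAPH_HEADER + "\n")
        for x in range(1, rs.n + 1):
            fh.write(f"#node\t{rs.ids[x - 1]}\t{rs.length(x)}\n")
        for s in range(1, rs.n + 1):
            for t in sorted(g.successors(s)):
                e = g[s][t]
                fh.write(
                    f"{rs.ids[s - 1]}\t{rs.ids[t - 1]}\t{e['weight']}\t"
                    f"{e['head_cut']}\t{e['tail_cut']}\t{int(e['containment'])}\n"
                )


def read_graph(path, rs: ReadSet) -> nx.DiGraph:
    """Parse a TSV written by :func:`write_graph` back into a graph."""
    idx = {name: j + 1 for j, name in enumerate(rs.ids)}
    g = nx.DiGraph()
    for x, name in enumerate(rs.ids, start=1):
        g.add_node(x, id=name, length=rs.length(x))
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != GRAPH_HEADER:
            raise ValueError(f"{path}: unrecognized graph file header")
        for line in fh:
            if line.startswith("#node") or not line.strip():
                continue
            src, tgt, w, hc, tc, cont = line.rstrip("\n").split("\t")
            g.add_edge(
                idx[src],
                idx[tgt],
                weight=int(w),
                head_cut=int(hc),
                tail_cut=int(tc),
                containment=bool(int(cont)),
            )
    return g


def write_gfa(g: nx.DiGraph, rs: ReadSet, path) -> None:
    """GFA-1 export: S-lines with sequences, L-lines with ``<len>M``."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for x in range(1, rs.n + 1):
            fh.write(f"S\t{rs.ids[x - 1]}\t{rs.reads[x - 1]}\n")
        for s in range(1, rs.n + 1):
            for t in sorted(g.successors(s)):
                fh.write(
                    f"L\t{rs.ids[s - 1]}\t+\t{rs.ids[t - 1]}\t+\t"
                    f"{g[s][t]['weight']}M\n"
                )
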