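"""Median-joining haplotype networks (Bandelt-style).

A median-joining (MJ) network starts from the minimum spanning network
(MSN) -- the union of all minimum spanning trees over the haplotype
distance matrix -- and then repeatedly proposes "median" (consensus)
sequences for triples of mutually connected nodes, adding those whose
connection cost is within ``epsilon`` of the minimum, until the network
stabilises. Median vectors represent unsampled (extinct or unsampled)
intermediate haplotypes; with shallow intraspecific divergence and
``epsilon = 0`` the result is often the MSN itself.

Distances default to ``INDEL_AS_EVENT`` so that a multi-base indel is one
mutation on one edge. Edge labels carry the mutated reference positions
(an indel run as a single ``start-end`` label), so each edge's label count
equals the distance between its endpoints in the active mode.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .diversity import DistanceMatrix, DistanceMode, sequence_distance
from .seqdata import HaplotypeTable

__all__ = ["MJNet", "minimum_spanning_net", "median_joining", "node_degree"]

MEDIAN_PREFIX = "mv"


def minimum_spanning_net(dm: DistanceMatrix) -> set[frozenset[str]]:
    """Union of all minimum spanning trees (the MSN backbone).

    An edge (u, v) belongs to some MST iff u and v are not connected using
    only edges strictly cheaper than d(u, v); equivalently, a Kruskal pass
    that, within each weight class, keeps every link joining components
    that were distinct when the class was entered.
    """
    ids = dm.haplotype_ids
    n = len(ids)
    pairs = sorted(
        ((float(dm.d[i, j]), i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: t[0],
    )
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges: set[frozenset[str]] = set()
    for _, group in itertools.groupby(pairs, key=lambda t: t[0]):
        group = list(group)
        keep = [(i, j) for _, i, j in group if find(i) != find(j)]
        for i, j in keep:
            edges.add(frozenset((ids[i], ids[j])))
        for i, j in keep:
            parent[find(i)] = find(j)
    return edges


def _indel_runs(seqs: list[str]) -> list[tuple[int, int]]:
    """Maximal contiguous 0-based column runs where both a gap and a base
    occur among `seqs`."""
    L = len(seqs[0])
    mark = [
        any(s[c] == "-" for s in seqs) and any(s[c] not in "-N" for s in seqs)
        for c in range(L)
    ]
    runs, c = [], 0
    while c < L:
        if mark[c]:
            start = c
            while c + 1 < L and mark[c + 1]:
                c += 1
            runs.append((start, c))
        c += 1
    return runs


def _median_of_three(a: str, b: str, c: str) -> str:
    """Columnwise majority consensus of three aligned sequences.

    Indel runs (columns where gap and base both occur among the triple)
    are treated as a single binary character so the consensus cannot mix a
    partial gap. Ties (all three states distinct) resolve to the first
    sequence's state; ``N`` never wins a vote unless all three are ``N``.
    """
    seqs = [a, b, c]
    runs = _indel_runs(seqs)
    in_run = {col for s, e in runs for col in range(s, e + 1)}
    out = []
    col = 0
    L = len(a)
    run_by_start = {s: e for s, e in runs}
    while col < L:
        if col in in_run and col in run_by_start:
            e = run_by_start[col]
            chunks = [s[col : e + 1] for s in seqs]
            votes = [ch for ch in chunks if "N" not in ch]
            if not votes:
                out.append(chunks[0])
            else:
                best = max(votes, key=lambda ch: (votes.count(ch), -chunks.index(ch)))
                out.append(best)
            col = e + 1
        else:
            states = [s[col] for s in seqs]
            votes = [x for x in states if x != "N"]
            if not votes:
                out.append("N")
            else:
                best = max(votes, key=lambda x: (votes.count(x), -states.index(x)))
                out.append(best)
            col += 1
    return "".join(out)


def _diff_labels(a: str, b: str, mode: DistanceMode, offset: int) -> tuple[str, ...]:
    """Mutation labels for the edge a--b; length equals the distance."""
    labels: list[str] = []
    in_run = False
    run_start = 0
    L = len(a)

    def flush(end_col: int) -> None:
        start_pos, end_pos = offset + run_start, offset + end_col
        if mode is DistanceMode.INDEL_AS_EVENT:
            labels.append(
                f"{start_pos}-{end_pos}" if end_pos > start_pos else f"{start_pos}"
            )
        elif mode is DistanceMode.PER_COLUMN_GAP:
            labels.extend(str(p) for p in range(start_pos, end_pos + 1))
        # SUBSTITUTIONS_ONLY: gap runs unlabelled

    for col in range(L):
        x, y = a[col], b[col]
        if x == "N" or y == "N":
            if in_run:
                flush(col - 1)
                in_run = False
            continue
        xg, yg = x == "-", y == "-"
        if xg != yg:
            if not in_run:
                run_start = col
                in_run = True
        else:
            if in_run:
                flush(col - 1)
                in_run = False
            if not xg and x != y:
                labels.append(str(offset + col))
    if in_run:
        flush(L - 1)
    return tuple(labels)


@dataclass
class MJNet:
    """Median-joining network.

    ``graph`` is an undirected networkx graph; node attributes are
    ``count`` (0 for medians), ``is_median`` and ``sequence``; edge
    attribute ``positions`` holds the mutation labels.
    """

    graph: nx.Graph
    mode: DistanceMode
    epsilon: int

    @property
    def median_nodes(self) -> list[str]:
        return [v for v, d in self.graph.nodes(data=True) if d["is_median"]]

    def edges_dataframe(self):
        import pandas as pd

        rows = [
            {"node_a": u, "node_b": v, "positions": ",".join(d["positions"])}
            for u, v, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "positions"])

    def nodes_dataframe(self):
        import pandas as pd

        rows = [
            {"node_id": v, "count": d["count"], "is_median": d["is_median"]}
            for v, d in sorted(self.graph.nodes(data=True))
        ]
        return pd.DataFrame(rows, columns=["node_id", "count", "is_median"])


def _msn_graph(
    sequences: dict[str, str], mode: DistanceMode
) -> tuple[nx.Graph, dict[str, str]]:
    ids = tuple(sorted(sequences))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sequence_distance(
                sequences[ids[i]], sequences[ids[j]], mode
            )
    dm = DistanceMatrix(ids, d, mode)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in minimum_spanning_net(dm):
        u, v = sorted(e)
        g.add_edge(u, v)
    return g, sequences


def median_joining(
    table: HaplotypeTable,
    mode: DistanceMode = DistanceMode.INDEL_AS_EVENT,
    epsilon: int = 0,
) -> MJNet:
    """Build the median-joining network of a haplotype table.

    Iterates: MSN over current nodes; drop unconnected median vectors;
    for every mutually connected triple propose the consensus median and
    add novel medians whose connection cost (summed distance to the
    triple) is within ``epsilon`` of the minimum; stop at a fixed point.
    Median vectors left with degree < 2 are pruned from the final network.
    """
    if len(table.entries) < 2:
        raise ValueError("median-joining needs at least 2 haplotypes")
    mode = DistanceMode(mode)
    seq_len = {len(e.sequence) for e in table.entries}
    if len(seq_len) != 1:
        raise ValueError("haplotype sequences are not aligned")

    sequences: dict[str, str] = {e.haplotype_id: e.sequence for e in table.entries}
    observed = set(sequences)
    known_seqs = set(sequences.values())
    next_median = itertools.count(1)

    for _ in range(100):  # fixed-point iteration; bound is a safety net
        g, _ = _msn_graph(sequences, mode)
        # obsolete medians: disconnected or pendant median vectors
        obsolete = [
            v for v in g.nodes if v not in observed and g.degree[v] <= 1
        ]
        if obsolete:
            for v in obsolete:
                known_seqs.discard(sequences[v])
                del sequences[v]
            continue
        candidates: dict[str, int] = {}
        for u, v, w in sorted(
            (t for t in itertools.combinations(sorted(g.nodes), 3))
        ):
            if not (g.has_edge(u, v) and g.has_edge(u, w) and g.has_edge(v, w)):
                continue
            m = _median_of_three(sequences[u], sequences[v], sequences[w])
            if m in known_seqs:
                continue
            cost = sum(
                sequence_distance(m, sequences[t], mode) for t in (u, v, w)
            )
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            break
        cmin = min(candidates.values())
        added = False
        for m, cost in sorted(candidates.items(), key=lambda kv: (kv[1], kv[0])):
            if cost <= cmin + epsilon:
                name = f"{MEDIAN_PREFIX}{next(next_median)}"
                sequences[name] = m
                known_seqs.add(m)
                added = True
        if not added:
            break

    # final network; prune medians of degree < 2 (rebuilding after removal)
    while True:
        g, _ = _msn_graph(sequences, mode)
        prune = [v for v in g.nodes if v not in observed and g.degree[v] < 2]
        if not prune:
            break
        for v in prune:
            del sequences[v]

    counts = {e.haplotype_id: e.count for e in table.entries}
    net = nx.Graph()
    for v in sorted(sequences):
        net.add_node(
            v,
            count=counts.get(v, 0),
            is_median=v not in observed,
            sequence=sequences[v],
        )
    offset = table.offset
    for u, v in sorted(map(sorted, g.edges())):
        net.add_edge(
            u, v, positions=_diff_labels(sequences[u], sequences[v], mode, offset)
        )
    return MJNet(net, mode, epsilon)


def node_degree(net: MJNet, node_id: str) -> int:
    """Number of edges incident to `node_id`."""
    if node_id not in net.graph:
        raise KeyError(f"unknown node: {node_id}")
    return int(net.graph.degree[node_id])
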