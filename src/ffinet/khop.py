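"""Directed 1/2/3-hop simple-path indexes over the bonded graph.

A hop-k entry is a directed simple path ``(i, ..., j)`` of exactly k bonds
with ``i`` the target atom and ``j`` the source atom.  Hop membership is by
path length, not shortest-path distance: in a ring a bonded neighbour is also
reachable by a 2-hop path and, by default, both entries are kept (each path
carries distinct geometry).  ``dedupe_hops=True`` keeps only paths whose
endpoints are at graph distance exactly k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = ["KHopIndex", "build_khop_index", "enumerate_paths_oracle", "MAX_HOP"]

MAX_HOP = 3


@dataclass
class KHopIndex:
    """Directed simple paths of length 1, 2, 3 as integer arrays.

    ``hop1`` has shape (P1, 2), ``hop2`` (P2, 3), ``hop3`` (P3, 4); column 0
    is the target atom i, the last column is the source atom j.  Rows are in
    lexicographic order and each path's reversal is present in the same list.
    """

    hop1: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))
    hop2: np.ndarray = field(default_factory=lambda: np.zeros((0, 3), dtype=np.int64))
    hop3: np.ndarray = field(default_factory=lambda: np.zeros((0, 4), dtype=np.int64))

    def hop(self, k: int) -> np.ndarray:
        return (self.hop1, self.hop2, self.hop3)[k - 1]


def _as_paths_array(paths: list[tuple[int, ...]], k: int) -> np.ndarray:
    if not paths:
        return np.zeros((0, k + 1), dtype=np.int64)
    return np.array(sorted(paths), dtype=np.int64)


def build_khop_index(
    bonds: list[tuple[int, int]],
    n_atoms: int,
    dedupe_hops: bool = False,
) -> KHopIndex:
    """Enumerate all directed simple paths of length 1, 2 and 3.

    Paths are extended breadth-first from every directed bond; atoms within a
    path are distinct.  Ordering is lexicographic by path tuple, so output is
    deterministic.
    """
    adj: list[set[int]] = [set() for _ in range(n_atoms)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    hops: dict[int, list[tuple[int, ...]]] = {1: [], 2: [], 3: []}
    for i in range(n_atoms):
        for j in adj[i]:
            hops[1].append((i, j))
    for k in (2, 3):
        for path in hops[k - 1]:
            tail = path[-1]
            used = set(path)
            for nxt in adj[tail]:
                if nxt not in used:
                    hops[k].append(path + (nxt,))

    if dedupe_hops:
        g = nx.Graph()
        g.add_nodes_from(range(n_atoms))
        g.add_edges_from(bonds)
        dist = dict(nx.all_pairs_shortest_path_length(g, cutoff=MAX_HOP))
        for k in (1, 2, 3):
            hops[k] = [p for p in hops[k] if dist.get(p[0], {}).get(p[-1], -1) == k]

    return KHopIndex(
        hop1=_as_paths_array(hops[1], 1),
        hop2=_as_paths_array(hops[2], 2),
        hop3=_as_paths_array(hops[3], 3),
    )


def enumerate_paths_oracle(bonds: list[tuple[int, int]], k: int) -> list[tuple[int, ...]]:
    """Exhaustive simple-path enumeration via networkx (independent oracle).

    Intended for small graphs; returns all directed simple paths with exactly
    ``k`` edges, sorted lexicographically.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k}")
    g = nx.Graph()
    g.add_edges_from(bonds)
    out = []
    for u in g.nodes:
        for v in g.nodes:
            if u == v:
                continue
            for path in nx.all_simple_paths(g, u, v, cutoff=k):
                if len(path) == k + 1:
                    out.append(tuple(path))
    return sorted(out)
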