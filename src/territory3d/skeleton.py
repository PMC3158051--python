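"""3D skeleton graphs of territory masks.

A mask is thinned to a one-voxel skeleton (Lee's algorithm via
``skimage.morphology.skeletonize``), turned into a graph whose nodes are
skeleton voxels connected under 26-connectivity with physical (µm) edge
weights, then condensed to a topological multigraph whose nodes are endpoints
and junctions and whose edges are branch paths.  Short terminal spurs — a
standard thinning artifact — are pruned before condensation.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from skimage.morphology import skeletonize

__all__ = ["skeleton_voxel_graph", "longest_geodesic_path", "BranchGraph",
           "branch_graph"]

DEFAULT_SPUR_LENGTH = 0.25  # µm


def skeleton_voxel_graph(mask: np.ndarray, voxel_size) -> nx.Graph:
    """Graph over skeleton voxels; nodes are (z, y, x) index tuples."""
    skel = skeletonize(mask)
    vs = np.asarray(voxel_size, dtype=float)
    idx = np.argwhere(skel)
    g = nx.Graph()
    if len(idx) == 0:
        return g
    voxset = set(map(tuple, idx))
    g.add_nodes_from(voxset)
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
    for v in voxset:
        for off in offsets:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if w in voxset:
                dist = float(np.linalg.norm(np.array(off) * vs))
                g.add_edge(v, w, weight=dist)
    _reduce_triangles(g)
    return g


def _reduce_triangles(g: nx.Graph) -> None:
    """Remove diagonal shortcut edges that close 3-cycles.

    Adjacent voxel triples on a thin chain form triangles under
    26-connectivity; the longest edge of each triangle is redundant (the
    two-step path remains) and would otherwise masquerade as a real cycle.
    """
    changed = True
    while changed:
        changed = False
        drop = set()
        for v in g.nodes:
            nbrs = sorted(g.neighbors(v))
            for i, a in enumerate(nbrs):
                for b in nbrs[i + 1:]:
                    if not g.has_edge(a, b):
                        continue
                    edges = [(g.edges[x, y]["weight"], (x, y))
                             for x, y in ((v, a), (v, b), (a, b))]
                    edges.sort(key=lambda e: (e[0], tuple(sorted(e[1]))))
                    drop.add(tuple(sorted(edges[-1][1])))
        live = {e for e in drop if g.has_edge(*e)}
        if live:
            # re-check one at a time: dropping one edge may fix several triangles
            for e in sorted(live):
                if not g.has_edge(*e):
                    continue
                a, b = e
                common = set(g.neighbors(a)) & set(g.neighbors(b))
                if common:
                    g.remove_edge(a, b)
                    changed = True


def _largest_component(g: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    return g.subgraph(comp)


def _farthest(g: nx.Graph, source) -> tuple[tuple, float, dict]:
    dist, paths = nx.single_source_dijkstra(g, source, weight="weight")
    # deterministic tie-break: smallest voxel index among farthest nodes
    far = max(dist.values())
    cands = sorted(n for n, d in dist.items() if d >= far - 1e-12)
    return cands[0], far, paths


def longest_geodesic_path(g: nx.Graph) -> list[tuple]:
    """Longest shortest path (graph diameter path) of the largest component.

    Double-sweep Dijkstra with lexicographic tie-breaking, exact for trees
    (skeletons of tubes are trees up to small cycles, where the double sweep
    is a standard, deterministic approximation).
    """
    if g.number_of_nodes() == 0:
        return []
    if g.number_of_nodes() == 1:
        return [next(iter(g.nodes))]
    sub = _largest_component(g)
    start = min(sub.nodes)
    a, _, _ = _farthest(sub, start)
    b, _, paths = _farthest(sub, a)
    return paths[b]


@dataclass
class Branch:
    """One condensed branch: an ordered voxel path between two graph nodes."""

    end_a: tuple
    end_b: tuple
    path: list[tuple]
    length: float  # µm


@dataclass
class BranchGraph:
    """Condensed skeleton topology."""

    branches: list[Branch]
    endpoints: list[tuple]  # degree-1 nodes
    junctions: list[tuple]  # degree>=3 nodes
    n_cycles: int
    total_length: float


def branch_graph(g: nx.Graph, spur_length: float = DEFAULT_SPUR_LENGTH,
                 rounds: int = 3) -> BranchGraph:
    """Condense a skeleton voxel graph, pruning short terminal spurs.

    Spur pruning repeats up to ``rounds`` times: a terminal branch shorter
    than ``spur_length`` that meets a junction is removed (its non-junction
    voxels deleted), then degree-2 chains are re-joined.
    """
    g = nx.Graph(g)
    for _ in range(rounds):
        branches = _condense(g)
        spurs = []
        degrees = dict(g.degree)
        for br in branches:
            da, db = degrees.get(br.end_a, 0), degrees.get(br.end_b, 0)
            terminal = (da == 1) != (db == 1)
            if terminal and br.length < spur_length and (da >= 3 or db >= 3):
                spurs.append(br)
        if not spurs:
            break
        for br in spurs:
            drop = [v for v in br.path
                    if g.has_node(v) and g.degree(v) <= 2 and
                    (v != br.end_a and v != br.end_b)]
            keep_end = br.end_a if g.degree(br.end_a) >= 3 else br.end_b
            lose_end = br.end_b if keep_end == br.end_a else br.end_a
            if g.has_node(lose_end) and g.degree(lose_end) <= 1:
                drop.append(lose_end)
            g.remove_nodes_from(drop)

    branches = _condense(g)
    endpoints = sorted(n for n, d in g.degree if d == 1)
    junctions = sorted(n for n, d in g.degree if d >= 3)
    n_nodes = g.number_of_nodes()
    n_edges = g.number_of_edges()
    n_comp = nx.number_connected_components(g) if n_nodes else 0
    n_cycles = n_edges - n_nodes + n_comp
    total = sum(b.length for b in branches)
    return BranchGraph(branches=branches, endpoints=endpoints,
                       junctions=junctions, n_cycles=n_cycles,
                       total_length=total)


def _condense(g: nx.Graph) -> list[Branch]:
    """Split the graph into maximal degree-2 paths between special nodes."""
    if g.number_of_nodes() == 0:
        return []
    degrees = dict(g.degree)
    special = {n for n, d in degrees.items() if d != 2}
    branches = []
    seen_edges = set()

    def walk(start, nxt):
        path = [start, nxt]
        length = g.edges[start, nxt]["weight"]
        prev, cur = start, nxt
        # stop at a special node or on closing a pure cycle back at the start
        while cur not in special and cur != start:
            nbrs = [n for n in g.neighbors(cur) if n != prev]
            if not nbrs:
                break
            nxt2 = nbrs[0]
            length += g.edges[cur, nxt2]["weight"]
            path.append(nxt2)
            prev, cur = cur, nxt2
        return path, length

    for s in sorted(special):
        for nbr in sorted(g.neighbors(s)):
            ekey = tuple(sorted((s, nbr)))
            if ekey in seen_edges:
                continue
            path, length = walk(s, nbr)
            for a, b in zip(path, path[1:]):
                seen_edges.add(tuple(sorted((a, b))))
            branches.append(Branch(end_a=path[0], end_b=path[-1],
                                   path=path, length=length))
    if not special:
        # pure cycle(s): pick an arbitrary node per cycle as the split point
        for comp in nx.connected_components(g):
            comp = sorted(comp)
            s = comp[0]
            nbrs = sorted(g.neighbors(s))
            if not nbrs:
                continue
            path, length = walk(s, nbrs[0])
            branches.append(Branch(end_a=path[0], end_b=path[-1],
                                   path=path, length=length))
    return branches
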