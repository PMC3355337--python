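"""Connectivity comparison via node coloring and core connectivity.

Each network is converted to a multigraph whose vertices are the network
nodes and whose edges are fibers.  Geometrically corresponding node
pairs across the two graphs receive a shared *color* (pairs closer than
sigma, matched greedily by ascending distance); unpaired vertices stay
uncolored (color -1).  Each edge carries the weight W(e) = |e| * M(e),
fiber length times mean geometric error, so shortest-path searches
prefer well-matched fibers.

The *core connectivity* of a colored graph keeps only the colored
vertices and connects them by minimum-weight paths whose interior
vertices are all uncolored.  Comparing the two core graphs by color pair
classifies every original edge as a true positive (on a matched core
path) or an error, yielding the connectivity rates
CFNR = FN / (FN + TP) and CFPR = FP / (FP + TP), where FN counts
uncolored ground-truth vertices plus ground-truth edges not used in any
matched connection (FP likewise on the test side).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geometry import GeometryResult, compute_metric
from .model import MetricConfig, Network

__all__ = [
    "ColoredGraph",
    "CoreGraph",
    "CoreEdge",
    "ConnectivityResult",
    "build_graph",
    "color_graphs",
    "assign_edge_weights",
    "core_connectivity",
    "compare_core_graphs",
    "connectivity_rates",
]


@dataclass
class GraphVertex:
    vertex_id: int
    position: np.ndarray
    color: int = -1


@dataclass
class GraphEdge:
    edge_id: int
    u: int
    v: int
    fiber_id: int
    length: float
    weight: float | None = None


@dataclass
class ColoredGraph:
    """Topological multigraph with vertex colors and edge weights."""

    vertices: dict[int, GraphVertex] = field(default_factory=dict)
    edges: dict[int, GraphEdge] = field(default_factory=dict)

    def colored_ids(self) -> list[int]:
        return sorted(v.vertex_id for v in self.vertices.values() if v.color >= 0)

    def uncolored_ids(self) -> list[int]:
        return sorted(v.vertex_id for v in self.vertices.values() if v.color < 0)

    def copy(self) -> "ColoredGraph":
        g = ColoredGraph()
        g.vertices = {
            k: GraphVertex(v.vertex_id, v.position.copy(), v.color)
            for k, v in self.vertices.items()
        }
        g.edges = {
            k: GraphEdge(e.edge_id, e.u, e.v, e.fiber_id, e.length, e.weight)
            for k, e in self.edges.items()
        }
        return g


@dataclass
class CoreEdge:
    """A core-graph connection between two colored vertices."""

    color_pair: tuple[int, int]  # sorted (c_min, c_max); equal for self-loops
    endpoints: tuple[int, int]  # vertex ids in the source graph
    path: tuple[int, ...]  # ordered original edge ids realizing the path
    weight: float


@dataclass
class CoreGraph:
    """Reduced graph over colored vertices with realizing paths."""

    vertex_colors: dict[int, int]  # colored vertex id -> color
    edges: list[CoreEdge]
    n_uncolored: int
    source_edge_ids: frozenset[int]


@dataclass
class ConnectivityResult:
    tp_gt: int
    fn: int
    tp_t: int
    fp: int
    cfnr: float
    cfpr: float
    uncolored_gt: int
    uncolored_t: int
    matched_core_pairs: list[tuple[CoreEdge, CoreEdge]]
    edge_class_gt: dict[int, str]  # fiber id -> "TP" | "FN"
    edge_class_t: dict[int, str]  # fiber id -> "TP" | "FP"
    colored_gt_ids: frozenset[int] = frozenset()  # detected GT vertex ids
    colored_t_ids: frozenset[int] = frozenset()  # detected test vertex ids

    def to_dict(self) -> dict:
        """JSON-serializable summary."""
        return {
            "tp_gt": self.tp_gt,
            "fn": self.fn,
            "tp_t": self.tp_t,
            "fp": self.fp,
            "cfnr": self.cfnr,
            "cfpr": self.cfpr,
            "uncolored_gt": self.uncolored_gt,
            "uncolored_t": self.uncolored_t,
            "matched_pairs": [
                {
                    "colors": list(g.color_pair),
                    "gt_path": list(g.path),
                    "test_path": list(t.path),
                }
                for g, t in self.matched_core_pairs
            ],
            "edge_class_gt": {str(k): v for k, v in sorted(self.edge_class_gt.items())},
            "edge_class_t": {str(k): v for k, v in sorted(self.edge_class_t.items())},
        }


def build_graph(network: Network) -> ColoredGraph:
    """One vertex per network node, one edge per fiber; colors unset (-1)."""
    g = ColoredGraph()
    for nid, pos in network.nodes.items():
        g.vertices[nid] = GraphVertex(nid, np.asarray(pos, dtype=float))
    for fid, fib in network.fibers.items():
        g.edges[fid] = GraphEdge(fid, fib.node_a, fib.node_b, fid, fib.length)
    return g


def color_graphs(g_gt: ColoredGraph, g_t: ColoredGraph, sigma: float) -> tuple[ColoredGraph, ColoredGraph]:
    """Pair geometrically corresponding vertices across the two graphs.

    Candidate pairs are all (GT vertex, test vertex) pairs closer than
    sigma; they are accepted greedily by ascending distance (ties broken
    by vertex ids), each vertex pairing at most once.  A paired GT vertex
    and its partner both receive the GT vertex id as color; everything
    else stays at -1.  The greedy order makes the pairing symmetric in
    the two arguments.
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    out_gt, out_t = g_gt.copy(), g_t.copy()
    for v in out_gt.vertices.values():
        v.color = -1
    for v in out_t.vertices.values():
        v.color = -1
    if not out_gt.vertices or not out_t.vertices:
        return out_gt, out_t
    gt_ids = sorted(out_gt.vertices)
    t_ids = sorted(out_t.vertices)
    gt_pos = np.array([out_gt.vertices[i].position for i in gt_ids])
    t_pos = np.array([out_t.vertices[i].position for i in t_ids])
    tree = cKDTree(t_pos)
    candidates: list[tuple[float, int, int]] = []
    for gi, neighbors in enumerate(cKDTree(gt_pos).query_ball_tree(tree, sigma)):
        for ti in neighbors:
            d = float(np.linalg.norm(gt_pos[gi] - t_pos[ti]))
            if d < sigma:  # strict: |v_i - v_j| < sigma
                candidates.append((d, gt_ids[gi], t_ids[ti]))
    candidates.sort()
    used_gt: set[int] = set()
    used_t: set[int] = set()
    for _d, gid, tid in candidates:
        if gid in used_gt or tid in used_t:
            continue
        used_gt.add(gid)
        used_t.add(tid)
        out_gt.vertices[gid].color = gid
        out_t.vertices[tid].color = gid
    return out_gt, out_t


def assign_edge_weights(graph: ColoredGraph, geometry: GeometryResult) -> ColoredGraph:
    """Set W(e) = |e| * M(e) from the per-fiber geometric scores."""
    out = graph.copy()
    for e in out.edges.values():
        if e.fiber_id not in geometry.per_fiber_M:
            raise ValueError(f"no geometry score for fiber {e.fiber_id}")
        e.weight = e.length * geometry.per_fiber_M[e.fiber_id]
    return out


def _adjacency(graph: ColoredGraph) -> dict[int, list[tuple[int, int, float]]]:
    adj: dict[int, list[tuple[int, int, float]]] = {v: [] for v in graph.vertices}
    for eid in sorted(graph.edges):
        e = graph.edges[eid]
        w = e.weight if e.weight is not None else 0.0
        adj[e.u].append((e.v, eid, w))
        if e.u != e.v:
            adj[e.v].append((e.u, eid, w))
    return adj


_SELF = -2  # sentinel target: the source vertex reached again through a cycle


def _search_from(v: int, adj, colors: dict[int, int]):
    """Bounded Dijkstra from colored vertex v through uncolored interiors.

    Returns {target vertex id: (weight, path edge ids)} for every colored
    vertex (v itself included, via cycles) reachable along paths whose
    interior vertices are all uncolored.  Ties in weight are broken by
    the lexicographically smallest edge-id sequence, making the search
    deterministic.
    """
    best: dict[int, tuple[float, tuple[int, ...]]] = {}
    settled: set[int] = set()
    heap: list[tuple[float, tuple[int, ...], int]] = []
    for nbr, eid, w in adj.get(v, []):
        tgt = _SELF if nbr == v else nbr
        heapq.heappush(heap, (w, (eid,), tgt))
    while heap:
        dist, path, node = heapq.heappop(heap)
        if node == _SELF or colors.get(node, -1) >= 0:
            key = v if node == _SELF else node
            if key not in best:
                best[key] = (dist, path)
            continue
        if node in settled:
            continue
        settled.add(node)
        for nbr, eid, w in adj.get(node, []):
            if eid in path:  # no edge reuse (self-loop back along same edge)
                continue
            tgt = _SELF if nbr == v else nbr
            if tgt != _SELF and tgt in settled:
                continue
            heapq.heappush(heap, (dist + w, path + (eid,), tgt))
    return best


def core_connectivity(graph: ColoredGraph) -> CoreGraph:
    """Reduce a colored, weighted graph to its core connectivity.

    Colored vertices are processed in ascending id order; each runs a
    weight-ordered shortest-path search bounded by colored vertices and
    emits one core edge per reachable colored neighbor (including itself,
    for cycles through uncolored mesh).  A processed vertex is then
    removed so the reverse connection is not emitted twice.
    """
    colors = {vid: vert.color for vid, vert in graph.vertices.items()}
    adj = _adjacency(graph)
    edges: list[CoreEdge] = []
    for v in graph.colored_ids():
        found = _search_from(v, adj, colors)
        for target in sorted(found):
            dist, path = found[target]
            cpair = tuple(sorted((colors[v], colors[target])))
            edges.append(CoreEdge(cpair, (v, target), path, dist))
        # mask v: remove it and its incident edges from the working graph
        for nbr, eid, w in adj.pop(v, []):
            if nbr != v:
                adj[nbr] = [t for t in adj[nbr] if t[1] != eid]
    return CoreGraph(
        vertex_colors={vid: c for vid, c in colors.items() if c >= 0},
        edges=edges,
        n_uncolored=sum(1 for c in colors.values() if c < 0),
        source_edge_ids=frozenset(graph.edges),
    )


def compare_core_graphs(core_gt: CoreGraph, core_t: CoreGraph) -> ConnectivityResult:
    """Match core edges by color pair and classify every original edge.

    Core edges with the same colored endpoint pair correspond; parallel
    core edges are matched greedily by ascending path weight.  Original
    edges on matched realizing paths are true positives (counted per
    side).  FN = uncolored GT vertices + GT edges not on any matched GT
    path; FP likewise for the test side.
    """
    for core in (core_gt, core_t):
        cols = list(core.vertex_colors.values())
        if len(cols) != len(set(cols)):
            raise ValueError("inconsistent coloring: duplicate colors within one graph")
    common = set(core_gt.vertex_colors.values()) & set(core_t.vertex_colors.values())
    only_gt = set(core_gt.vertex_colors.values()) - set(core_t.vertex_colors.values())
    if only_gt or (set(core_t.vertex_colors.values()) - common):
        raise ValueError("inconsistent coloring between the two core graphs")

    def by_pair(core: CoreGraph) -> dict[tuple[int, int], list[CoreEdge]]:
        groups: dict[tuple[int, int], list[CoreEdge]] = {}
        for e in core.edges:
            groups.setdefault(e.color_pair, []).append(e)
        for lst in groups.values():
            lst.sort(key=lambda e: (e.weight, e.path))
        return groups

    gt_groups, t_groups = by_pair(core_gt), by_pair(core_t)
    matched: list[tuple[CoreEdge, CoreEdge]] = []
    for pair in sorted(set(gt_groups) & set(t_groups)):
        for ge, te in zip(gt_groups[pair], t_groups[pair]):
            matched.append((ge, te))

    tp_edges_gt = {eid for ge, _ in matched for eid in ge.path}
    tp_edges_t = {eid for _, te in matched for eid in te.path}
    edge_class_gt = {
        eid: ("TP" if eid in tp_edges_gt else "FN") for eid in core_gt.source_edge_ids
    }
    edge_class_t = {
        eid: ("TP" if eid in tp_edges_t else "FP") for eid in core_t.source_edge_ids
    }
    tp_gt = len(tp_edges_gt)
    tp_t = len(tp_edges_t)
    fn = core_gt.n_uncolored + (len(core_gt.source_edge_ids) - tp_gt)
    fp = core_t.n_uncolored + (len(core_t.source_edge_ids) - tp_t)
    cfnr = fn / (fn + tp_gt) if fn + tp_gt > 0 else 0.0
    cfpr = fp / (fp + tp_t) if fp + tp_t > 0 else 0.0
    return ConnectivityResult(
        tp_gt=tp_gt,
        fn=fn,
        tp_t=tp_t,
        fp=fp,
        cfnr=float(cfnr),
        cfpr=float(cfpr),
        uncolored_gt=core_gt.n_uncolored,
        uncolored_t=core_t.n_uncolored,
        matched_core_pairs=matched,
        edge_class_gt=edge_class_gt,
        edge_class_t=edge_class_t,
        colored_gt_ids=frozenset(core_gt.vertex_colors),
        colored_t_ids=frozenset(core_t.vertex_colors),
    )


def connectivity_rates(gt: Network, test: Network, config: MetricConfig,
                       geo_gt: GeometryResult | None = None,
                       geo_t: GeometryResult | None = None) -> ConnectivityResult:
    """Full connectivity pipeline: build, color, weight, reduce, compare.

    ``geo_gt`` / ``geo_t`` are the geometric results of GT-vs-test and
    test-vs-GT; they are computed here when not supplied.
    """
    g_gt, g_t = color_graphs(build_graph(gt), build_graph(test), config.sigma)
    if gt.fibers and test.fibers:
        if geo_gt is None:
            geo_gt = compute_metric(gt, test, config)
        if geo_t is None:
            geo_t = compute_metric(test, gt, config)
        g_gt = assign_edge_weights(g_gt, geo_gt)
        g_t = assign_edge_weights(g_t, geo_t)
    return compare_core_graphs(core_connectivity(g_gt), core_connectivity(g_t))
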