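"""Graph coloring, core connectivity, and connectivity rate classification."""

import itertools

import numpy as np
import pytest

from fibermetrics.connectivity import (
    ColoredGraph,
    CoreEdge,
    CoreGraph,
    GraphEdge,
    GraphVertex,
    assign_edge_weights,
    build_graph,
    color_graphs,
    compare_core_graphs,
    connectivity_rates,
    core_connectivity,
)
from fibermetrics.geometry import compute_metric
from fibermetrics.model import MetricConfig
from fibermetrics.synthetic import generate_lattice_network, generate_tree, inject_errors

from conftest import make_network, straight_fiber_network


def graph_from(vertex_colors, edge_list):
    """ColoredGraph from {vid: color} and [(eid, u, v, weight), ...]."""
    g = ColoredGraph()
    for vid, color in vertex_colors.items():
        g.vertices[vid] = GraphVertex(vid, np.zeros(3), color)
    for eid, u, v, w in edge_list:
        g.edges[eid] = GraphEdge(eid, u, v, eid, length=1.0, weight=w)
    return g


class TestBuildGraph:
    def test_y_tree(self, y_tree):
        g = build_graph(y_tree)
        assert len(g.vertices) == 4
        assert len(g.edges) == 3
        assert all(v.color == -1 for v in g.vertices.values())

    def test_ring_is_one_self_loop(self):
        from fibermetrics.model import build_topology

        theta = np.linspace(0, 2 * np.pi, 30)
        ring = np.stack([10 * np.cos(theta), 10 * np.sin(theta), 0 * theta], axis=1)
        ring[-1] = ring[0]
        g = build_graph(build_topology([ring]))
        assert len(g.vertices) == 1
        assert len(g.edges) == 1
        (e,) = g.edges.values()
        assert e.u == e.v


class TestColoring:
    def _two_graphs(self, gt_pos, t_pos):
        def graph(positions):
            g = ColoredGraph()
            for i, p in enumerate(positions):
                g.vertices[i] = GraphVertex(i, np.asarray(p, dtype=float))
            return g

        return graph(gt_pos), graph(t_pos)

    def test_pair_within_sigma(self):
        gt, t = self._two_graphs([(0, 0, 0)], [(0.5, 0, 0)])
        cgt, ct = color_graphs(gt, t, sigma=1.0)
        assert cgt.vertices[0].color == ct.vertices[0].color == 0

    def test_no_pair_beyond_sigma(self):
        gt, t = self._two_graphs([(0, 0, 0)], [(2.0, 0, 0)])
        cgt, ct = color_graphs(gt, t, sigma=1.0)
        assert cgt.vertices[0].color == -1
        assert ct.vertices[0].color == -1

    def test_collision_resolved_by_distance(self):
        # two GT vertices nearest to one test vertex at 0.3 and 0.6 sigma:
        # the closer GT vertex wins, the farther stays uncolored
        gt, t = self._two_graphs([(0, 0, 0), (0.9, 0, 0)], [(0.3, 0, 0)])
        cgt, ct = color_graphs(gt, t, sigma=1.0)
        assert cgt.vertices[0].color == 0 and ct.vertices[0].color == 0
        assert cgt.vertices[1].color == -1

    def test_colors_bijective(self):
        rng = np.random.default_rng(0)
        gt, t = self._two_graphs(rng.uniform(0, 5, (12, 3)), rng.uniform(0, 5, (15, 3)))
        cgt, ct = color_graphs(gt, t, sigma=1.5)
        gt_cols = [v.color for v in cgt.vertices.values() if v.color >= 0]
        t_cols = [v.color for v in ct.vertices.values() if v.color >= 0]
        assert len(gt_cols) == len(set(gt_cols))
        assert sorted(gt_cols) == sorted(t_cols)

    @pytest.mark.parametrize("seed", range(5))
    def test_swap_symmetry_pairs_same_vertices(self, seed):
        """Swapping the arguments pairs exactly the same vertex sets."""
        rng = np.random.default_rng(seed)
        gt, t = self._two_graphs(rng.uniform(0, 6, (10, 3)), rng.uniform(0, 6, (12, 3)))
        cgt, ct = color_graphs(gt, t, sigma=2.0)
        ct2, cgt2 = color_graphs(t, gt, sigma=2.0)
        pairs_fwd = {(g, tt.color) for g, tt in
                     ((v.vertex_id, v) for v in cgt.vertices.values()) if tt.color >= 0}
        colored_fwd = {v.vertex_id for v in cgt.vertices.values() if v.color >= 0}
        colored_bwd = {v.vertex_id for v in cgt2.vertices.values() if v.color >= 0}
        assert colored_fwd == colored_bwd
        assert {v.vertex_id for v in ct.vertices.values() if v.color >= 0} == \
               {v.vertex_id for v in ct2.vertices.values() if v.color >= 0}


class TestEdgeWeights:
    def test_product_of_length_and_score(self, y_tree):
        other = generate_tree(1, seed=42)
        cfg = MetricConfig(sigma=1.0)
        geo = compute_metric(y_tree, other, cfg)
        g = assign_edge_weights(build_graph(y_tree), geo)
        for e in g.edges.values():
            expected = y_tree.fibers[e.fiber_id].length * geo.per_fiber_M[e.fiber_id]
            assert e.weight == pytest.approx(expected)
            assert e.weight >= 0

    def test_missing_score_raises(self, y_tree):
        cfg = MetricConfig(sigma=1.0)
        geo = compute_metric(y_tree, y_tree, cfg)
        geo.per_fiber_M.pop(0)
        with pytest.raises(ValueError, match="no geometry score"):
            assign_edge_weights(build_graph(y_tree), geo)


class TestCoreConnectivity:
    def test_all_colored_gives_original_graph(self):
        g = graph_from({0: 0, 1: 1, 2: 2, 3: 3},
                       [(0, 0, 1, 0.1), (1, 1, 2, 0.1), (2, 1, 3, 0.1)])
        core = core_connectivity(g)
        assert len(core.edges) == 3
        assert all(len(e.path) == 1 for e in core.edges)

    def test_chain_through_uncolored_interior(self):
        # a -- u -- b with u uncolored: single core edge with a 2-edge path
        g = graph_from({0: 0, 1: -1, 2: 2}, [(0, 0, 1, 0.5), (1, 1, 2, 0.5)])
        core = core_connectivity(g)
        assert len(core.edges) == 1
        e = core.edges[0]
        assert e.color_pair == (0, 2)
        assert e.path == (0, 1)
        assert e.weight == pytest.approx(1.0)

    def test_weight_guided_route_choice(self):
        # two uncolored routes join the same colored pair: lower-error wins
        g = graph_from(
            {0: 0, 1: -1, 2: -1, 3: 3},
            [(0, 0, 1, 0.1), (1, 1, 3, 0.1),  # cheap route
             (2, 0, 2, 0.5), (3, 2, 3, 0.5)],  # expensive route
        )
        core = core_connectivity(g)
        assert len(core.edges) == 1
        assert core.edges[0].path == (0, 1)

    def test_self_loop_cycle_through_uncolored_mesh(self):
        g = graph_from({0: 0, 1: -1}, [(0, 0, 1, 0.2), (1, 1, 0, 0.3)])
        core = core_connectivity(g)
        assert len(core.edges) == 1
        assert core.edges[0].color_pair == (0, 0)
        assert sorted(core.edges[0].path) == [0, 1]

    def test_no_path_through_colored_vertices(self):
        # a -- b -- c all colored: no core edge (a, c); only direct edges
        g = graph_from({0: 0, 1: 1, 2: 2}, [(0, 0, 1, 0.1), (1, 1, 2, 0.1)])
        core = core_connectivity(g)
        pairs = {e.color_pair for e in core.edges}
        assert pairs == {(0, 1), (1, 2)}

    def test_interior_vertices_always_uncolored(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = _random_colored_graph(rng)
            colors = {v: g.vertices[v].color for v in g.vertices}
            adj_ends = {eid: (e.u, e.v) for eid, e in g.edges.items()}
            for ce in core_connectivity(g).edges:
                interior = _path_interior(ce, adj_ends)
                assert all(colors[v] < 0 for v in interior)


def _path_interior(core_edge, ends):
    """Vertex sequence strictly between the endpoints of a realizing path."""
    cur = core_edge.endpoints[0]
    interior = []
    for eid in core_edge.path[:-1]:
        u, v = ends[eid]
        cur = v if u == cur else u
        interior.append(cur)
    return interior


def _random_colored_graph(rng, max_vertices=8):
    n = int(rng.integers(3, max_vertices + 1))
    k = int(rng.integers(1, min(n, 4) + 1))
    colors = {i: (i if i < k else -1) for i in range(n)}
    m = int(rng.integers(1, 11))
    edges = []
    for eid in range(m):
        u, v = int(rng.integers(n)), int(rng.integers(n))
        edges.append((eid, u, v, float(rng.uniform(0.1, 1.0))))
    return graph_from(colors, edges)


def _oracle_core(graph: ColoredGraph) -> CoreGraph:
    """Exhaustive enumeration of uncolored-interior simple paths.

    For every pair of colored vertices (including a vertex with itself,
    via simple cycles) keep the minimum-weight path.
    """
    colors = {v: graph.vertices[v].color for v in graph.vertices}
    adj = {}
    for eid, e in graph.edges.items():
        adj.setdefault(e.u, []).append((e.v, eid, e.weight))
        if e.u != e.v:
            adj.setdefault(e.v, []).append((e.u, eid, e.weight))
    colored = sorted(v for v, c in colors.items() if c >= 0)
    best: dict[tuple[int, int], tuple[float, tuple[int, ...]]] = {}
    second: dict[tuple[int, int], float] = {}

    def record(a, b, weight, path):
        key = (min(a, b), max(a, b))
        canon = (weight, tuple(path))
        if key not in best or canon < best[key]:
            if key in best:
                second[key] = min(second.get(key, np.inf), best[key][0])
            best[key] = canon
        else:
            second[key] = min(second.get(key, np.inf), weight)

    def dfs(start, cur, visited, used_edges, weight, path):
        for nbr, eid, w in adj.get(cur, []):
            if eid in used_edges:
                continue
            if colors.get(nbr, -1) >= 0:
                if nbr >= start:  # canonical direction; covers (start, start)
                    record(start, nbr, weight + w, path + [eid])
                continue
            if nbr in visited:
                continue
            dfs(start, nbr, visited | {nbr}, used_edges | {eid},
                weight + w, path + [eid])

    for v in colored:
        dfs(v, v, {v}, frozenset(), 0.0, [])
    edges = [
        CoreEdge((colors[a], colors[b]) if colors[a] <= colors[b] else (colors[b], colors[a]),
                 (a, b), path, w)
        for (a, b), (w, path) in sorted(best.items())
    ]
    ambiguous = any(
        np.isfinite(second.get(k, np.inf)) and second[k] - best[k][0] < 1e-9
        for k in best
    )
    core = CoreGraph(
        vertex_colors={v: colors[v] for v in colored},
        edges=edges,
        n_uncolored=sum(1 for c in colors.values() if c < 0),
        source_edge_ids=frozenset(graph.edges),
    )
    return core, ambiguous


class TestCoreOracleEquivalence:
    def test_matches_exhaustive_enumeration(self):
        """Core connectivity equals brute-force minimum-weight simple paths
        on random graphs with <= 8 vertices (continuous weights, no ties)."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            g = _random_colored_graph(rng)
            oracle, ambiguous = _oracle_core(g)
            if ambiguous:
                continue
            core = core_connectivity(g)
            got = {(e.color_pair, round(e.weight, 9), tuple(sorted(e.path)))
                   for e in core.edges}
            want = {(e.color_pair, round(e.weight, 9), tuple(sorted(e.path)))
                    for e in oracle.edges}
            assert got == want
            checked += 1

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(7)
        graphs = [_random_colored_graph(rng) for _ in range(20)]
        for g in graphs:
            a = core_connectivity(g)
            b = core_connectivity(g.copy())
            assert [(e.color_pair, e.path, e.weight) for e in a.edges] == \
                   [(e.color_pair, e.path, e.weight) for e in b.edges]


class TestCompareCoreGraphs:
    def test_identical_fully_colored_graphs_zero_rates(self):
        g = graph_from({0: 0, 1: 1, 2: 2, 3: 3},
                       [(0, 0, 1, 0.1), (1, 1, 2, 0.1), (2, 2, 3, 0.1)])
        res = compare_core_graphs(core_connectivity(g), core_connectivity(g.copy()))
        assert (res.fn, res.fp) == (0, 0)
        assert (res.cfnr, res.cfpr) == (0.0, 0.0)
        assert res.tp_gt == res.tp_t == 3

    def test_uncolored_vertex_counts_on_both_sides(self):
        # identical structure, but an undetected (uncolored) interior vertex
        # contributes one FN and one FP by definition; edges all match
        g = graph_from({0: 0, 1: 1, 2: -1, 3: 3},
                       [(0, 0, 1, 0.1), (1, 1, 2, 0.1), (2, 2, 3, 0.1)])
        res = compare_core_graphs(core_connectivity(g), core_connectivity(g.copy()))
        assert (res.fn, res.fp) == (1, 1)
        assert res.tp_gt == res.tp_t == 3
        assert res.edge_class_gt == {0: "TP", 1: "TP", 2: "TP"}

    def test_gap_worked_example(self):
        """GT edge a-b; test has a-c and d-b with an uncolored gap: the GT
        connection is missed entirely (cfnr = 1) and the whole test side is
        unusable (fp = 2 uncolored vertices + 2 unused edges = 4)."""
        gt = graph_from({0: 0, 1: 1}, [(0, 0, 1, 0.0)])
        test = graph_from({10: 0, 11: -1, 12: -1, 13: 1},
                          [(0, 10, 11, 0.0), (1, 12, 13, 0.0)])
        res = compare_core_graphs(core_connectivity(gt), core_connectivity(test))
        assert res.fn == 1 and res.tp_gt == 0 and res.cfnr == 1.0
        assert res.fp == 4 and res.tp_t == 0 and res.cfpr == 1.0

    def test_missing_branch_worked_example(self):
        """GT Y-tree missing one tip in the test: junction dissolves, so FN =
        2 uncolored vertices + 1 unmatched edge over 5, i.e. cfnr = 3/5."""
        # GT: root 0 - junction 1 - tips 2, 3 (junction/tip unpaired in test)
        gt = graph_from({0: 0, 1: -1, 2: 2, 3: -1},
                        [(0, 0, 1, 0.0), (1, 1, 2, 0.0), (2, 1, 3, 0.9)])
        # test: single merged fiber root - tip
        test = graph_from({10: 0, 11: 2}, [(0, 10, 11, 0.0)])
        res = compare_core_graphs(core_connectivity(gt), core_connectivity(test))
        assert res.fn == 3 and res.tp_gt == 2
        assert res.cfnr == pytest.approx(3 / 5)
        assert (res.fp, res.cfpr) == (0, 0.0)

    def test_duplicate_parallel_edge(self):
        gt = graph_from({0: 0, 1: 1}, [(0, 0, 1, 0.0)])
        test = graph_from({10: 0, 11: 1}, [(0, 10, 11, 0.0), (1, 10, 11, 0.7)])
        res = compare_core_graphs(core_connectivity(gt), core_connectivity(test))
        assert res.fp == 1 and res.tp_t == 1
        assert res.edge_class_t == {0: "TP", 1: "FP"}
        assert res.cfpr == pytest.approx(0.5)

    def test_inconsistent_coloring_rejected(self):
        gt = graph_from({0: 0}, [])
        test = graph_from({10: 5}, [])
        with pytest.raises(ValueError, match="coloring"):
            compare_core_graphs(core_connectivity(gt), core_connectivity(test))

    def test_every_edge_classified_once(self):
        rng = np.random.default_rng(11)
        g1 = _random_colored_graph(rng)
        g2 = _random_colored_graph(rng)
        common = set(v.color for v in g1.vertices.values() if v.color >= 0) & \
                 set(v.color for v in g2.vertices.values() if v.color >= 0)
        for g in (g1, g2):
            for v in g.vertices.values():
                if v.color >= 0 and v.color not in common:
                    v.color = -1
        res = compare_core_graphs(core_connectivity(g1), core_connectivity(g2))
        assert set(res.edge_class_gt) == set(g1.edges)
        assert set(res.edge_class_t) == set(g2.edges)
        assert res.tp_gt + (res.fn - res.uncolored_gt) == len(g1.edges)
        assert res.tp_t + (res.fp - res.uncolored_t) == len(g2.edges)


class TestConnectivityRates:
    def test_self_comparison_zero(self):
        for net in (generate_tree(3, seed=1), generate_lattice_network(3, 2, 2, seed=1)):
            res = connectivity_rates(net, net, MetricConfig(sigma=1.0))
            assert (res.cfnr, res.cfpr) == (0.0, 0.0)
            assert res.fn == res.fp == 0

    def test_swap_exchanges_rates(self):
        gt = generate_tree(3, seed=4)
        test, _ = inject_errors(gt, [{"kind": "gap", "width": 2.0},
                                     {"kind": "spur", "length": 5.0}], seed=5)
        cfg = MetricConfig(sigma=1.0)
        res = connectivity_rates(gt, test, cfg)
        swapped = connectivity_rates(test, gt, cfg)
        assert (res.cfnr, res.cfpr) == (swapped.cfpr, swapped.cfnr)
        assert (res.fn, res.fp) == (swapped.fp, swapped.fn)

    def test_spur_counts(self):
        gt = generate_tree(2, seed=6)
        test, ledger = inject_errors(gt, [{"kind": "spur", "length": 5.0}], seed=7)
        res = connectivity_rates(gt, test, MetricConfig(sigma=1.0))
        assert res.fp == ledger.entries[0].expected["fp"] == 3
        assert res.fn == 0
        assert res.tp_gt == gt.n_fibers

    def test_vertex_conservation(self):
        gt = generate_tree(3, seed=8)
        test, _ = inject_errors(gt, [{"kind": "missing_fiber"}], seed=9)
        res = connectivity_rates(gt, test, MetricConfig(sigma=1.0))
        assert len(res.colored_gt_ids) + res.uncolored_gt == gt.n_nodes
        assert len(res.colored_t_ids) + res.uncolored_t == test.n_nodes
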