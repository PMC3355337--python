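"""Core network model: nodes, fibers, and topology construction.

A fiber network is modelled as a geometric multigraph.  *Nodes* are
junctions (degree != 2 in the skeleton) or fiber endpoints; each *fiber*
is a 3D polyline joining two nodes (possibly the same node, for a closed
loop).  Interior polyline vertices carry the fiber's geometric shape and,
optionally, a per-point radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Fiber", "Network", "MetricConfig", "build_topology"]

#: tolerance for "polyline endpoint coincides with node position"
ENDPOINT_TOL = 1e-9


@dataclass
class Fiber:
    """A single fiber: polyline geometry plus its two graph endpoints."""

    fiber_id: int
    node_a: int
    node_b: int
    points: np.ndarray  # (k, 3) float64, k >= 2
    radii: np.ndarray | None = None  # (k,) float64 or None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("fiber polyline must be an (k>=2, 3) array")
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=float)
            if self.radii.shape != (len(self.points),):
                raise ValueError("radii must have one value per polyline point")

    @property
    def length(self) -> float:
        """Arc length of the polyline."""
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each polyline vertex (starts at 0)."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def reversed(self) -> "Fiber":
        return replace(
            self,
            node_a=self.node_b,
            node_b=self.node_a,
            points=self.points[::-1].copy(),
            radii=None if self.radii is None else self.radii[::-1].copy(),
        )


@dataclass
class Network:
    """Geometric multigraph of fibers.

    ``nodes`` maps node id -> 3D position; ``fibers`` maps fiber id ->
    :class:`Fiber`.  Self-loops (closed-loop fibers) and parallel fibers
    between the same node pair are permitted.
    """

    nodes: dict[int, np.ndarray] = field(default_factory=dict)
    fibers: dict[int, Fiber] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_fibers(self) -> int:
        return len(self.fibers)

    def is_empty(self) -> bool:
        return not self.fibers and not self.nodes

    def total_length(self) -> float:
        """L: total arc length over all fibers."""
        return float(sum(f.length for f in self.fibers.values()))

    def mean_radius(self) -> float | None:
        """Mean of all per-point radii, or None if no fiber carries radii."""
        vals = [f.radii for f in self.fibers.values() if f.radii is not None]
        if not vals:
            return None
        return float(np.mean(np.concatenate(vals)))

    def segments(self) -> list[tuple[np.ndarray, np.ndarray | None]]:
        """Raw (points, radii) polylines, suitable for :func:`build_topology`."""
        return [
            (f.points.copy(), None if f.radii is None else f.radii.copy())
            for _, f in sorted(self.fibers.items())
        ]

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        referenced: set[int] = set()
        for fid, fib in self.fibers.items():
            for nid, pt in ((fib.node_a, fib.points[0]), (fib.node_b, fib.points[-1])):
                if nid not in self.nodes:
                    raise ValueError(f"fiber {fid} references missing node {nid}")
                if np.linalg.norm(self.nodes[nid] - pt) > ENDPOINT_TOL:
                    raise ValueError(
                        f"fiber {fid} endpoint does not coincide with node {nid}"
                    )
            referenced.update((fib.node_a, fib.node_b))
        orphans = set(self.nodes) - referenced
        if orphans:
            raise ValueError(f"orphan nodes not referenced by any fiber: {sorted(orphans)}")
        if self.fibers and not self.total_length() > 0:
            raise ValueError("non-empty network must have positive total length")

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "Network":
        """Apply a rigid transform (rotation then translation) to a copy."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out = Network()
        out.nodes = {nid: R @ pos + t for nid, pos in self.nodes.items()}
        out.fibers = {
            fid: replace(f, points=f.points @ R.T + t) for fid, f in self.fibers.items()
        }
        return out


@dataclass
class MetricConfig:
    """Parameters of the comparison.

    sigma : float
        Standard deviation of the Gaussian envelope, in model units.
        Conventionally set to the mean fiber radius.
    epsilon : float
        Dimensionless sampling accuracy in (0, 1]; samples are spaced at
        most ``epsilon * sigma`` apart.
    sampling_mode : {"grid", "regular"}
        Grid-boundary-crossing sampling on a common uniform grid (tighter
        error bound) or regular arc-length resampling.
    grid_origin : 3-tuple
        Origin of the common sampling grid (grid mode only).
    """

    sigma: float
    epsilon: float = 0.1
    sampling_mode: str = "grid"
    grid_origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must be in (0, 1]")
        if self.sampling_mode not in ("grid", "regular"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")

    @property
    def spacing(self) -> float:
        """Sample spacing / grid cell size, epsilon * sigma."""
        return self.epsilon * self.sigma


# ---------------------------------------------------------------------------
# topology construction


def _weld_endpoints(segments, tol: float):
    """Map each segment endpoint to a welded vertex id; return (ids, positions)."""
    n = len(segments)
    pts = np.empty((2 * n, 3))
    for i, (p, _r) in enumerate(segments):
        pts[2 * i] = p[0]
        pts[2 * i + 1] = p[-1]
    if tol > 0:
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial import cKDTree

        # union-find over endpoint pairs closer than tol
        parent = list(range(2 * n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        tree = cKDTree(pts)
        for i, j in tree.query_pairs(tol):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
        labels = [find(i) for i in range(2 * n)]
    else:
        seen: dict[bytes, int] = {}
        labels = []
        for i in range(2 * n):
            key = pts[i].tobytes()
            labels.append(seen.setdefault(key, i))
    remap: dict[int, int] = {}
    positions: list[np.ndarray] = []
    out = []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(positions)
            positions.append(pts[lab])
        out.append(remap[lab])
    return out, positions


def _concat_chain(parts):
    """Concatenate oriented (points, radii) parts, dropping duplicated joints."""
    pts = [parts[0][0]]
    radii = [parts[0][1]]
    for p, r in parts[1:]:
        pts.append(p[1:])
        radii.append(None if r is None else r[1:])
    points = np.concatenate(pts, axis=0)
    if any(r is None for r in radii):
        rad = None
    else:
        rad = np.concatenate(radii)
    return points, rad


def build_topology(segments, weld_tol: float = 0.0) -> Network:
    """Assemble a :class:`Network` from raw polyline segments.

    Endpoints within ``weld_tol`` (exact match when 0) are merged into
    common vertices.  Welded vertices of degree != 2 become network nodes;
    chains of segments running through degree-2 vertices are merged into
    single fibers.  A pure cycle with no junction collapses to one node at
    its canonical first vertex plus one self-loop fiber — except for a
    two-segment cycle between two vertices, which is kept as a parallel
    fiber pair (two distinct polylines drawn between the same endpoints
    encode two fibers, not one ring).
    """
    norm = []
    for s in segments:
        p, r = s if isinstance(s, tuple) else (s, None)
        norm.append(
            (np.asarray(p, dtype=float), None if r is None else np.asarray(r, dtype=float))
        )
    segments = norm
    for p, _ in segments:
        if p.ndim != 2 or p.shape[1] != 3 or len(p) < 2:
            raise ValueError("each segment must be an (k>=2, 3) polyline")
    net = Network()
    if not segments:
        return net

    vert_of_end, positions = _weld_endpoints(segments, weld_tol)
    nseg = len(segments)
    # incidence: vertex -> list of (segment index, end flag 0=start 1=stop)
    incident: dict[int, list[tuple[int, int]]] = {}
    for si in range(nseg):
        incident.setdefault(vert_of_end[2 * si], []).append((si, 0))
        incident.setdefault(vert_of_end[2 * si + 1], []).append((si, 1))
    degree = {v: len(ends) for v, ends in incident.items()}

    node_id_of_vertex: dict[int, int] = {}

    def node_for(vertex: int) -> int:
        if vertex not in node_id_of_vertex:
            nid = len(node_id_of_vertex)
            node_id_of_vertex[vertex] = nid
            net.nodes[nid] = positions[vertex].copy()
        return node_id_of_vertex[vertex]

    def oriented(si: int, entering_end: int):
        p, r = segments[si]
        if entering_end == 0:
            return p, r
        return p[::-1].copy(), None if r is None else r[::-1].copy()

    used = [False] * nseg
    next_fid = 0
    anchors = sorted(v for v, d in degree.items() if d != 2)

    def other_vertex(si: int, end: int) -> int:
        return vert_of_end[2 * si + (1 - end)]

    for v in anchors:
        for si, end in incident[v]:
            if used[si]:
                continue
            # walk the chain from anchor v through degree-2 vertices
            parts = [oriented(si, end)]
            used[si] = True
            cur = other_vertex(si, end)
            while degree[cur] == 2 and cur not in node_id_of_vertex and cur != v:
                nxt = [(sj, e) for sj, e in incident[cur] if not used[sj]]
                if not nxt:
                    break  # closed back onto an already-used chain
                sj, e = nxt[0]
                used[sj] = True
                parts.append(oriented(sj, e))
                cur = other_vertex(sj, e)
                if degree.get(cur) != 2:
                    break
            pts, rad = _concat_chain(parts)
            a, b = node_for(v), node_for(cur)
            net.fibers[next_fid] = Fiber(next_fid, a, b, pts, rad)
            next_fid += 1

    # leftover segments form pure cycles (every vertex degree 2)
    remaining = [si for si in range(nseg) if not used[si]]
    comp_of: dict[int, list[int]] = {}
    for si in remaining:
        root = min(vert_of_end[2 * si], vert_of_end[2 * si + 1])
        comp_of.setdefault(root, []).append(si)
    # merge components that share vertices
    vert_comp: dict[int, int] = {}
    comps: list[list[int]] = []
    for si in remaining:
        va, vb = vert_of_end[2 * si], vert_of_end[2 * si + 1]
        ca, cb = vert_comp.get(va), vert_comp.get(vb)
        if ca is None and cb is None:
            cid = len(comps)
            comps.append([si])
            vert_comp[va] = vert_comp[vb] = cid
        elif ca is None or cb is None:
            cid = ca if ca is not None else cb
            comps[cid].append(si)
            vert_comp[va] = vert_comp[vb] = cid
        elif ca == cb:
            comps[ca].append(si)
        else:  # merge two components
            keep, drop = min(ca, cb), max(ca, cb)
            comps[keep].extend(comps[drop])
            for vv, cc in list(vert_comp.items()):
                if cc == drop:
                    vert_comp[vv] = keep
            comps[drop] = []

    for comp in comps:
        if not comp:
            continue
        comp = sorted(comp)
        verts = {vert_of_end[2 * si] for si in comp} | {
            vert_of_end[2 * si + 1] for si in comp
        }
        if len(comp) == 2 and len(verts) == 2:
            # parallel pair: two distinct polylines between the same endpoints
            for si in comp:
                a = node_for(vert_of_end[2 * si])
                b = node_for(vert_of_end[2 * si + 1])
                p, r = segments[si]
                net.fibers[next_fid] = Fiber(next_fid, a, b, p.copy(), r)
                next_fid += 1
            continue
        # walk the cycle starting at the first segment's start vertex
        start = vert_of_end[2 * comp[0]]
        parts = [oriented(comp[0], 0)]
        used[comp[0]] = True
        cur = other_vertex(comp[0], 0)
        while cur != start:
            nxt = [(sj, e) for sj, e in incident[cur] if not used[sj]]
            sj, e = nxt[0]
            used[sj] = True
            parts.append(oriented(sj, e))
            cur = other_vertex(sj, e)
        pts, rad = _concat_chain(parts)
        a = node_for(start)
        net.fibers[next_fid] = Fiber(next_fid, a, a, pts, rad)
        next_fid += 1

    net.validate()
    return net
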