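"""Readers and writers for network model files (SWC and polyline OBJ).

SWC is the 7-column whitespace format for traced neuron morphologies
(``id type x y z radius parent``, '#' comments, parent -1 for a root);
it encodes rooted trees/forests only.  OBJ polyline files (``v`` vertex
and ``l`` line elements, 1-based indices) can additionally encode closed
loops and interconnected networks.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .model import Network, build_topology

__all__ = ["read_swc", "write_swc", "read_obj", "write_network_obj", "load_network"]


class ParseError(ValueError):
    """Malformed record in a network model file."""


class StructureError(ValueError):
    """Structurally invalid network description (bad parent links, loops)."""


def read_swc(path) -> Network:
    """Read an SWC morphology into a :class:`Network`.

    SWC samples with degree != 2 in the sample graph (roots, tips and
    branch points) become network nodes; maximal chains of degree-2
    samples collapse into single fibers with per-point radii preserved.
    Forests (multiple roots) are accepted; parent links must refer to
    previously listed samples, which also rules out cycles.
    """
    samples: dict[int, tuple[np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 7:
                raise ParseError(f"{path}: line {lineno}: expected 7 fields, got {len(fields)}")
            try:
                sid = int(fields[0])
                xyz = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
                radius = float(fields[5])
                parent = int(fields[6])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            if sid in samples:
                raise StructureError(f"{path}: line {lineno}: duplicate sample id {sid}")
            if parent != -1 and parent not in samples:
                raise StructureError(
                    f"{path}: line {lineno}: parent {parent} of sample {sid} "
                    "does not exist or has not been seen yet"
                )
            samples[sid] = (xyz, radius, parent)
            order.append(sid)

    segments = []
    for sid in order:
        xyz, radius, parent = samples[sid]
        if parent == -1:
            continue
        pxyz, pradius, _ = samples[parent]
        if np.array_equal(pxyz, xyz):
            continue  # degenerate zero-length link (duplicated sample position)
        segments.append(
            (np.array([pxyz, xyz]), np.array([pradius, radius]))
        )
    net = build_topology(segments)
    # isolated samples (no parent, never referenced as one) become bare nodes
    referenced = {samples[s][2] for s in order}
    next_nid = max(net.nodes, default=-1) + 1
    for sid in order:
        xyz, _, parent = samples[sid]
        if parent == -1 and sid not in referenced:
            net.nodes[next_nid] = xyz
            next_nid += 1
    return net


def write_swc(network: Network, path) -> None:
    """Write a tree-like (acyclic) network as SWC.

    Raises :class:`StructureError` for networks with loops, which SWC
    cannot encode.
    """
    import networkx as nx

    g = nx.MultiGraph()
    g.add_nodes_from(network.nodes)
    for fid, fib in network.fibers.items():
        g.add_edge(fib.node_a, fib.node_b, key=fid)
    if g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g) != 0:
        raise StructureError("network contains loops; SWC cannot encode them")

    lines = ["# generated by fibermetrics"]
    sid = 0
    sample_of_node: dict[int, int] = {}

    def emit(pos, radius, parent) -> int:
        nonlocal sid
        sid += 1
        r = 1.0 if radius is None or not np.isfinite(radius) else float(radius)
        lines.append(
            f"{sid} 3 {pos[0]:.9g} {pos[1]:.9g} {pos[2]:.9g} {r:.9g} {parent}"
        )
        return sid

    visited_fibers: set[int] = set()
    for root in sorted(network.nodes):
        if root in sample_of_node:
            continue
        sample_of_node[root] = emit(network.nodes[root], _node_radius(network, root), -1)
        stack = [root]
        while stack:
            nid = stack.pop()
            for fid, fib in sorted(network.fibers.items()):
                if fid in visited_fibers:
                    continue
                if fib.node_a == nid or fib.node_b == nid:
                    visited_fibers.add(fid)
                    f = fib if fib.node_a == nid else fib.reversed()
                    parent = sample_of_node[nid]
                    prev = f.points[0]
                    for i in range(1, len(f.points)):
                        if i < len(f.points) - 1 and np.allclose(f.points[i], prev):
                            continue  # skip degenerate zero-length steps
                        r = None if f.radii is None else f.radii[i]
                        parent = emit(f.points[i], r, parent)
                        prev = f.points[i]
                    sample_of_node[f.node_b] = parent
                    stack.append(f.node_b)
    Path(path).write_text("\n".join(lines) + "\n")


def _node_radius(network: Network, nid: int) -> float | None:
    for fib in network.fibers.values():
        if fib.radii is None:
            continue
        if fib.node_a == nid:
            return float(fib.radii[0])
        if fib.node_b == nid:
            return float(fib.radii[-1])
    return None


def read_obj(path, weld_tol: float = 0.0) -> Network:
    """Read a polyline OBJ file into a :class:`Network`.

    ``v`` records define vertices and each ``l`` record one polyline
    (1-based vertex indices; ``v/vt`` references accepted, the texture
    coordinate part is ignored).  Face records are skipped with a
    warning.  Shared endpoint vertices are welded into common nodes and
    chains merged by :func:`fibermetrics.model.build_topology`; closed
    loops are permitted.
    """
    verts: list[np.ndarray] = []
    polylines: list[list[int]] = []
    saw_faces = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tag, *rest = line.split()
            if tag == "v":
                if len(rest) < 3:
                    raise ParseError(f"{path}: line {lineno}: vertex needs 3 coordinates")
                try:
                    verts.append(np.array([float(v) for v in rest[:3]]))
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from None
            elif tag == "l":
                if len(rest) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: polyline needs at least 2 vertex indices"
                    )
                idx = []
                for tok in rest:
                    try:
                        i = int(tok.split("/")[0])
                    except ValueError as exc:
                        raise ParseError(f"{path}: line {lineno}: {exc}") from None
                    if i < 1 or i > len(verts):
                        raise ParseError(
                            f"{path}: line {lineno}: vertex index {i} out of range "
                            "(OBJ indices are 1-based)"
                        )
                    idx.append(i - 1)
                polylines.append(idx)
            elif tag == "f":
                saw_faces = True
    if saw_faces:
        warnings.warn(f"{path}: face elements ignored", stacklevel=2)
    segments = [np.array([verts[i] for i in poly]) for poly in polylines]
    return build_topology(segments, weld_tol=weld_tol)


def write_network_obj(network: Network, path, per_point_scalar=None) -> None:
    """Write the network's fiber polylines as an OBJ file.

    ``per_point_scalar``, if given, must hold one value in [0, 1] per
    polyline point (concatenated over fibers in ascending fiber id) and
    is emitted as ``vt s 0`` texture coordinates paired with each vertex.
    """
    n_points = sum(len(f.points) for f in network.fibers.values())
    scalars = None
    if per_point_scalar is not None:
        scalars = np.asarray(per_point_scalar, dtype=float)
        if scalars.shape != (n_points,):
            raise ValueError(
                f"per_point_scalar has {scalars.shape} values, expected ({n_points},)"
            )
    lines = ["# fibermetrics network export"]
    index: list[list[int]] = []
    vi = 0
    si = 0
    for fid, fib in sorted(network.fibers.items()):
        ids = []
        for p in fib.points:
            lines.append(f"v {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}")
            if scalars is not None:
                lines.append(f"vt {scalars[si]:.9g} 0")
                si += 1
            vi += 1
            ids.append(vi)
        index.append(ids)
    for ids in index:
        if scalars is not None:
            lines.append("l " + " ".join(f"{i}/{i}" for i in ids))
        else:
            lines.append("l " + " ".join(str(i) for i in ids))
    Path(path).write_text("\n".join(lines) + "\n")


def load_network(path) -> Network:
    """Load a network, inferring the format from the file extension."""
    suffix = Path(path).suffix.lower()
    if suffix == ".swc":
        return read_swc(path)
    if suffix == ".obj":
        return read_obj(path)
    raise ValueError(f"unsupported network format: {suffix!r} (expected .swc or .obj)")
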