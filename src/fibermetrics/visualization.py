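"""Colormapped export of comparison results to static geometry files.

Per-point geometric error weights are pushed through one of four
colormaps (diverging blue-red by default) onto the fiber polylines and
written as ASCII PLY line geometry with per-vertex RGB.  Connectivity
results are exported as node markers (red = undetected, gray =
detected) plus edges colored by matched-pair palette index, with
unmatched edges in a neutral color.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .connectivity import ConnectivityResult
from .geometry import GeometryResult
from .model import Network

__all__ = [
    "Colormap",
    "get_colormap",
    "apply_colormap",
    "diverging_inverse",
    "export_comparison",
    "write_ply_lines",
    "read_ply_lines",
]

# diverging map control points: blue -> desaturated light gray -> red.
# chosen so that (red - blue + 1) / 2 recovers the scalar exactly, which
# makes exported colors invertible back to weights (up to 8-bit rounding)
_DIV_LO = np.array([0.0, 0.0, 1.0])
_DIV_MID = np.array([0.85, 0.85, 0.85])
_DIV_HI = np.array([1.0, 0.0, 0.0])

# isoluminant endpoints (approx. equal Rec.709 luminance ~0.50)
_ISO_LO = np.array([0.23, 0.55, 0.75])
_ISO_HI = np.array([0.75, 0.452, 0.20])


def _lerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    return a[None, :] * (1.0 - t[:, None]) + b[None, :] * t[:, None]


def _diverging(v: np.ndarray) -> np.ndarray:
    lo = _lerp(_DIV_LO, _DIV_MID, 2.0 * v)
    hi = _lerp(_DIV_MID, _DIV_HI, 2.0 * v - 1.0)
    return np.where((v < 0.5)[:, None], lo, hi)


def _rainbow(v: np.ndarray) -> np.ndarray:
    """Hue sweep blue (240 deg) -> red (0 deg), full saturation and value."""
    h = (1.0 - v) * (240.0 / 360.0) * 6.0
    i = np.floor(h)
    f = h - i
    rgb = np.empty((len(v), 3))
    for k, (r, g, b) in enumerate([(1, "f", 0), ("1-f", 1, 0), (0, 1, "f"), (0, "1-f", 1), ("f", 0, 1), (1, 0, "1-f")]):
        mask = np.minimum(i, 5) == k
        for c, spec in enumerate((r, g, b)):
            if spec == "f":
                rgb[mask, c] = f[mask]
            elif spec == "1-f":
                rgb[mask, c] = 1.0 - f[mask]
            else:
                rgb[mask, c] = spec
    return rgb


def _blackbody(v: np.ndarray) -> np.ndarray:
    """Heated-body ramp: black -> red -> yellow -> white."""
    r = np.clip(3.0 * v, 0.0, 1.0)
    g = np.clip(3.0 * v - 1.0, 0.0, 1.0)
    b = np.clip(3.0 * v - 2.0, 0.0, 1.0)
    return np.stack([r, g, b], axis=1)


def _isoluminant(v: np.ndarray) -> np.ndarray:
    return _lerp(_ISO_LO, _ISO_HI, v)


@dataclass(frozen=True)
class Colormap:
    """A named, continuous map from [0, 1] scalars to RGB in [0, 1]^3."""

    name: str

    def lookup(self, values) -> np.ndarray:
        v = np.clip(np.atleast_1d(np.asarray(values, dtype=float)), 0.0, 1.0)
        return _TABLES[self.name](v)

    def __call__(self, values) -> np.ndarray:
        return self.lookup(values)


_TABLES = {
    "diverging": _diverging,
    "rainbow": _rainbow,
    "blackbody": _blackbody,
    "isoluminant": _isoluminant,
}


def get_colormap(name: str) -> Colormap:
    if name not in _TABLES:
        raise ValueError(
            f"unknown colormap {name!r}; choose from {sorted(_TABLES)}"
        )
    return Colormap(name)


def apply_colormap(values, cmap: Colormap | str) -> np.ndarray:
    """Elementwise colormap lookup on values clipped to [0, 1]."""
    if isinstance(cmap, str):
        cmap = get_colormap(cmap)
    return cmap.lookup(values)


def diverging_inverse(rgb: np.ndarray) -> np.ndarray:
    """Recover scalars from diverging-map colors via the monotone r-b channel."""
    rgb = np.atleast_2d(np.asarray(rgb, dtype=float))
    return np.clip((rgb[:, 0] - rgb[:, 2] + 1.0) / 2.0, 0.0, 1.0)


# ---------------------------------------------------------------------------
# PLY export


def write_ply_lines(path, vertices: np.ndarray, colors: np.ndarray,
                    edges: np.ndarray, comments=()) -> None:
    """ASCII PLY with colored vertices and line (edge) elements."""
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    colors255 = np.clip(np.rint(np.asarray(colors, dtype=float) * 255), 0, 255).astype(int)
    edges = np.asarray(edges, dtype=int).reshape(-1, 2)
    lines = ["ply", "format ascii 1.0"]
    lines += [f"comment {c}" for c in comments]
    lines += [
        f"element vertex {len(vertices)}",
        "property float x", "property float y", "property float z",
        "property uchar red", "property uchar green", "property uchar blue",
        f"element edge {len(edges)}",
        "property int vertex1", "property int vertex2",
        "end_header",
    ]
    for p, c in zip(vertices, colors255):
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {c[0]} {c[1]} {c[2]}")
    for a, b in edges:
        lines.append(f"{a} {b}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ply_lines(path):
    """Parse an ASCII PLY written by :func:`write_ply_lines`.

    Returns (vertices (n,3), colors (n,3) in [0,1], edges (m,2)).
    """
    text = Path(path).read_text().splitlines()
    n_vert = n_edge = 0
    body_at = 0
    for i, line in enumerate(text):
        parts = line.split()
        if parts[:2] == ["element", "vertex"]:
            n_vert = int(parts[2])
        elif parts[:2] == ["element", "edge"]:
            n_edge = int(parts[2])
        elif parts[:1] == ["end_header"]:
            body_at = i + 1
            break
    verts = np.array(
        [[float(x) for x in text[body_at + i].split()[:3]] for i in range(n_vert)]
    ).reshape(-1, 3)
    cols = np.array(
        [[int(x) for x in text[body_at + i].split()[3:6]] for i in range(n_vert)]
    ).reshape(-1, 3) / 255.0
    edges = np.array(
        [[int(x) for x in text[body_at + n_vert + i].split()[:2]] for i in range(n_edge)]
    ).reshape(-1, 2)
    return verts, cols, edges


def _palette(n: int) -> np.ndarray:
    """n visually distinct saturated colors (hue wheel, avoiding pure red)."""
    if n == 0:
        return np.empty((0, 3))
    hues = 0.08 + 0.84 * np.arange(n) / max(n, 1)
    return _rainbow(1.0 - hues)


def _geometry_ply(network: Network, result: GeometryResult, cmap: Colormap):
    """Sample polylines with per-point weight colors as (verts, colors, edges)."""
    verts, cols, edges = [], [], []
    offset = 0
    samples, weights = result.samples, result.per_point_weight
    for fid in sorted(network.fibers):
        m = samples.fiber_ids == fid
        order = np.argsort(samples.arc[m], kind="stable")
        pts = samples.points[m][order]
        w = weights[m][order]
        verts.append(pts)
        cols.append(cmap.lookup(w))
        edges.extend((offset + i, offset + i + 1) for i in range(len(pts) - 1))
        offset += len(pts)
    verts = np.concatenate(verts) if verts else np.empty((0, 3))
    cols = np.concatenate(cols) if cols else np.empty((0, 3))
    return verts, cols, np.array(edges, dtype=int).reshape(-1, 2)


def _connectivity_ply(network: Network, colored_vertex_ids: set[int],
                      edge_color: dict[int, np.ndarray], neutral):
    """Node markers first (red = undetected, gray = detected), then edges."""
    node_ids = sorted(network.nodes)
    verts = [network.nodes[nid] for nid in node_ids]
    cols = [
        np.array([0.5, 0.5, 0.5]) if nid in colored_vertex_ids else np.array([1.0, 0.0, 0.0])
        for nid in node_ids
    ]
    edges = []
    offset = len(verts)
    for fid in sorted(network.fibers):
        fib = network.fibers[fid]
        color = edge_color.get(fid)
        if color is None:
            color = np.asarray(neutral, dtype=float)
        verts.extend(fib.points)
        cols.extend([color] * len(fib.points))
        edges.extend((offset + i, offset + i + 1) for i in range(len(fib.points) - 1))
        offset += len(fib.points)
    return np.array(verts), np.array(cols), np.array(edges, dtype=int).reshape(-1, 2)


def export_comparison(gt: Network, test: Network, geo_gt: GeometryResult,
                      geo_t: GeometryResult, conn: ConnectivityResult,
                      out_dir, cmap: Colormap | str = "diverging",
                      neutral=(0.7, 0.7, 0.7)) -> dict:
    """Write colored geometry, connectivity geometry and a JSON summary.

    Produces ``gt_geometry.ply`` / ``test_geometry.ply`` (per-point
    weights through the colormap), ``gt_connectivity.ply`` /
    ``test_connectivity.ply`` (node markers and matched-pair edge
    colors), and ``summary.json``.  Returns the summary dict.
    """
    if isinstance(cmap, str):
        cmap = get_colormap(cmap)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    for name, net, geo in (("gt", gt, geo_gt), ("test", test, geo_t)):
        v, c, e = _geometry_ply(net, geo, cmap)
        write_ply_lines(out / f"{name}_geometry.ply", v, c, e,
                        comments=[f"{name} per-point geometric error, colormap {cmap.name}"])

    pal = _palette(len(conn.matched_core_pairs))
    color_gt: dict[int, np.ndarray] = {}
    color_t: dict[int, np.ndarray] = {}
    for i, (ge, te) in enumerate(conn.matched_core_pairs):
        for eid in ge.path:
            color_gt[eid] = pal[i]
        for eid in te.path:
            color_t[eid] = pal[i]

    colored_gt = set(conn.colored_gt_ids)
    colored_t = set(conn.colored_t_ids)
    for name, net, colored, ecol in (
        ("gt", gt, colored_gt, color_gt),
        ("test", test, colored_t, color_t),
    ):
        v, c, e = _connectivity_ply(net, colored, ecol, neutral)
        write_ply_lines(out / f"{name}_connectivity.ply", v, c, e,
                        comments=[f"{name} connectivity: first {net.n_nodes} vertices are node markers"])

    summary = {
        "gfnr": geo_gt.global_M,
        "gfpr": geo_t.global_M,
        "cfnr": conn.cfnr,
        "cfpr": conn.cfpr,
        "connectivity": conn.to_dict(),
        "per_fiber_M_gt": {str(k): v for k, v in sorted(geo_gt.per_fiber_M.items())},
        "per_fiber_M_test": {str(k): v for k, v in sorted(geo_t.per_fiber_M.items())},
        "n_matched_core_pairs": len(conn.matched_core_pairs),
        "red_node_count_gt": gt.n_nodes - len(colored_gt),
        "red_node_count_test": test.n_nodes - len(colored_t),
        "colormap": cmap.name,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
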