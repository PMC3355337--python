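"""Synthetic fixture networks and controlled error injection.

Two generators emulate the structures the comparison is designed for:
branched neuron-like trees (:func:`generate_tree`) and interconnected,
loop-containing lattices emulating microvasculature
(:func:`generate_lattice_network`).  :func:`inject_errors` corrupts a
copy of a network with the canonical segmentation-error taxonomy — gaps,
spurs, missing and spurious fibers, fiber deformation, node jitter,
subdivision, duplicated (parallel) edges — and returns a machine-readable
:class:`ErrorLedger` predicting the metric consequences of each error.

Errors are placed with a minimum mutual separation of 5 sigma so their
predicted effects compose additively; all randomness flows from one
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import Fiber, Network

__all__ = [
    "LedgerEntry",
    "ErrorLedger",
    "generate_tree",
    "generate_lattice_network",
    "generate_fiber_pair",
    "delete_length_fraction",
    "inject_errors",
]


@dataclass
class LedgerEntry:
    """One injected error and its predicted metric consequences."""

    kind: str
    targets: dict
    magnitude: float
    expected: dict[str, float]

    def __post_init__(self) -> None:
        for key, val in self.expected.items():
            if isinstance(val, (int, float)) and val < 0:
                raise ValueError(f"expected effect {key} must be non-negative")


@dataclass
class ErrorLedger:
    """Record of injected errors with expected metric consequences."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def totals(self) -> dict[str, float]:
        """Sum the expected numeric effects over all entries."""
        out: dict[str, float] = {}
        for e in self.entries:
            for k, v in e.expected.items():
                out[k] = out.get(k, 0.0) + v
        return out

    def to_dict(self) -> dict:
        return {
            "entries": [
                {
                    "kind": e.kind,
                    "targets": e.targets,
                    "magnitude": e.magnitude,
                    "expected": e.expected,
                }
                for e in self.entries
            ],
            "totals": self.totals(),
        }


# ---------------------------------------------------------------------------
# generators


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([0.0, 0.0, 1.0])
    return v / n


def _random_perp(rng: np.random.Generator, d: np.ndarray) -> np.ndarray:
    while True:
        r = rng.standard_normal(3)
        p = r - np.dot(r, d) * d
        if np.linalg.norm(p) > 1e-6:
            return _unit(p)


def _grow_fiber(rng, start, direction, length, root, n_steps=None, wobble=0.12):
    """Random-walk polyline of exact arc length ``length``.

    The walk direction gets Gaussian wobble plus a bias away from the
    tree root, which keeps sibling branches spreading apart the way
    neuronal processes radiate from the soma.  Steps are about one model
    unit long, giving tortuosity comparable to real traces (and fiber
    orientation that decorrelates along the fiber, so no fiber is stuck
    in one grid-aligned direction).
    """
    if n_steps is None:
        n_steps = max(16, int(round(length)))
    step = length / n_steps
    pts = [np.asarray(start, dtype=float)]
    d = _unit(np.asarray(direction, dtype=float))
    for _ in range(n_steps):
        d = _unit(d + wobble * rng.standard_normal(3))
        radial = pts[-1] - root
        if np.linalg.norm(radial) > 1e-9:
            d = _unit(d + 0.15 * _unit(radial))
        pts.append(pts[-1] + step * d)
    # rescale segments to make the arc length exactly `length`
    pts = np.array(pts)
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    seg = seg / seg_len[:, None] * step
    out = np.concatenate([[pts[0]], pts[0] + np.cumsum(seg, axis=0)])
    return out


def generate_tree(n_branch_events: int, branch_length=40.0, seed: int = 0,
                  radius: float = 1.0) -> Network:
    """Rooted binary-branching tree with random-walk fiber geometry.

    Starts as a single fiber; each branch event replaces a random leaf
    tip with a junction sprouting two child fibers, so a tree with n
    events has exactly 2n+1 fibers and 2n+2 nodes.  ``branch_length`` is
    either a fixed fiber length or a (lo, hi) range sampled per fiber.
    Every polyline point carries the constant ``radius`` (so the
    conventional sigma default, the mean fiber radius, equals
    ``radius``).  Deterministic per seed.
    """
    if n_branch_events < 0:
        raise ValueError("n_branch_events must be >= 0")
    rng = np.random.default_rng(seed)

    def _length() -> float:
        if np.isscalar(branch_length):
            return float(branch_length)
        lo, hi = branch_length
        return float(rng.uniform(lo, hi))

    root = np.zeros(3)
    net = Network()
    net.nodes[0] = root.copy()
    first = _grow_fiber(rng, root, _unit(rng.standard_normal(3)), _length(), root)
    net.nodes[1] = first[-1].copy()
    net.fibers[0] = Fiber(0, 0, 1, first, np.full(len(first), radius))
    tips = [1]  # node ids of current leaf tips
    for _ in range(n_branch_events):
        tip = tips.pop(rng.integers(len(tips)))
        pos = net.nodes[tip]
        # direction of the fiber arriving at this tip
        parent = next(f for f in net.fibers.values() if f.node_b == tip or f.node_a == tip)
        d_in = _unit(
            parent.points[-1] - parent.points[-2]
            if parent.node_b == tip
            else parent.points[0] - parent.points[1]
        )
        perp = _random_perp(rng, d_in)
        spread = np.deg2rad(55.0)
        for sign in (+1.0, -1.0):
            d_child = _unit(np.cos(spread) * d_in + sign * np.sin(spread) * perp)
            pts = _grow_fiber(rng, pos, d_child, _length(), root)
            nid = max(net.nodes) + 1
            fid = max(net.fibers) + 1
            net.nodes[nid] = pts[-1].copy()
            net.fibers[fid] = Fiber(fid, tip, nid, pts, np.full(len(pts), radius))
            tips.append(nid)
    net.validate()
    return net


def generate_lattice_network(nx: int, ny: int, nz: int, jitter: float = 0.0,
                             seed: int = 0, spacing: float = 10.0) -> Network:
    """Jittered 3D grid network with loops (degree <= 6 per node).

    Nodes sit on an nx x ny x nz grid with uniform positional jitter;
    fibers are straight polylines (with interior points) between
    axis-adjacent nodes.  Deterministic per seed.
    """
    if min(nx, ny, nz) < 1 or sorted((nx, ny, nz))[1] < 2:
        raise ValueError("at least two axes need >= 2 grid points")
    rng = np.random.default_rng(seed)
    net = Network()
    nid_of: dict[tuple[int, int, int], int] = {}
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                nid = len(nid_of)
                pos = spacing * np.array([i, j, k], dtype=float)
                if jitter > 0:
                    pos = pos + rng.uniform(-jitter, jitter, 3)
                nid_of[(i, j, k)] = nid
                net.nodes[nid] = pos
    fid = 0
    for (i, j, k), a in sorted(nid_of.items(), key=lambda kv: kv[1]):
        for di, dj, dk in ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            nb = (i + di, j + dj, k + dk)
            if nb in nid_of:
                b = nid_of[nb]
                pts = np.linspace(net.nodes[a], net.nodes[b], 6)
                net.fibers[fid] = Fiber(fid, a, b, pts)
                fid += 1
    net.validate()
    return net


def generate_fiber_pair(rng, sigma: float = 1.0, length_range=(50.0, 100.0),
                        max_angle: float = 0.05, max_offset: float = 3.0):
    """A random straight fiber and a slightly rotated, offset copy.

    Used to probe the sampling accuracy of the geometry metric: the
    nearest-distance field between the two fibers ranges over roughly
    [0, max_offset*sigma].  Fibers are long relative to sigma, as in
    traced networks, so finite-length end effects stay small.  ``rng``
    is a numpy Generator (or an integer seed).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    start = rng.uniform(0, 10, 3)
    d = _unit(rng.standard_normal(3))
    length = rng.uniform(*length_range) * sigma

    n1 = Network()
    pts = np.vstack([start, start + d * length])
    n1.nodes[0], n1.nodes[1] = pts[0].copy(), pts[1].copy()
    n1.fibers[0] = Fiber(0, 0, 1, pts)

    angle = rng.uniform(-max_angle, max_angle)
    axis = _unit(rng.standard_normal(3))
    # Rodrigues rotation about the fiber midpoint
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
    offset = _unit(rng.standard_normal(3)) * rng.uniform(0, max_offset * sigma)
    mid = start + d * length / 2
    n2 = n1.transformed(rotation=R, translation=mid - R @ mid + offset)
    return n1, n2


def _subtree_map(net: Network) -> dict[int, frozenset[int]]:
    """fiber id -> the smaller of the two fiber sets it separates (its subtree)."""
    adj: dict[int, list[tuple[int, int]]] = {}
    for fid, f in net.fibers.items():
        adj.setdefault(f.node_a, []).append((f.node_b, fid))
        adj.setdefault(f.node_b, []).append((f.node_a, fid))

    def walk(node, via):
        out = set()
        for nbr, fid in adj.get(node, []):
            if fid != via:
                out |= {fid} | walk(nbr, fid)
        return out

    return {
        fid: frozenset(min(
            {fid} | walk(net.fibers[fid].node_b, fid),
            {fid} | walk(net.fibers[fid].node_a, fid),
            key=len,
        ))
        for fid in net.fibers
    }


def delete_length_fraction(net: Network, fraction: float,
                           max_subtrees: int = 3) -> tuple[Network, float]:
    """Remove whole subtrees totaling about ``fraction`` of the tree's length.

    Deleting complete subtrees keeps the number of deleted/kept attachment
    boundaries small (at most ``max_subtrees``), so the removed geometry
    is cleanly absent rather than fringed by partial coverage.  Returns
    the pruned network and the achieved length fraction.  Tree inputs
    only (acyclic).
    """
    import itertools

    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    subtrees = sorted({s for s in _subtree_map(net).values()}, key=sorted)
    length = {fid: f.length for fid, f in net.fibers.items()}
    total = sum(length.values())
    best, best_key = None, (np.inf, np.inf)
    for k in range(1, max_subtrees + 1):
        for combo in itertools.combinations(subtrees, k):
            union = set().union(*combo)
            if sum(len(c) for c in combo) != len(union):
                continue  # overlapping subtrees
            err = abs(sum(length[i] for i in union) / total - fraction)
            if (err, k) < best_key:
                best, best_key = union, (err, k)
    out = Network()
    out.fibers = {fid: f for fid, f in net.fibers.items() if fid not in best}
    keep = {f.node_a for f in out.fibers.values()} | {
        f.node_b for f in out.fibers.values()
    }
    out.nodes = {nid: p.copy() for nid, p in net.nodes.items() if nid in keep}
    achieved = sum(length[i] for i in best) / total
    return out, float(achieved)


# ---------------------------------------------------------------------------
# error injection


def _copy_network(net: Network) -> Network:
    out = Network()
    out.nodes = {nid: pos.copy() for nid, pos in net.nodes.items()}
    out.fibers = {
        fid: replace(f, points=f.points.copy(),
                     radii=None if f.radii is None else f.radii.copy())
        for fid, f in net.fibers.items()
    }
    return out


def _position_at(fib: Fiber, s: float) -> np.ndarray:
    arcs = fib.arc_lengths()
    out = np.empty(3)
    for k in range(3):
        out[k] = np.interp(s, arcs, fib.points[:, k])
    return out


def _tangent_at(fib: Fiber, s: float) -> np.ndarray:
    arcs = fib.arc_lengths()
    i = int(np.clip(np.searchsorted(arcs, s) - 1, 0, len(arcs) - 2))
    return _unit(fib.points[i + 1] - fib.points[i])


def _sub_polyline(fib: Fiber, s_lo: float, s_hi: float):
    """Extract the [s_lo, s_hi] arc window as (points, radii)."""
    arcs = fib.arc_lengths()
    tol = 1e-9 * max(1.0, arcs[-1])  # keep cut points from duplicating vertices
    interior = (arcs > s_lo + tol) & (arcs < s_hi - tol)
    s_vals = np.concatenate([[s_lo], arcs[interior], [s_hi]])
    pts = np.array([_position_at(fib, s) for s in s_vals])
    radii = None
    if fib.radii is not None:
        radii = np.interp(s_vals, arcs, fib.radii)
    return pts, radii


def _degree(net: Network, nid: int) -> int:
    d = 0
    for f in net.fibers.values():
        d += (f.node_a == nid) + (f.node_b == nid)
    return d


class _Injector:
    """Working state for sequential error injection on one network copy."""

    def __init__(self, network: Network, rng, sigma: float):
        self.clean = network
        self.net = _copy_network(network)
        self.rng = rng
        self.sigma = sigma
        self.sites: list[np.ndarray] = []  # 3D positions of placed errors
        self.ledger = ErrorLedger()

    def _next_nid(self) -> int:
        return max(self.net.nodes, default=-1) + 1

    def _next_fid(self) -> int:
        return max(self.net.fibers, default=-1) + 1

    def _separated(self, pos: np.ndarray) -> bool:
        return all(np.linalg.norm(pos - s) > 5 * self.sigma for s in self.sites)

    def _pick_fiber(self, fiber_id, min_length: float) -> int:
        if fiber_id is not None:
            if fiber_id not in self.net.fibers:
                raise ValueError(f"target fiber {fiber_id} not found")
            if self.net.fibers[fiber_id].length <= min_length:
                raise ValueError(f"fiber {fiber_id} too short for this error")
            return fiber_id
        pool = sorted(
            fid for fid, f in self.net.fibers.items() if f.length > min_length
        )
        if not pool:
            raise ValueError("no fiber long enough for this error")
        return pool[self.rng.integers(len(pool))]

    def _place_arc(self, fid: int, margin: float, window: float = 0.0) -> float:
        """Arc position on fiber `fid` at >= margin from both ends and
        >= 5 sigma (in 3D) from previously placed errors."""
        fib = self.net.fibers[fid]
        lo, hi = margin, fib.length - margin - window
        if hi <= lo:
            raise ValueError("fiber too short for requested placement margins")
        for _ in range(200):
            s = self.rng.uniform(lo, hi)
            pos = _position_at(fib, s)
            if self._separated(pos):
                self.sites.append(pos)
                return float(s)
        raise RuntimeError("could not place error with 5-sigma separation")

    # ---- individual error kinds ------------------------------------------

    def gap(self, width: float, fiber_id=None) -> None:
        margin = 3 * self.sigma
        fid = self._pick_fiber(fiber_id, width + 2 * margin)
        fib = self.net.fibers[fid]
        if not width > 0 or width >= fib.length:
            raise ValueError("gap width must be positive and smaller than the fiber")
        s0 = self._place_arc(fid, margin, window=width)
        c, d = self._next_nid(), self._next_nid() + 1
        p1, r1 = _sub_polyline(fib, 0.0, s0)
        p2, r2 = _sub_polyline(fib, s0 + width, fib.length)
        self.net.nodes[c] = p1[-1].copy()
        self.net.nodes[d] = p2[0].copy()
        f1, f2 = self._next_fid(), self._next_fid() + 1
        del self.net.fibers[fid]
        self.net.fibers[f1] = Fiber(f1, fib.node_a, c, p1, r1)
        self.net.fibers[f2] = Fiber(f2, d, fib.node_b, p2, r2)
        self.ledger.entries.append(LedgerEntry(
            kind="gap",
            targets={"fiber_id": int(fid), "new_node_ids": [c, d],
                     "new_fiber_ids": [f1, f2]},
            magnitude=float(width),
            expected={
                "removed_length": float(width),
                "uncolored_test": 2,
                "unused_test_edges": 2,
                "fn_edges": 1,
                "tp_gt_loss": 1,
                "fn": 1,
                "fp": 4,
            },
        ))

    def spur(self, length: float, fiber_id=None) -> None:
        if not length > 0:
            raise ValueError("spur length must be positive")
        margin = 3 * self.sigma
        fid = self._pick_fiber(fiber_id, 2 * margin)
        fib = self.net.fibers[fid]
        s0 = self._place_arc(fid, margin)
        j, t = self._next_nid(), self._next_nid() + 1
        p1, r1 = _sub_polyline(fib, 0.0, s0)
        p2, r2 = _sub_polyline(fib, s0, fib.length)
        jpos = p1[-1].copy()
        tangent = _tangent_at(fib, s0)
        direction = _random_perp(self.rng, tangent)
        n_pts = max(4, int(np.ceil(length / self.sigma)) + 1)
        spur_pts = jpos + np.outer(np.linspace(0.0, length, n_pts), direction)
        self.net.nodes[j] = jpos
        self.net.nodes[t] = spur_pts[-1].copy()
        f1, f2, fs = (self._next_fid() + i for i in range(3))
        del self.net.fibers[fid]
        self.net.fibers[f1] = Fiber(f1, fib.node_a, j, p1, r1)
        self.net.fibers[f2] = Fiber(f2, j, fib.node_b, p2, r2)
        self.net.fibers[fs] = Fiber(fs, j, t, spur_pts)
        self.ledger.entries.append(LedgerEntry(
            kind="spur",
            targets={"fiber_id": int(fid), "new_node_ids": [j, t],
                     "spur_fiber_id": fs},
            magnitude=float(length),
            expected={
                "added_length": float(length),
                "uncolored_test": 2,
                "unused_test_edges": 1,
                "fn_edges": 0,
                "tp_gt_loss": 0,
                "fn": 0,
                "fp": 3,
            },
        ))

    def missing_fiber(self, fiber_id=None) -> None:
        fid = self._pick_fiber(fiber_id, 0.0)
        fib = self.net.fibers[fid]
        self.sites.append(_position_at(fib, fib.length / 2))
        removed = fib.length
        del self.net.fibers[fid]
        uncolored_gt = 0
        for nid in dict.fromkeys((fib.node_a, fib.node_b)):
            deg = _degree(self.net, nid)
            if deg == 0:
                del self.net.nodes[nid]
                uncolored_gt += 1
            elif deg == 2:
                self._dissolve_degree2(nid)
                uncolored_gt += 1
        self.ledger.entries.append(LedgerEntry(
            kind="missing_fiber",
            targets={"fiber_id": int(fid)},
            magnitude=float(removed),
            expected={
                "removed_length": float(removed),
                "uncolored_gt": uncolored_gt,
                "fn_edges": 1,
                "tp_gt_loss": 1,
                "fn": 1 + uncolored_gt,
                "fp": 0,
            },
        ))

    def _dissolve_degree2(self, nid: int) -> None:
        """Merge the two fibers meeting at a degree-2 node; drop the node."""
        inc = [f for f in self.net.fibers.values()
               if f.node_a == nid or f.node_b == nid]
        if len(inc) != 2:
            return  # self-loop at nid; leave as is
        f1, f2 = inc
        if f1.node_b != nid:
            f1 = f1.reversed()
        if f2.node_a != nid:
            f2 = f2.reversed()
        pts = np.concatenate([f1.points, f2.points[1:]])
        if f1.radii is not None and f2.radii is not None:
            radii = np.concatenate([f1.radii, f2.radii[1:]])
        else:
            radii = None
        fid = self._next_fid()
        del self.net.fibers[inc[0].fiber_id]
        del self.net.fibers[inc[1].fiber_id]
        del self.net.nodes[nid]
        self.net.fibers[fid] = Fiber(fid, f1.node_a, f2.node_b, pts, radii)

    def spurious_fiber(self, length: float) -> None:
        if not length > 0:
            raise ValueError("spurious fiber length must be positive")
        all_pts = np.concatenate([f.points for f in self.net.fibers.values()])
        lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
        margin = 10 * self.sigma
        for _ in range(200):
            axis = int(self.rng.integers(3))
            side = 1 if self.rng.random() < 0.5 else -1
            start = self.rng.uniform(lo, hi)
            start[axis] = (hi[axis] + margin) if side > 0 else (lo[axis] - margin)
            if self._separated(start):
                break
        else:
            raise RuntimeError("could not place spurious fiber")
        self.sites.append(start.copy())
        direction = _unit(self.rng.standard_normal(3))
        direction[axis] = abs(direction[axis]) * side  # point away from the network
        # random-walk geometry, like genuine fibers, so grid-crossing density
        # (and hence the sample-mean length weighting) matches the rest
        pts = _grow_fiber(self.rng, start, _unit(direction), length, root=start)
        a, b = self._next_nid(), self._next_nid() + 1
        fid = self._next_fid()
        self.net.nodes[a] = pts[0].copy()
        self.net.nodes[b] = pts[-1].copy()
        self.net.fibers[fid] = Fiber(fid, a, b, pts)
        self.ledger.entries.append(LedgerEntry(
            kind="spurious_fiber",
            targets={"fiber_id": fid, "new_node_ids": [a, b]},
            magnitude=float(length),
            expected={
                "added_length": float(length),
                "uncolored_test": 2,
                "unused_test_edges": 1,
                "fn": 0,
                "fp": 3,
            },
        ))

    def duplicate_edge(self, amplitude: float | None = None, fiber_id=None) -> None:
        amp = 2 * self.sigma if amplitude is None else amplitude
        fid = self._pick_fiber(fiber_id, 4 * amp)
        fib = self.net.fibers[fid]
        self.sites.append(_position_at(fib, fib.length / 2))
        arcs = np.linspace(0.0, fib.length, 80)
        base = np.array([_position_at(fib, s) for s in arcs])
        perp = _random_perp(self.rng, _unit(fib.points[-1] - fib.points[0]))
        bump = amp * np.sin(np.pi * arcs / fib.length) ** 2
        pts = base + bump[:, None] * perp
        dup = self._next_fid()
        self.net.fibers[dup] = Fiber(dup, fib.node_a, fib.node_b, pts)
        self.ledger.entries.append(LedgerEntry(
            kind="duplicate_edge",
            targets={"fiber_id": int(fid), "duplicate_fiber_id": dup},
            magnitude=float(amp),
            expected={
                "unused_test_edges": 1,
                "fn": 0,
                "fp": 1,
            },
        ))

    def deformation(self, amplitude: float, fiber_id=None) -> None:
        if not amplitude > 0:
            raise ValueError("deformation amplitude must be positive")
        fid = self._pick_fiber(fiber_id, 0.0)
        fib = self.net.fibers[fid]
        self.sites.append(_position_at(fib, fib.length / 2))
        arcs = np.linspace(0.0, fib.length, 200)
        base = np.array([_position_at(fib, s) for s in arcs])
        perp = _random_perp(self.rng, _unit(fib.points[-1] - fib.points[0]))
        bump = amplitude * np.sin(np.pi * arcs / fib.length) ** 2
        pts = base + bump[:, None] * perp
        radii = None
        if fib.radii is not None:
            radii = np.interp(arcs, fib.arc_lengths(), fib.radii)
        self.net.fibers[fid] = Fiber(fid, fib.node_a, fib.node_b, pts, radii)
        # quadrature prediction of the deformed fiber's mean geometric error
        w = 1.0 - np.exp(-(bump**2) / (2.0 * self.sigma**2))
        expected_m = float(np.trapezoid(w, arcs) / fib.length)
        self.ledger.entries.append(LedgerEntry(
            kind="deformation",
            targets={"fiber_id": int(fid)},
            magnitude=float(amplitude),
            expected={
                "expected_fiber_M": expected_m,
                "fn": 0,
                "fp": 0,
            },
        ))

    def node_jitter(self, magnitude: float, node_id=None) -> None:
        if not magnitude > 0:
            raise ValueError("jitter magnitude must be positive")
        if node_id is None:
            ids = sorted(self.net.nodes)
            node_id = ids[self.rng.integers(len(ids))]
        elif node_id not in self.net.nodes:
            raise ValueError(f"target node {node_id} not found")
        shift = magnitude * _unit(self.rng.standard_normal(3))
        self.sites.append(self.net.nodes[node_id].copy())
        self.net.nodes[node_id] = self.net.nodes[node_id] + shift
        for f in self.net.fibers.values():
            if f.node_a == node_id:
                f.points[0] = f.points[0] + shift
            if f.node_b == node_id:
                f.points[-1] = f.points[-1] + shift
        self.ledger.entries.append(LedgerEntry(
            kind="node_jitter",
            targets={"node_id": int(node_id)},
            magnitude=float(magnitude),
            expected={"fn": 0, "fp": 0} if magnitude < self.sigma else {},
        ))

    def subdivision(self, fiber_id=None) -> None:
        fid = self._pick_fiber(fiber_id, 0.0)
        fib = self.net.fibers[fid]
        s0 = fib.length / 2
        m = self._next_nid()
        p1, r1 = _sub_polyline(fib, 0.0, s0)
        p2, r2 = _sub_polyline(fib, s0, fib.length)
        self.net.nodes[m] = p1[-1].copy()
        f1, f2 = self._next_fid(), self._next_fid() + 1
        del self.net.fibers[fid]
        self.net.fibers[f1] = Fiber(f1, fib.node_a, m, p1, r1)
        self.net.fibers[f2] = Fiber(f2, m, fib.node_b, p2, r2)
        self.ledger.entries.append(LedgerEntry(
            kind="subdivision",
            targets={"fiber_id": int(fid), "new_node_id": m},
            magnitude=0.0,
            expected={"fn": 0, "fp": 0, "extra_degree2_nodes": 1},
        ))


_DISPATCH = {
    "gap": lambda inj, req: inj.gap(req["width"], req.get("fiber_id")),
    "spur": lambda inj, req: inj.spur(req.get("length", 5 * inj.sigma), req.get("fiber_id")),
    "missing_fiber": lambda inj, req: inj.missing_fiber(req.get("fiber_id")),
    "spurious_fiber": lambda inj, req: inj.spurious_fiber(req["length"]),
    "duplicate_edge": lambda inj, req: inj.duplicate_edge(req.get("amplitude"), req.get("fiber_id")),
    "deformation": lambda inj, req: inj.deformation(req["amplitude"], req.get("fiber_id")),
    "node_jitter": lambda inj, req: inj.node_jitter(req["magnitude"], req.get("node_id")),
    "subdivision": lambda inj, req: inj.subdivision(req.get("fiber_id")),
}


def inject_errors(network: Network, requests, seed: int = 0,
                  sigma: float = 1.0) -> tuple[Network, ErrorLedger]:
    """Apply a list of error requests to a copy of ``network``.

    Each request is a dict with a ``kind`` key (one of gap, spur,
    missing_fiber, spurious_fiber, duplicate_edge, deformation,
    node_jitter, subdivision) plus kind-specific parameters; targets are
    chosen at random (seeded) when not given.  Returns the corrupted
    network and the ledger of expected effects.  ``sigma`` is the
    sensitivity scale used for placement margins and the 5-sigma mutual
    separation rule.
    """
    rng = np.random.default_rng(seed)
    inj = _Injector(network, rng, sigma)
    for req in requests:
        kind = req.get("kind")
        if kind not in _DISPATCH:
            raise ValueError(f"unknown error kind {kind!r}")
        _DISPATCH[kind](inj, req)
    inj.net.validate()
    return inj.net, inj.ledger
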