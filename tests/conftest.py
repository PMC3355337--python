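"""Shared fixtures: small hand-built networks used across test modules."""

import numpy as np
import pytest

from fibermetrics.model import Fiber, Network


def make_network(fiber_specs):
    """Build a Network from [(node_a_pos, node_b_pos, interior_points), ...].

    Node positions that compare equal are merged into one node id.
    """
    net = Network()
    pos_to_id = {}

    def nid(pos):
        key = tuple(np.round(np.asarray(pos, dtype=float), 12))
        if key not in pos_to_id:
            pos_to_id[key] = len(pos_to_id)
            net.nodes[pos_to_id[key]] = np.asarray(pos, dtype=float)
        return pos_to_id[key]

    for fid, (a, b, interior) in enumerate(fiber_specs):
        pts = np.vstack([[a], np.asarray(interior).reshape(-1, 3), [b]])
        net.fibers[fid] = Fiber(fid, nid(a), nid(b), pts)
    net.validate()
    return net


def straight_fiber_network(length=100.0, offset=(0.0, 0.0, 0.0), n_pts=2):
    """A single straight fiber along +x starting at ``offset``."""
    o = np.asarray(offset, dtype=float)
    pts = o + np.linspace([0, 0, 0], [length, 0, 0], n_pts)
    net = Network()
    net.nodes[0] = pts[0].copy()
    net.nodes[1] = pts[-1].copy()
    net.fibers[0] = Fiber(0, 0, 1, pts)
    return net


@pytest.fixture
def y_tree():
    """Root -> junction with two tips (4 nodes, 3 fibers)."""
    return make_network([
        ((0, 0, 0), (10, 0, 0), [(5, 0, 0)]),
        ((10, 0, 0), (20, 8, 0), [(15, 4, 0)]),
        ((10, 0, 0), (20, -8, 0), [(15, -4, 0)]),
    ])
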