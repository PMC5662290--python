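import numpy as np
import pytest

from arborscale.skeletons import Skeleton, SkeletonNode


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def make_skeleton(parents, coords=None, neuron_id="n", tags=None, **meta):
    """Build a Skeleton from a parent list (parents[0] must be None) with
    node ids 0..n-1.  Coordinates default to random-ish deterministic values.
    Coordinates are given in um and stored in nm."""
    n = len(parents)
    if coords is None:
        r = np.random.default_rng(abs(hash(tuple(parents))) % (2**31))
        coords = r.uniform(0, 100, size=(n, 3))
    nodes = {
        i: SkeletonNode(
            node_id=i,
            parent_id=parents[i],
            x=float(coords[i][0]) * 1000.0,
            y=float(coords[i][1]) * 1000.0,
            z=float(coords[i][2]) * 1000.0,
        )
        for i in range(n)
    }
    return Skeleton(
        neuron_id=neuron_id, nodes=nodes, tags=tags or {}, **meta
    ).validate()


def random_tree(rng, n_nodes, coord_scale=50.0):
    """Random rooted tree: each node's parent drawn among earlier nodes."""
    parents = [None] + [int(rng.integers(i)) for i in range(1, n_nodes)]
    coords = rng.uniform(0, coord_scale, size=(n_nodes, 3))
    return make_skeleton(parents, coords)


def chain(n, spacing_um=1.0):
    parents = [None] + list(range(n - 1))
    coords = [(0.0, 0.0, i * spacing_um) for i in range(n)]
    return make_skeleton(parents, coords)


def perfect_binary_tree(levels, edge_um=1.0):
    """Root plus `levels` levels of symmetric bifurcation; equal edge lengths.

    Coordinates spread siblings apart so edges have identical length edge_um.
    """
    parents = [None]
    coords = [(0.0, 0.0, 0.0)]
    prev_level = [0]
    nid = 1
    for lvl in range(1, levels + 1):
        cur = []
        for j, p in enumerate(prev_level):
            for k in (0, 1):
                parents.append(p)
                px, py, pz = coords[p]
                # step in z keeps all edge lengths equal
                coords.append((px + (2 * j + k) * 1e-6, py, pz + edge_um))
                cur.append(nid)
                nid += 1
        prev_level = cur
    return make_skeleton(parents, coords)
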