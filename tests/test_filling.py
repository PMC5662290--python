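import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from arborscale.filling import (
    filling_fraction,
    potential_synapses,
    prune_terminal_branches,
    radius_sweep,
    resample_points,
)
from arborscale.morphometry import strahler
from arborscale.skeletons import CircuitVolume, Connector, Skeleton, SkeletonNode
from arborscale.synthetic import planted_filling_instance

from conftest import chain, make_skeleton, perfect_binary_tree, random_tree


def straight_cable(n=21, spacing_um=1.0, y_um=0.0):
    """Long straight skeleton with side branches so its core survives pruning."""
    parents = [None]
    coords = [(0.0, y_um, 0.0)]
    spine = [0]
    nid = 1
    for i in range(1, n):
        parents.append(spine[-1])
        coords.append((i * spacing_um, y_um, 0.0))
        spine.append(nid)
        nid += 1
    for i in range(0, n, 2):
        parents.append(spine[i])
        coords.append((i * spacing_um, y_um + 0.3, 0.0))
        nid += 1
    return make_skeleton(parents, coords)


class TestPrune:
    def test_chain_collapses_to_root_with_warning(self):
        skel = chain(6)
        with pytest.warns(UserWarning, match="unbranched"):
            pruned = prune_terminal_branches(skel)
        assert set(pruned.nodes) == {skel.root}

    def test_perfect_binary_tree_keeps_core(self):
        skel = perfect_binary_tree(2)
        pruned = prune_terminal_branches(skel)
        order = strahler(skel)
        assert set(pruned.nodes) == {n for n, o in order.items() if o >= 2}
        pruned.validate()

    def test_pruned_set_equals_high_strahler_nodes(self, rng):
        for _ in range(10):
            skel = random_tree(rng, 120)
            order = strahler(skel)
            expect = {n for n, o in order.items() if o >= 2}
            if not expect:
                continue
            assert set(prune_terminal_branches(skel).nodes) == expect


class TestPotentialSynapses:
    def test_sites_within_radius_counted(self):
        post = straight_cable()
        sites = np.array(
            [[5000.0, 1000.0, 0.0], [8000.0, -1000.0, 0.0],
             [10000.0, 1000.0, 0.0], [12000.0, 1000.0, 0.0]]
        )
        pruned = prune_terminal_branches(post)
        assert potential_synapses(sites, pruned, d_um=2.0).sum() == 4
        assert potential_synapses(sites, pruned, d_um=0.5).sum() == 0

    def test_matches_brute_force_distance_scan(self, rng):
        for _ in range(5):
            post = random_tree(rng, 60, coord_scale=20.0)
            pruned = prune_terminal_branches(post)
            sites = rng.uniform(0, 20000.0, size=(40, 3))
            d_um = 3.0
            mask = potential_synapses(sites, pruned, d_um=d_um)
            samples = resample_points(pruned)
            expect = cdist(sites, samples).min(axis=1) <= d_um * 1000.0
            assert np.array_equal(mask, expect)

    def test_nested_across_radii(self, rng):
        post = random_tree(rng, 60, coord_scale=20.0)
        pruned = prune_terminal_branches(post)
        sites = rng.uniform(0, 20000.0, size=(50, 3))
        prev = np.zeros(50, dtype=bool)
        for d in [0.5, 1.0, 2.0, 4.0, 8.0]:
            mask = potential_synapses(sites, pruned, d_um=d)
            assert (prev <= mask).all()  # superset property
            prev = mask

    def test_resampling_step_halved_changes_counts_little(self, rng):
        # smooth arbor: gentle random walk with 1 um steps
        n = 150
        steps = rng.normal(size=(n, 3))
        steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pts = np.cumsum(steps * 1000.0, axis=0)
        parents = [None] + list(range(n - 1))
        nodes = {
            i: SkeletonNode(i, parents[i], *pts[i]) for i in range(n)
        }
        skel = Skeleton("smooth", nodes).validate()
        sites = pts[:: 5] + rng.normal(scale=1500.0, size=(len(pts[::5]), 3))
        full = potential_synapses(sites, skel, d_um=2.0, step_um=0.5).sum()
        half = potential_synapses(sites, skel, d_um=2.0, step_um=0.25).sum()
        assert abs(int(full) - int(half)) <= max(1, 0.02 * full)


def two_neuron_geometry(rng, q, n_sites):
    circuit, pre, post = planted_filling_instance(
        q=q, n_sites=n_sites, seed=int(rng.integers(2**31))
    )
    return circuit, pre, post


class TestFillingFraction:
    def test_half_connected(self):
        # 4 potential sites, 2 actually connected -> fraction 0.5
        post = straight_cable()
        pre = straight_cable(y_um=1.0)
        bgp = [None]
        bg = make_skeleton(bgp, [(0.0, 50.0, 0.0)], neuron_id="bg")
        pre.neuron_id, post.neuron_id = "pre", "post"
        conns = []
        post_spine = sorted(post.nodes)
        for i, x in enumerate([4, 8, 12, 16]):
            target = ("post", post_spine[x]) if i < 2 else ("bg", 0)
            conns.append(
                Connector(
                    connector_id=i,
                    pre=("pre", sorted(pre.nodes)[x]),
                    posts=[target],
                    location=(x * 1000.0, 1000.0, 0.0),
                )
            )
        circuit = CircuitVolume(
            stage="s", skeletons={"pre": pre, "post": post, "bg": bg},
            connectors=conns,
        ).validate()
        r = filling_fraction(circuit, "pre", "post", d_um=2.0)
        assert r.n_potential == 4
        assert r.n_actual == 2
        assert r.fraction == pytest.approx(0.5)

    def test_all_connected_gives_one(self, rng):
        circuit, pre, post = two_neuron_geometry(rng, q=1.0, n_sites=50)
        r = filling_fraction(circuit, pre, post)
        assert r.fraction == pytest.approx(1.0)

    def test_planted_connection_probability_recovered(self, rng):
        q, n = 0.3, 400
        circuit, pre, post = two_neuron_geometry(rng, q, n)
        r = filling_fraction(circuit, pre, post)
        assert r.n_potential == n
        # binomial tolerance: 3 sd of qhat around q
        tol = 3 * math.sqrt(q * (1 - q) / n)
        assert abs(r.fraction - q) < tol

    def test_rigid_transform_invariance(self, rng):
        circuit, pre, post = two_neuron_geometry(rng, q=0.5, n_sites=80)
        r = filling_fraction(circuit, pre, post)
        theta = 0.9
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        shift = np.array([1e4, -2e4, 3e3])

        def transform_skel(s):
            nodes = {
                nid: SkeletonNode(
                    nid, n.parent_id, *(rot @ n.xyz + shift)
                )
                for nid, n in s.nodes.items()
            }
            return Skeleton(s.neuron_id, nodes).validate()

        skels = {k: transform_skel(v) for k, v in circuit.skeletons.items()}
        conns = [
            Connector(
                c.connector_id, c.pre, c.posts,
                tuple(rot @ np.array(c.location) + shift),
            )
            for c in circuit.connectors
        ]
        moved = CircuitVolume("s", skels, conns).validate()
        r2 = filling_fraction(moved, pre, post)
        assert r2.n_potential == r.n_potential
        assert r2.fraction == pytest.approx(r.fraction)


class TestRadiusSweep:
    def test_saturation_and_monotonicity(self, rng):
        circuit, pre, post = two_neuron_geometry(rng, q=0.4, n_sites=60)
        grid = [0.25, 0.5, 1.0, 2.0, 4.0, 50.0]
        curve = radius_sweep(circuit, pre, post, grid)
        potentials = [r.n_potential for r in curve]
        assert potentials == sorted(potentials)  # non-decreasing in d
        # at large d every presynaptic site is potential
        n_sites = len(circuit.presynaptic_sites(pre))
        assert curve[-1].n_potential == n_sites
        assert curve[-1].fraction == pytest.approx(
            curve[-1].n_actual / n_sites
        )

    def test_matches_single_radius_calls(self, rng):
        circuit, pre, post = two_neuron_geometry(rng, q=0.5, n_sites=40)
        grid = [1.0, 2.0, 3.0]
        curve = radius_sweep(circuit, pre, post, grid)
        for d, r in zip(grid, curve):
            single = filling_fraction(circuit, pre, post, d_um=d)
            assert r.n_potential == single.n_potential
            assert r.n_actual == single.n_actual

    def test_bad_grid_rejected(self, rng):
        circuit, pre, post = two_neuron_geometry(rng, q=0.5, n_sites=10)
        with pytest.raises(ValueError):
            radius_sweep(circuit, pre, post, [2.0, 1.0])
        with pytest.raises(ValueError):
            radius_sweep(circuit, pre, post, [-1.0, 1.0])
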