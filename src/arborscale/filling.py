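"""Potential synapses and filling fraction for directed neuron pairs.

A presynaptic site is a *potential synapse* onto a target neuron if it lies
within a radius d (default 2 um) of the target's arbor after terminal
branches (Strahler order 1) have been computationally removed — pruning
approximates the reach of typical twig growth without overestimating the
neuron's spatial extent.  The *filling fraction* of a directed pair is the
fraction of those potential sites that actually make a contact onto the
target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .morphometry import strahler
from .skeletons import CircuitVolume, Connector, Skeleton

__all__ = [
    "DEFAULT_RADIUS_UM",
    "RESAMPLE_STEP_UM",
    "FillingFractionResult",
    "prune_terminal_branches",
    "resample_points",
    "potential_synapses",
    "presynaptic_site_locations",
    "filling_fraction",
    "radius_sweep",
]

DEFAULT_RADIUS_UM = 2.0
#: maximum spacing of arbor sample points for distance queries
RESAMPLE_STEP_UM = 0.5
NM_PER_UM = 1000.0


def prune_terminal_branches(skeleton: Skeleton) -> Skeleton:
    """Remove all Strahler-order-1 nodes, keeping the order>=2 core.

    An unbranched arbor (everything order 1) collapses to its root, with a
    warning.  The result is a valid skeleton.
    """
    order = strahler(skeleton)
    keep = {nid for nid, o in order.items() if o >= 2}
    if not keep:
        warnings.warn(
            f"skeleton {skeleton.neuron_id!r} is unbranched; pruning leaves "
            "only the root node",
            stacklevel=2,
        )
        keep = {skeleton.root}
    pruned = Skeleton(
        neuron_id=skeleton.neuron_id,
        nodes={nid: skeleton.nodes[nid] for nid in keep},
        tags={nid: set(v) for nid, v in skeleton.tags.items() if nid in keep},
        cell_type=skeleton.cell_type,
        side=skeleton.side,
        segment=skeleton.segment,
        stage=skeleton.stage,
    )
    return pruned.validate()


def resample_points(
    skeleton: Skeleton, step_um: float = RESAMPLE_STEP_UM
) -> np.ndarray:
    """Sample the arbor's cable at spacing <= step_um (nm coordinates).

    Every node is included, and each parent edge is subdivided evenly so no
    gap between consecutive samples exceeds the step.
    """
    pts = [skeleton.coords(sorted(skeleton.nodes))]
    step_nm = step_um * NM_PER_UM
    for parent, child in skeleton.edges():
        a = skeleton.nodes[parent].xyz
        b = skeleton.nodes[child].xyz
        length = float(np.linalg.norm(b - a))
        n_seg = int(np.ceil(length / step_nm))
        if n_seg > 1:
            t = np.arange(1, n_seg)[:, None] / n_seg
            pts.append(a[None, :] + t * (b - a)[None, :])
    return np.vstack(pts)


def presynaptic_site_locations(
    circuit: CircuitVolume, pre_neuron: str
) -> tuple[list[Connector], np.ndarray]:
    """Presynaptic sites of a neuron and their positions (nm).

    A site's position is its connector location when present, else the
    position of its presynaptic treenode.
    """
    sites = circuit.presynaptic_sites(pre_neuron)
    locs = []
    skel = circuit.skeletons[pre_neuron]
    for c in sites:
        if c.location is not None and all(np.isfinite(c.location)):
            locs.append(np.asarray(c.location, dtype=float))
        else:
            locs.append(skel.nodes[c.pre[1]].xyz)
    return sites, (
        np.array(locs) if locs else np.empty((0, 3))
    )


def potential_synapses(
    site_locations: np.ndarray,
    post_pruned: Skeleton,
    d_um: float = DEFAULT_RADIUS_UM,
    step_um: float = RESAMPLE_STEP_UM,
) -> np.ndarray:
    """Boolean mask of presynaptic sites within d of the pruned target arbor.

    The target is resampled at <= step_um spacing and queried with a k-d
    tree; distance is site-to-sample-point.
    """
    if d_um <= 0:
        raise ValueError("potential synapse radius must be positive")
    if len(site_locations) == 0:
        return np.zeros(0, dtype=bool)
    samples = resample_points(post_pruned, step_um=step_um)
    tree = cKDTree(samples)
    dist, _ = tree.query(site_locations, k=1)
    return dist <= d_um * NM_PER_UM


@dataclass
class FillingFractionResult:
    pre_neuron: str
    post_neuron: str
    d_um: float
    n_potential: int
    n_actual: int
    fraction: float  # NaN when no potential synapses
    #: actual contacting sites that fell outside the potential set (e.g. on
    #: pruned terminal branches further than d); reported, never clipped
    n_actual_outside_potential: int


def filling_fraction(
    circuit: CircuitVolume,
    pre_neuron: str,
    post_neuron: str,
    d_um: float = DEFAULT_RADIUS_UM,
    post_pruned: Skeleton | None = None,
    step_um: float = RESAMPLE_STEP_UM,
) -> FillingFractionResult:
    """Filling fraction of the directed pair pre -> post at radius d.

    Potential synapses are counted against the pruned target arbor; actual
    synapses are presynaptic sites with at least one contact onto the target,
    wherever the contact lands (contacts on pruned terminal branches still
    count as actual).  Sites that are actual but not potential are tallied
    separately rather than silently clipped.
    """
    sites, locs = presynaptic_site_locations(circuit, pre_neuron)
    if post_pruned is None:
        post_pruned = prune_terminal_branches(circuit.skeletons[post_neuron])
    mask = potential_synapses(locs, post_pruned, d_um=d_um, step_um=step_um)
    actual_mask = np.array(
        [any(nrn == post_neuron for nrn, _ in c.posts) for c in sites], dtype=bool
    )
    n_potential = int(mask.sum())
    n_actual = int(actual_mask.sum())
    outside = int((actual_mask & ~mask).sum())
    fraction = (n_actual / n_potential) if n_potential else float("nan")
    return FillingFractionResult(
        pre_neuron=pre_neuron,
        post_neuron=post_neuron,
        d_um=d_um,
        n_potential=n_potential,
        n_actual=n_actual,
        fraction=fraction,
        n_actual_outside_potential=outside,
    )


def radius_sweep(
    circuit: CircuitVolume,
    pre_neuron: str,
    post_neuron: str,
    d_grid_um,
    step_um: float = RESAMPLE_STEP_UM,
) -> list[FillingFractionResult]:
    """Filling fraction over an increasing grid of potential-synapse radii.

    Potential counts are non-decreasing in d (nested balls), so the fraction
    is non-increasing once every actual contact is within reach.
    """
    d_grid = list(d_grid_um)
    if any(b <= a for a, b in zip(d_grid, d_grid[1:])) or any(
        d <= 0 for d in d_grid
    ):
        raise ValueError("radius grid must be positive and strictly increasing")
    pruned = prune_terminal_branches(circuit.skeletons[post_neuron])
    return [
        filling_fraction(
            circuit, pre_neuron, post_neuron, d_um=d, post_pruned=pruned,
            step_um=step_um,
        )
        for d in d_grid
    ]
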