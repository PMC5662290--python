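"""Arbor morphometry: cable length, Strahler order, twig/backbone decomposition.

Terminology
-----------
*Cable length* is the summed Euclidean length of parent-child edges, in um.
*Strahler order* labels branches by topological depth: terminal tips are
order 1 and the order increments where two branches of equal order merge, so
the most proximal neurites carry the highest order.
*Twigs* are the microtubule-free, spine-like terminal branches that host most
postsynaptic contacts; the microtubule-containing *backbone* spans the soma
and main branches.  Twig extent is read from "microtubule_end" node tags when
an annotator has placed them (the tag marks the first microtubule-free node),
or approximated topologically as the distal Strahler-order<=k subtrees
("proxy" mode).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .skeletons import CircuitVolume, Skeleton, SkeletonError

__all__ = [
    "MICROTUBULE_END",
    "TwigDecomposition",
    "cable_length",
    "total_cable",
    "strahler",
    "decompose_twigs",
    "inter_twig_distances",
    "cable_by_strahler",
    "geodesic_distances_from",
]

MICROTUBULE_END = "microtubule_end"

NM_PER_UM = 1000.0

TWIG_TABLE_COLUMNS = [
    "twig_id",
    "root_node",
    "n_nodes",
    "cable_um",
    "max_depth_um",
    "n_branch_points",
    "n_inputs",
]


def cable_length(skeleton: Skeleton, node_subset=None) -> float:
    """Cable (um) over edges whose child AND parent both lie in ``node_subset``.

    With ``node_subset=None`` the whole arbor is measured.  An empty subset
    returns 0 with a warning.
    """
    if node_subset is None:
        node_subset = set(skeleton.nodes)
    else:
        node_subset = set(node_subset)
    if not node_subset:
        warnings.warn("cable_length: empty node subset", stacklevel=2)
        return 0.0
    total = 0.0
    for nid in node_subset:
        parent = skeleton.nodes[nid].parent_id
        if parent is not None and parent in node_subset:
            total += skeleton.edge_length_nm(nid)
    return total / NM_PER_UM


def _cable_of_children(skeleton: Skeleton, node_subset: set[int]) -> float:
    """Cable (um) of all parent edges whose child is in ``node_subset``.

    Attributing every edge to its child node makes cable additive over any
    partition of the non-root nodes (used for twig/backbone conservation).
    """
    return (
        sum(skeleton.edge_length_nm(nid) for nid in node_subset) / NM_PER_UM
    )


def total_cable(skeleton: Skeleton) -> float:
    """Total arbor cable in um."""
    return cable_length(skeleton)


def strahler(skeleton: Skeleton) -> dict[int, int]:
    """Strahler order for every node.

    Tips have order 1.  At a junction the order is the maximum child order,
    incremented by one when two or more children attain that maximum.
    Along unbranched stretches the order is inherited unchanged.
    """
    order: dict[int, int] = {}
    ch = skeleton.children()
    # post-order without recursion (trees can be deep)
    for nid in reversed(skeleton.dfs_preorder()):
        kids = ch[nid]
        if not kids:
            order[nid] = 1
        else:
            orders = [order[k] for k in kids]
            top = max(orders)
            order[nid] = top + 1 if orders.count(top) >= 2 else top
    return order


@dataclass
class TwigDecomposition:
    """Result of splitting an arbor into backbone and twigs.

    ``table`` has one row per twig (columns: twig_id, root_node, n_nodes,
    cable_um, max_depth_um, n_branch_points, n_inputs); ``membership`` maps
    every twig node to its twig_id; ``backbone`` is the complementary node
    set.  Twig cable includes the attachment edge from the backbone root to
    the first twig node, so twig cable + backbone cable = total cable.
    """

    neuron_id: str
    mode: str
    table: pd.DataFrame
    membership: dict[int, int]
    backbone: set[int]

    @property
    def n_twigs(self) -> int:
        return len(self.table)

    def twig_nodes(self, twig_id: int) -> set[int]:
        return {n for n, t in self.membership.items() if t == twig_id}

    def twig_of_node(self, node_id: int) -> int | None:
        return self.membership.get(node_id)


def _twig_stats(
    skeleton: Skeleton,
    twig_roots: list[tuple[int, int]],
    inputs_by_node: dict[int, int] | None,
    mode: str,
) -> TwigDecomposition:
    """Build a TwigDecomposition from (backbone_root, first_twig_node) pairs."""
    inputs_by_node = inputs_by_node or {}
    ch = skeleton.children()
    membership: dict[int, int] = {}
    rows = []
    for twig_id, (backbone_root, head) in enumerate(twig_roots):
        nodes = skeleton.subtree_nodes(head)
        overlap = [n for n in nodes if n in membership]
        if overlap:
            raise SkeletonError(
                f"skeleton {skeleton.neuron_id!r}: twig node sets overlap at "
                f"node {overlap[0]}"
            )
        for n in nodes:
            membership[n] = twig_id
        # geodesic depth from the backbone root through the twig
        depth_nm: dict[int, float] = {backbone_root: 0.0}
        stack = [head]
        depth_nm[head] = skeleton.edge_length_nm(head)
        while stack:
            cur = stack.pop()
            for k in ch[cur]:
                depth_nm[k] = depth_nm[cur] + skeleton.edge_length_nm(k)
                stack.append(k)
        rows.append(
            {
                "twig_id": twig_id,
                "root_node": backbone_root,
                "n_nodes": len(nodes),
                "cable_um": _cable_of_children(skeleton, nodes),
                "max_depth_um": max(depth_nm[n] for n in nodes) / NM_PER_UM,
                "n_branch_points": sum(1 for n in nodes if len(ch[n]) >= 2),
                "n_inputs": sum(inputs_by_node.get(n, 0) for n in nodes),
            }
        )
    backbone = set(skeleton.nodes) - set(membership)
    table = pd.DataFrame(rows, columns=TWIG_TABLE_COLUMNS)
    return TwigDecomposition(
        neuron_id=skeleton.neuron_id,
        mode=mode,
        table=table,
        membership=membership,
        backbone=backbone,
    )


def decompose_twigs(
    skeleton: Skeleton,
    mode: str = "tags",
    proxy_max_order: int = 1,
    inputs_by_node: dict[int, int] | None = None,
) -> TwigDecomposition:
    """Partition the arbor into microtubule backbone and terminal twigs.

    mode="tags"
        Every node tagged "microtubule_end" starts a twig: the twig is that
        node plus all its descendants, rooted on its (backbone) parent.  Tags
        nested inside another tagged subtree are ignored.  Raises if the
        skeleton carries no tags at all (advise proxy mode); a skeleton with
        tags but no microtubule_end labels yields an empty decomposition
        (pure backbone).
    mode="proxy"
        Automated topological stand-in where manual microtubule annotations
        are unavailable: twigs are the maximal distal subtrees of Strahler
        order <= proxy_max_order.  With the default k=1 these are exactly the
        terminal branches.  Outputs are labeled with the mode used.

    ``inputs_by_node`` (postsynaptic contact counts per node, from
    :meth:`CircuitVolume.inputs_by_node`) fills the per-twig synapse column.
    """
    skeleton.validate()
    if mode == "tags":
        if not skeleton.tags:
            raise SkeletonError(
                f"skeleton {skeleton.neuron_id!r} has no node tags; twig "
                "decomposition needs 'microtubule_end' annotations — "
                "use mode='proxy' for a topological approximation"
            )
        tagged = skeleton.tagged(MICROTUBULE_END)
        heads = []
        for nid in sorted(tagged):
            if skeleton.nodes[nid].parent_id is None:
                raise SkeletonError(
                    f"skeleton {skeleton.neuron_id!r}: root node {nid} tagged "
                    "microtubule_end (whole arbor would be twig)"
                )
            heads.append(nid)
        # drop tags nested within another tagged subtree
        maximal = []
        for nid in heads:
            cur = skeleton.nodes[nid].parent_id
            nested = False
            while cur is not None:
                if cur in tagged:
                    nested = True
                    break
                cur = skeleton.nodes[cur].parent_id
            if not nested:
                maximal.append(nid)
        roots = [(skeleton.nodes[h].parent_id, h) for h in maximal]
        return _twig_stats(skeleton, roots, inputs_by_node, "tags")
    elif mode == "proxy":
        order = strahler(skeleton)
        k = proxy_max_order
        roots = []
        for nid in skeleton.dfs_preorder():
            parent = skeleton.nodes[nid].parent_id
            if parent is None:
                continue  # component containing the root stays backbone
            if order[nid] <= k and order[parent] > k:
                roots.append((parent, nid))
        return _twig_stats(skeleton, roots, inputs_by_node, "proxy")
    raise ValueError(f"unknown twig decomposition mode {mode!r}")


def geodesic_distances_from(
    skeleton: Skeleton, source: int, targets: set[int] | None = None
) -> dict[int, float]:
    """Geodesic (along-cable) distance in um from ``source`` to every node
    (or to ``targets`` only).  Tree metric: unique paths, single traversal.
    """
    ch = skeleton.children()
    dist: dict[int, float] = {source: 0.0}
    stack = [source]
    while stack:
        cur = stack.pop()
        node = skeleton.nodes[cur]
        neighbours = list(ch[cur])
        if node.parent_id is not None:
            neighbours.append(node.parent_id)
        for nb in neighbours:
            if nb not in dist:
                # the edge between cur and nb is stored on whichever is the child
                dist[nb] = dist[cur] + (
                    skeleton.edge_length_nm(nb)
                    if skeleton.nodes[nb].parent_id == cur
                    else skeleton.edge_length_nm(cur)
                )
                stack.append(nb)
    if targets is not None:
        return {t: dist[t] / NM_PER_UM for t in targets}
    return {k: v / NM_PER_UM for k, v in dist.items()}


def inter_twig_distances(
    skeleton: Skeleton, decomposition: TwigDecomposition
) -> list[float]:
    """Along-backbone geodesic distance (um) from each twig root to the
    nearest other twig root.  Fewer than 2 twigs yields an empty list.
    Twigs sharing a backbone root are at distance 0 of each other.
    """
    roots = list(decomposition.table["root_node"])
    if len(roots) < 2:
        return []
    out = []
    for r in roots:
        others = [x for x in roots if x != r]
        if len(others) < len(roots) - 1:
            # another twig shares this backbone root
            out.append(0.0)
            continue
        d = geodesic_distances_from(skeleton, r, targets=set(others))
        out.append(min(d.values()))
    return out


def cable_by_strahler(skeleton: Skeleton) -> dict[int, float]:
    """Fraction of total cable at each Strahler order.

    An edge is attributed the order of its child node.  Fractions sum to 1.
    """
    order = strahler(skeleton)
    cable: dict[int, float] = {}
    for _, child in skeleton.edges():
        cable[order[child]] = cable.get(order[child], 0.0) + skeleton.edge_length_nm(
            child
        )
    total = sum(cable.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in sorted(cable.items())}


# ---------------------------------------------------------------------------
# Circuit-level summaries
# ---------------------------------------------------------------------------

def morphometry_summary(
    circuit: CircuitVolume,
    twig_mode: str = "tags",
) -> pd.DataFrame:
    """Per-neuron morphometry: cable, twig counts/cable, backbone cable,
    fraction of inputs on twigs, median inter-twig spacing."""
    rows = []
    for nid in sorted(circuit.skeletons):
        skel = circuit.skeletons[nid]
        inputs = circuit.inputs_by_node(nid)
        dec = decompose_twigs(skel, mode=twig_mode, inputs_by_node=inputs)
        spacing = inter_twig_distances(skel, dec)
        n_inputs = sum(inputs.values())
        on_twigs = int(dec.table["n_inputs"].sum()) if dec.n_twigs else 0
        rows.append(
            {
                "neuron_id": nid,
                "cell_type": skel.cell_type,
                "side": skel.side,
                "stage": skel.stage,
                "cable_um": total_cable(skel),
                "n_twigs": dec.n_twigs,
                "twig_cable_um": float(dec.table["cable_um"].sum()),
                "backbone_cable_um": _cable_of_children(skel, dec.backbone),
                "n_inputs": n_inputs,
                "frac_inputs_on_twigs": (on_twigs / n_inputs) if n_inputs else np.nan,
                "median_inter_twig_um": (
                    float(np.median(spacing)) if spacing else np.nan
                ),
                "twig_mode": dec.mode,
            }
        )
    return pd.DataFrame(rows)
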