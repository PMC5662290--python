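"""Axon-dendrite compartment splitting by synaptic segregation.

Many interneurons separate synaptic input and output spatially on the arbor.
Cutting one tree edge splits the arbor into two components; the cut is chosen
to maximize an entropy-based segregation index S:

    S = 1 - [ sum_i N_i H(p_i) ] / [ N H(p) ],   H(q) = -q ln q - (1-q) ln(1-q)

where, per compartment i, N_i is the total number of synaptic contacts
(inputs + outputs) and p_i the fraction of them that are inputs, and N, p are
the same quantities over the whole arbor.  S = 0 when both compartments mix
inputs and outputs in the global ratio; S = 1 when each compartment is pure.
The compartment with the higher input fraction is labeled dendrite.

If the arbor carries only inputs or only outputs globally (H(p) = 0) the
index is undefined and the whole arbor is treated as a single dendrite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .skeletons import CircuitVolume, Skeleton, SkeletonError

__all__ = [
    "SegregationResult",
    "binary_entropy",
    "segregation_index",
    "split_axon_dendrite",
    "POORLY_SEGREGATED_THRESHOLD",
]

#: below this optimal S a split is flagged as poorly segregated
POORLY_SEGREGATED_THRESHOLD = 0.05


def binary_entropy(q: float) -> float:
    """H(q) = -q ln q - (1-q) ln(1-q), with 0 ln 0 = 0.  Natural log."""
    if q <= 0.0 or q >= 1.0:
        return 0.0
    return -q * math.log(q) - (1.0 - q) * math.log(1.0 - q)


def segregation_index(
    n_axon: float, p_axon: float, n_dendrite: float, p_dendrite: float
) -> float:
    """Entropy-ratio segregation index for a two-compartment split.

    Returns NaN when the whole arbor is of a single polarity (global binary
    entropy zero), where segregation is undefined.
    """
    n = n_axon + n_dendrite
    if n <= 0:
        raise ValueError("segregation_index: no synaptic contacts")
    p = (n_axon * p_axon + n_dendrite * p_dendrite) / n
    h_total = binary_entropy(p)
    if h_total == 0.0:
        return math.nan
    h_within = (n_axon * binary_entropy(p_axon) + n_dendrite * binary_entropy(p_dendrite)) / n
    s = 1.0 - h_within / h_total
    # clamp tiny negative float error
    return min(1.0, max(0.0, s))


@dataclass
class SegregationResult:
    """Outcome of the optimal single-edge axon/dendrite split."""

    neuron_id: str
    split_edge: tuple[int, int] | None  # (parent, child); None = unsplit
    n_axon: int
    p_axon: float
    n_dendrite: int
    p_dendrite: float
    n_total: int
    p_total: float
    segregation: float  # S of the chosen split (NaN if undefined)
    poorly_segregated: bool


def split_axon_dendrite(
    skeleton: Skeleton,
    inputs_by_node: dict[int, int],
    outputs_by_node: dict[int, int],
) -> tuple[set[int], set[int], SegregationResult]:
    """Find the single tree edge whose removal best segregates inputs from
    outputs, and label the two components.

    Returns ``(dendrite_nodes, axon_nodes, result)``.  The dendrite is the
    component with the higher input fraction.  Candidate splits are all tree
    edges; ties in S are broken toward the more cable-balanced split.  Raises
    if the arbor has no synaptic contacts at all; with contacts of a single
    polarity only, S is undefined and the unsplit arbor is labeled dendrite.
    """
    skeleton.validate()
    n_in_total = sum(inputs_by_node.values())
    n_out_total = sum(outputs_by_node.values())
    n_total = n_in_total + n_out_total
    if n_total == 0:
        raise SkeletonError(
            f"skeleton {skeleton.neuron_id!r}: cannot split an arbor with no synapses"
        )
    p_total = n_in_total / n_total

    all_nodes = set(skeleton.nodes)
    if n_in_total == 0 or n_out_total == 0:
        res = SegregationResult(
            neuron_id=skeleton.neuron_id,
            split_edge=None,
            n_axon=0,
            p_axon=math.nan,
            n_dendrite=n_total,
            p_dendrite=p_total,
            n_total=n_total,
            p_total=p_total,
            segregation=math.nan,
            poorly_segregated=False,
        )
        return all_nodes, set(), res

    # subtree input/output/cable accumulated in post-order
    order = skeleton.dfs_preorder()
    sub_in: dict[int, int] = {}
    sub_out: dict[int, int] = {}
    sub_cable: dict[int, float] = {}
    ch = skeleton.children()
    for nid in reversed(order):
        sub_in[nid] = inputs_by_node.get(nid, 0) + sum(sub_in[k] for k in ch[nid])
        sub_out[nid] = outputs_by_node.get(nid, 0) + sum(sub_out[k] for k in ch[nid])
        sub_cable[nid] = skeleton.edge_length_nm(nid) + sum(
            sub_cable[k] for k in ch[nid]
        )
    total_cable = sub_cable[skeleton.root]

    best: tuple[float, float, int] | None = None  # (-S, cable imbalance, child)
    for nid in order:
        if skeleton.nodes[nid].parent_id is None:
            continue
        in_a, out_a = sub_in[nid], sub_out[nid]
        in_b, out_b = n_in_total - in_a, n_out_total - out_a
        n_a, n_b = in_a + out_a, in_b + out_b
        if n_a == 0 or n_b == 0:
            # an empty compartment is never better than the unsplit arbor;
            # S would equal 0 here, keep as valid but weak candidate
            s = 0.0
        else:
            s = segregation_index(n_a, in_a / n_a, n_b, in_b / n_b)
        imbalance = abs(total_cable - 2.0 * sub_cable[nid])
        key = (-s, imbalance, nid)
        if best is None or key < best:
            best = key
    assert best is not None
    s_best = -best[0]
    child = best[2]
    comp_a = skeleton.subtree_nodes(child)
    comp_b = all_nodes - comp_a

    def stats(nodes: set[int]) -> tuple[int, float]:
        n_in = sum(inputs_by_node.get(n, 0) for n in nodes)
        n_out = sum(outputs_by_node.get(n, 0) for n in nodes)
        n = n_in + n_out
        return n, (n_in / n) if n else math.nan

    n_a, p_a = stats(comp_a)
    n_b, p_b = stats(comp_b)
    # dendrite = component with higher input fraction
    if (p_a if not math.isnan(p_a) else -1.0) >= (p_b if not math.isnan(p_b) else -1.0):
        dendrite, axon = comp_a, comp_b
        n_den, p_den, n_ax, p_ax = n_a, p_a, n_b, p_b
    else:
        dendrite, axon = comp_b, comp_a
        n_den, p_den, n_ax, p_ax = n_b, p_b, n_a, p_a

    res = SegregationResult(
        neuron_id=skeleton.neuron_id,
        split_edge=(skeleton.nodes[child].parent_id, child),
        n_axon=n_ax,
        p_axon=p_ax,
        n_dendrite=n_den,
        p_dendrite=p_den,
        n_total=n_total,
        p_total=p_total,
        segregation=s_best,
        poorly_segregated=s_best < POORLY_SEGREGATED_THRESHOLD,
    )
    return dendrite, axon, res


def split_circuit(
    circuit: CircuitVolume,
) -> dict[str, tuple[set[int], set[int], SegregationResult]]:
    """Split every neuron in a circuit that carries at least one synapse."""
    out = {}
    for nid in sorted(circuit.skeletons):
        inputs = circuit.inputs_by_node(nid)
        outputs = circuit.outputs_by_node(nid)
        if not inputs and not outputs:
            continue
        out[nid] = split_axon_dendrite(circuit.skeletons[nid], inputs, outputs)
    return out
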