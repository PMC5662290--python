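"""Synthetic paired-stage circuit generator.

Generates two :class:`~arborscale.skeletons.CircuitVolume` objects emulating
the statistical structure of a nociceptive circuit reconstructed at two
larval stages: sensory axon terminals (three cell types per side) presynaptic
to a population of local interneurons (LNs), with

* skeletons built as branching random walks inside a calibrated neuropile
  box, with a microtubule backbone and short, spine-like twigs sprouting from
  it at a set density (twig roots carry the "microtubule_end" tag and the
  true membership is recorded);
* dendritic input contacts whose presynaptic sources realize a target
  normalized-input matrix in expectation, grouped into polyadic connectors
  with a configurable posts-per-site distribution;
* per-connection synapse placement that concentrates 1-2 contacts per twig;
* stage-to-stage scaling by configurable fold factors (total dendritic cable,
  dendritic inputs, twig count, backbone cable, spatial span).

Every generated quantity is recorded in truth tables so each analysis stage
of the pipeline can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeletons import (
    CircuitVolume,
    Connector,
    Skeleton,
    SkeletonError,
    SkeletonNode,
)
from .morphometry import MICROTUBULE_END

__all__ = [
    "GrowthSpec",
    "GeneratedNeuron",
    "PairTruth",
    "default_normalized_input",
    "generate_neuron",
    "generate_circuit_pair",
    "planted_filling_instance",
]

NM_PER_UM = 1000.0

MDIV_TYPES = ("v'ada", "vdaB", "ddaC")
SIDES = ("L", "R")
DEFAULT_LN_TYPES = ("A09a", "A09c", "A02n", "A10a")


def default_normalized_input() -> pd.DataFrame:
    """Target normalized-input matrix for a RIGHT-side LN of each type.

    Rows are the six sensory terminals labeled by body-wall field
    (ipsilateral = _R for a right-side cell); columns are LN types.  Entries
    are the fraction of the LN's total dendritic input contributed by that
    terminal; the remainder (1 - column sum) comes from unmodeled background
    partners.  Left-side LNs use the mirror image.
    """
    data = {
        "A09a": [0.16, 0.12, 0.08, 0.03, 0.04, 0.06],
        "A09c": [0.10, 0.14, 0.12, 0.04, 0.05, 0.04],
        "A02n": [0.12, 0.10, 0.10, 0.04, 0.04, 0.05],
        "A10a": [0.08, 0.08, 0.14, 0.05, 0.03, 0.03],
    }
    index = ["v'ada_R", "vdaB_R", "ddaC_R", "ddaC_L", "vdaB_L", "v'ada_L"]
    return pd.DataFrame(data, index=index)


@dataclass
class GrowthSpec:
    """Study conditions for the paired-circuit generator.

    Stage-1 values describe one LN dendrite of a first-instar-like circuit;
    stage 2 is derived through the fold factors.  Lengths in um.
    """

    # -- stage-1 LN dendrite ------------------------------------------------
    backbone_cable_um: float = 50.0
    twig_density_per_um: float = 1.2  # expected spacing ~0.83 um
    twig_mean_cable_um: float = 0.8
    n_inputs: int = 100
    frac_inputs_on_twigs: tuple[float, float] = (0.80, 0.90)
    # -- stage-1 LN axon ----------------------------------------------------
    axon_cable_um: float = 25.0
    n_axon_outputs: int = 30
    # -- stage-1 sensory terminals -----------------------------------------
    mdiv_cable_um: float = 30.0
    # -- distributions ------------------------------------------------------
    posts_per_site_lambda: float = 1.5  # posts = 1 + Poisson(lambda)
    synapses_per_twig_probs: tuple[float, float] = (0.80, 0.15)  # P(1), P(2)
    synapses_per_twig_tail: float = 0.5  # geometric decay beyond 2
    polarity_noise: float = 0.02  # inputs on axon / outputs on dendrite
    # -- stage-to-stage fold factors ---------------------------------------
    fold_cable: float = 5.0  # total dendritic cable
    fold_inputs: float = 5.0  # dendritic input contacts
    fold_twigs: float = 2.7  # twig count
    fold_backbone_cable: float = 3.31
    fold_axon: float = 2.15  # axon cable and outputs
    # -- geometry / calibration --------------------------------------------
    neuropile_width_um: tuple[float, float] = (43.0, 72.0)
    segment_length_um: tuple[float, float] = (15.0, 27.0)
    backbone_step_um: float = 0.5
    twig_step_um: float = 0.25
    branch_prob: float = 0.05  # per backbone growth step
    site_grouping_radius_um: float = 2.5  # polyadic contacts grouped locally
    # -- circuit ------------------------------------------------------------
    ln_types: tuple[str, ...] = DEFAULT_LN_TYPES
    normalized_input: pd.DataFrame | None = None
    stage_labels: tuple[str, str] = ("stage1", "stage2")
    seed: int = 0

    def target_matrix(self) -> pd.DataFrame:
        w = (
            default_normalized_input()
            if self.normalized_input is None
            else self.normalized_input
        )
        w = w.loc[:, list(self.ln_types)]
        if (w.values < 0).any() or (w.values > 1).any():
            raise SkeletonError("normalized-input entries must lie in [0, 1]")
        bad = w.sum(axis=0)
        if (bad > 1.0 + 1e-9).any():
            raise SkeletonError(
                "infeasible normalized-input matrix: input fractions for "
                f"{list(bad[bad > 1].index)} sum to more than 1"
            )
        return w

    def validate(self) -> "GrowthSpec":
        if self.backbone_cable_um <= 0 or self.mdiv_cable_um <= 0:
            raise SkeletonError("degenerate growth spec: zero cable")
        if self.twig_density_per_um < 0 or self.twig_mean_cable_um <= 0:
            raise SkeletonError("twig density/size must be nonnegative/positive")
        for f in (
            self.fold_cable,
            self.fold_inputs,
            self.fold_twigs,
            self.fold_backbone_cable,
            self.fold_axon,
        ):
            if f <= 0:
                raise SkeletonError("fold factors must be positive")
        p1, p2 = self.synapses_per_twig_probs
        if p1 < 0 or p2 < 0 or p1 + p2 > 1 or not 0 < self.synapses_per_twig_tail < 1:
            raise SkeletonError("improper synapses-per-twig distribution")
        self.target_matrix()
        return self

    # -- derived stage parameters ------------------------------------------

    def stage_params(self, stage: int) -> dict:
        """Resolved geometry/size parameters for stage index 0 or 1."""
        if stage not in (0, 1):
            raise ValueError("stage index must be 0 or 1")
        b1 = self.backbone_cable_um
        twigs1 = self.twig_density_per_um * b1
        twig_cable1 = twigs1 * self.twig_mean_cable_um
        total1 = b1 + twig_cable1
        if stage == 0:
            backbone, n_twig_mean, twig_mean = b1, twigs1, self.twig_mean_cable_um
        else:
            backbone = b1 * self.fold_backbone_cable
            n_twig_mean = twigs1 * self.fold_twigs
            twig_cable2 = self.fold_cable * total1 - backbone
            if twig_cable2 <= 0:
                raise SkeletonError(
                    "infeasible fold factors: backbone fold exceeds total-cable fold"
                )
            twig_mean = twig_cable2 / n_twig_mean if n_twig_mean else 0.0
        span = 1.0 if stage == 0 else (
            self.neuropile_width_um[1] / self.neuropile_width_um[0]
        )
        return {
            "backbone_cable_um": backbone,
            "twig_density_per_um": (n_twig_mean / backbone) if backbone else 0.0,
            "twig_mean_cable_um": twig_mean,
            "n_inputs": int(round(self.n_inputs * (self.fold_inputs if stage else 1))),
            "frac_on_twigs": self.frac_inputs_on_twigs[stage],
            "axon_cable_um": self.axon_cable_um * (self.fold_axon if stage else 1),
            "n_axon_outputs": int(
                round(self.n_axon_outputs * (self.fold_axon if stage else 1))
            ),
            "mdiv_cable_um": self.mdiv_cable_um * span,
            "box_um": (
                self.neuropile_width_um[stage],
                self.segment_length_um[stage],
                0.6 * self.neuropile_width_um[stage],
            ),
            "stage_label": self.stage_labels[stage],
        }


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


class _Builder:
    """Incremental skeleton builder with integer node ids."""

    def __init__(self) -> None:
        self.nodes: dict[int, SkeletonNode] = {}
        self.tags: dict[int, set[str]] = {}
        self._next = 0

    def add(self, parent: int | None, xyz: np.ndarray) -> int:
        nid = self._next
        self._next += 1
        self.nodes[nid] = SkeletonNode(
            node_id=nid, parent_id=parent, x=float(xyz[0]), y=float(xyz[1]),
            z=float(xyz[2]),
        )
        return nid

    def tag(self, nid: int, label: str) -> None:
        self.tags.setdefault(nid, set()).add(label)


def _branching_walk(
    builder: _Builder,
    rng: np.random.Generator,
    root: int,
    target_cable_um: float,
    step_um: float,
    branch_prob: float,
    box_nm: np.ndarray,
) -> list[int]:
    """Grow a persistent branching random walk from ``root`` until the target
    cable is laid down; returns the new node ids (excluding the root)."""
    step_nm = step_um * NM_PER_UM
    tips: list[tuple[int, np.ndarray]] = [(root, _unit(rng.normal(size=3)))]
    created: list[int] = []
    cable = 0.0
    while cable < target_cable_um:
        idx = int(rng.integers(len(tips)))
        nid, direction = tips[idx]
        direction = _unit(direction + 0.45 * rng.normal(size=3))
        pos = builder.nodes[nid].xyz + direction * step_nm
        # reflect into the box
        for ax in range(3):
            if pos[ax] < 0:
                pos[ax] = -pos[ax]
                direction[ax] = -direction[ax]
            elif pos[ax] > box_nm[ax]:
                pos[ax] = 2 * box_nm[ax] - pos[ax]
                direction[ax] = -direction[ax]
        new = builder.add(nid, pos)
        created.append(new)
        tips[idx] = (new, direction)
        cable += step_um
        if rng.random() < branch_prob and created:
            origin = int(created[int(rng.integers(len(created)))])
            tips.append((origin, _unit(rng.normal(size=3))))
    return created


def _grow_twig(
    builder: _Builder,
    rng: np.random.Generator,
    attach: int,
    cable_um: float,
    step_um: float,
    box_nm: np.ndarray,
) -> list[int]:
    """Grow one microtubule-free twig below backbone node ``attach``; the
    first twig node carries the microtubule_end tag."""
    step_nm = step_um * NM_PER_UM
    direction = _unit(rng.normal(size=3))
    head = builder.add(attach, builder.nodes[attach].xyz + direction * step_nm)
    builder.tag(head, MICROTUBULE_END)
    created = [head]
    n_extra = max(0, int(round(cable_um / step_um)) - 1)
    tips = [(head, direction)]
    for _ in range(n_extra):
        idx = int(rng.integers(len(tips)))
        nid, d = tips[idx]
        d = _unit(d + 0.8 * rng.normal(size=3))
        new = builder.add(nid, builder.nodes[nid].xyz + d * step_nm)
        created.append(new)
        tips[idx] = (new, d)
        if rng.random() < 0.15:
            tips.append((new, _unit(rng.normal(size=3))))
    return created


@dataclass
class GeneratedNeuron:
    """A generated skeleton plus its ground truth."""

    skeleton: Skeleton
    dendrite_nodes: set[int] = field(default_factory=set)
    axon_nodes: set[int] = field(default_factory=set)
    backbone_nodes: set[int] = field(default_factory=set)  # dendritic backbone
    twig_membership: dict[int, int] = field(default_factory=dict)
    twig_root_of: dict[int, int] = field(default_factory=dict)  # twig -> backbone node

    @property
    def n_twigs(self) -> int:
        return len(self.twig_root_of)

    def twig_nodes(self, twig_id: int) -> list[int]:
        return sorted(n for n, t in self.twig_membership.items() if t == twig_id)


def generate_neuron(
    spec: GrowthSpec,
    stage: int,
    cell_type: str,
    side: str,
    rng: np.random.Generator,
    kind: str = "ln",
    origin_um: np.ndarray | None = None,
) -> GeneratedNeuron:
    """Generate one neuron for a stage.

    kind="ln": soma root with a dendritic backbone carrying twigs (tagged
    ground truth) and a separate axonal subtree.  kind="mdiv": a bare axon
    terminal (backbone only) that will host presynaptic sites.
    """
    spec.validate()
    params = spec.stage_params(stage)
    box_nm = np.array(params["box_um"]) * NM_PER_UM
    builder = _Builder()
    if origin_um is None:
        origin = box_nm * rng.uniform(0.25, 0.75, size=3)
    else:
        origin = np.asarray(origin_um) * NM_PER_UM
    root = builder.add(None, origin)
    builder.tag(root, "soma")
    neuron_id = f"{cell_type}_{side}_{params['stage_label']}"

    if kind == "mdiv":
        created = _branching_walk(
            builder, rng, root, params["mdiv_cable_um"], spec.backbone_step_um,
            spec.branch_prob, box_nm,
        )
        skel = Skeleton(
            neuron_id=neuron_id, nodes=builder.nodes, tags=builder.tags,
            cell_type=cell_type, side=side, stage=params["stage_label"],
        ).validate()
        nodes = {root, *created}
        return GeneratedNeuron(skeleton=skel, axon_nodes=nodes)

    dendrite_backbone = _branching_walk(
        builder, rng, root, params["backbone_cable_um"], spec.backbone_step_um,
        spec.branch_prob, box_nm,
    )
    axon = _branching_walk(
        builder, rng, root, params["axon_cable_um"], spec.backbone_step_um,
        spec.branch_prob, box_nm,
    )
    backbone_nodes = set(dendrite_backbone)
    # sprout twigs along the dendritic backbone
    n_twigs = int(rng.poisson(params["twig_density_per_um"] * params["backbone_cable_um"]))
    membership: dict[int, int] = {}
    twig_root_of: dict[int, int] = {}
    mean_cable = params["twig_mean_cable_um"]
    # distinct attachment nodes keep twig roots spread along the cable;
    # fall back to reuse only if twigs outnumber backbone nodes
    if n_twigs <= len(dendrite_backbone):
        attach_nodes = rng.choice(
            np.asarray(dendrite_backbone), size=n_twigs, replace=False
        )
    else:
        attach_nodes = rng.choice(
            np.asarray(dendrite_backbone), size=n_twigs, replace=True
        )
    for t in range(n_twigs):
        attach = int(attach_nodes[t])
        cable = max(spec.twig_step_um, rng.exponential(mean_cable))
        for nid in _grow_twig(builder, rng, attach, cable, spec.twig_step_um, box_nm):
            membership[nid] = t
        twig_root_of[t] = attach
    skel = Skeleton(
        neuron_id=neuron_id, nodes=builder.nodes, tags=builder.tags,
        cell_type=cell_type, side=side, stage=params["stage_label"],
    ).validate()
    return GeneratedNeuron(
        skeleton=skel,
        dendrite_nodes={root, *dendrite_backbone, *membership},
        axon_nodes=set(axon),
        backbone_nodes={root, *backbone_nodes},
        twig_membership=membership,
        twig_root_of=twig_root_of,
    )


# ---------------------------------------------------------------------------
# synapse placement
# ---------------------------------------------------------------------------

def _sample_group_size(spec: GrowthSpec, rng: np.random.Generator) -> int:
    """Synapses placed together on one twig: P(1), P(2), geometric tail."""
    p1, p2 = spec.synapses_per_twig_probs
    u = rng.random()
    if u < p1:
        return 1
    if u < p1 + p2:
        return 2
    k = 3
    while rng.random() < spec.synapses_per_twig_tail:
        k += 1
    return k


def _place_connection_contacts(
    spec: GrowthSpec,
    neuron: GeneratedNeuron,
    n_contacts: int,
    frac_on_twigs: float,
    rng: np.random.Generator,
) -> list[int]:
    """Target nodes on one LN for all contacts of a single connection.

    Contacts go to twigs in groups of 1-2 (per the synapses-per-twig
    distribution), each group on a distinct random twig where possible; a
    small share lands on dendritic backbone, and polarity noise puts a few
    on the axon.
    """
    targets: list[int] = []
    backbone = sorted(neuron.backbone_nodes)
    axon = sorted(neuron.axon_nodes)
    n_twig_contacts = 0
    remaining = n_contacts
    on_twig_total = sum(
        1
        for _ in range(n_contacts)
        if rng.random() < frac_on_twigs and neuron.n_twigs > 0
    )
    off_twig = n_contacts - on_twig_total
    # twig groups
    twig_ids = list(neuron.twig_root_of)
    unused = list(twig_ids)
    while n_twig_contacts < on_twig_total:
        size = min(_sample_group_size(spec, rng), on_twig_total - n_twig_contacts)
        if unused:
            t = unused.pop(int(rng.integers(len(unused))))
        else:
            t = twig_ids[int(rng.integers(len(twig_ids)))]
        nodes = neuron.twig_nodes(t)
        for _ in range(size):
            targets.append(int(nodes[int(rng.integers(len(nodes)))]))
        n_twig_contacts += size
    # backbone / polarity-noise contacts
    for _ in range(off_twig):
        if axon and rng.random() < spec.polarity_noise:
            targets.append(int(axon[int(rng.integers(len(axon)))]))
        else:
            targets.append(int(backbone[int(rng.integers(len(backbone)))]))
    assert remaining == len(targets)
    rng.shuffle(targets)
    return targets


def _mirror_label(label: str) -> str:
    if label.endswith("_L"):
        return label[:-2] + "_R"
    if label.endswith("_R"):
        return label[:-2] + "_L"
    return label


def _group_into_connectors(
    spec: GrowthSpec,
    rng: np.random.Generator,
    pre_id: str,
    pre_skel: Skeleton,
    contacts: list[tuple[str, int, np.ndarray]],  # (post neuron, node, xyz nm)
    next_cid: int,
) -> tuple[list[Connector], int]:
    """Partition a presynaptic neuron's contacts into polyadic release sites.

    Site size is 1 + Poisson(lambda).  Contacts of one site are grouped by
    spatial proximity (a release site's postsynaptic elements all abut the
    same bouton), seeded at a random contact and filled with its nearest
    ungrouped contacts within the grouping radius.  The site sits next to its
    seed contact; the presynaptic treenode is the nearest node of the
    presynaptic skeleton.
    """
    from scipy.spatial import cKDTree

    pre_ids = sorted(pre_skel.nodes)
    tree = cKDTree(pre_skel.coords(pre_ids))
    xyz = np.array([c[2] for c in contacts])
    unused = list(rng.permutation(len(contacts)))
    used = np.zeros(len(contacts), dtype=bool)
    radius_nm = spec.site_grouping_radius_um * NM_PER_UM
    out: list[Connector] = []
    for seed in unused:
        if used[seed]:
            continue
        size = 1 + int(rng.poisson(spec.posts_per_site_lambda))
        members = [seed]
        used[seed] = True
        if size > 1:
            d = np.linalg.norm(xyz - xyz[seed], axis=1)
            d[used] = np.inf
            candidates = np.argsort(d)[: size - 1]
            for c in candidates:
                if np.isfinite(d[c]) and d[c] <= radius_nm:
                    members.append(int(c))
                    used[c] = True
        loc = xyz[seed] + rng.normal(scale=50.0, size=3)  # ~50 nm jitter
        _, nearest = tree.query(loc)
        out.append(
            Connector(
                connector_id=next_cid,
                pre=(pre_id, int(pre_ids[int(nearest)])),
                posts=[(contacts[j][0], int(contacts[j][1])) for j in members],
                location=(float(loc[0]), float(loc[1]), float(loc[2])),
            )
        )
        next_cid += 1
    return out, next_cid


@dataclass
class PairTruth:
    """Ground truth recorded while generating a circuit pair."""

    spec: GrowthSpec
    target_matrix: pd.DataFrame  # right-side frame labels x LN types
    per_neuron: pd.DataFrame  # one row per generated LN per stage
    source_counts: pd.DataFrame  # stage, ln, source label, contacts
    generated: dict[str, GeneratedNeuron]  # all neurons, both stages


def generate_circuit_pair(
    spec: GrowthSpec | None = None, seed: int | None = None
) -> tuple[CircuitVolume, CircuitVolume, PairTruth]:
    """Generate matched circuits for two developmental stages.

    Stage 2 differs from stage 1 by the spec's fold factors while realizing
    the same target normalized-input matrix, so every pipeline comparison has
    a known expected value.
    """
    spec = (spec or GrowthSpec()).validate()
    seed = spec.seed if seed is None else seed
    master = np.random.SeedSequence(seed)
    rng_stage = [
        np.random.default_rng(s) for s in master.spawn(2)
    ]
    w_right = spec.target_matrix()
    circuits: list[CircuitVolume] = []
    truth_rows = []
    source_rows = []
    generated: dict[str, GeneratedNeuron] = {}

    for stage in (0, 1):
        rng = rng_stage[stage]
        params = spec.stage_params(stage)
        label = params["stage_label"]
        skeletons: dict[str, Skeleton] = {}
        neurons: dict[str, GeneratedNeuron] = {}

        # sensory terminals: one per type per side, labeled by body-wall field
        mdiv_ids = {}
        for mtype in MDIV_TYPES:
            for side in SIDES:
                gn = generate_neuron(spec, stage, mtype, side, rng, kind="mdiv")
                skeletons[gn.skeleton.neuron_id] = gn.skeleton
                neurons[gn.skeleton.neuron_id] = gn
                mdiv_ids[f"{mtype}_{side}"] = gn.skeleton.neuron_id
        # background partners, one per side
        bg_ids = {}
        for side in SIDES:
            gn = generate_neuron(spec, stage, "background", side, rng, kind="mdiv")
            skeletons[gn.skeleton.neuron_id] = gn.skeleton
            neurons[gn.skeleton.neuron_id] = gn
            bg_ids[side] = gn.skeleton.neuron_id
        # local interneurons
        ln_ids = []
        for ltype in spec.ln_types:
            for side in SIDES:
                gn = generate_neuron(spec, stage, ltype, side, rng, kind="ln")
                skeletons[gn.skeleton.neuron_id] = gn.skeleton
                neurons[gn.skeleton.neuron_id] = gn
                ln_ids.append(gn.skeleton.neuron_id)

        # dendritic input contacts per LN: source ~ target matrix
        contacts_by_pre: dict[str, list[tuple[str, int, np.ndarray]]] = {
            nid: [] for nid in list(mdiv_ids.values()) + list(bg_ids.values())
        }
        for ln_id in ln_ids:
            gn = neurons[ln_id]
            skel = gn.skeleton
            w = w_right[skel.cell_type]
            if skel.side == "L":
                w = w.rename(index=_mirror_label)
            labels = list(w.index)
            probs = list(w.values)
            labels.append("background")
            probs.append(max(0.0, 1.0 - sum(probs)))
            n_in = params["n_inputs"]
            counts = rng.multinomial(n_in, np.asarray(probs) / sum(probs))
            for src_label, c in zip(labels, counts):
                if c == 0:
                    continue
                if src_label == "background":
                    pre_id = bg_ids[skel.side]
                else:
                    pre_id = mdiv_ids[src_label]
                nodes = _place_connection_contacts(
                    spec, gn, int(c), params["frac_on_twigs"], rng
                )
                for node in nodes:
                    contacts_by_pre[pre_id].append(
                        (ln_id, node, skel.nodes[node].xyz)
                    )
                source_rows.append(
                    {
                        "stage": label,
                        "ln": ln_id,
                        "cell_type": skel.cell_type,
                        "side": skel.side,
                        "source": src_label,
                        "contacts": int(c),
                    }
                )

        # polyadic grouping
        connectors: list[Connector] = []
        next_cid = 0
        for pre_id in sorted(contacts_by_pre):
            if not contacts_by_pre[pre_id]:
                continue
            conns, next_cid = _group_into_connectors(
                spec, rng, pre_id, skeletons[pre_id], contacts_by_pre[pre_id],
                next_cid,
            )
            connectors.extend(conns)

        # LN axonal outputs onto the background partner
        for ln_id in ln_ids:
            gn = neurons[ln_id]
            axon = sorted(gn.axon_nodes)
            dend = sorted(gn.dendrite_nodes)
            bg = skeletons[bg_ids[gn.skeleton.side]]
            bg_nodes = sorted(bg.nodes)
            for _ in range(params["n_axon_outputs"]):
                if dend and rng.random() < spec.polarity_noise:
                    site_node = int(dend[int(rng.integers(len(dend)))])
                else:
                    site_node = int(axon[int(rng.integers(len(axon)))])
                loc = gn.skeleton.nodes[site_node].xyz + rng.normal(scale=50.0, size=3)
                n_posts = 1 + int(rng.poisson(spec.posts_per_site_lambda))
                posts = [
                    (bg.neuron_id, int(bg_nodes[int(rng.integers(len(bg_nodes)))]))
                    for _ in range(n_posts)
                ]
                connectors.append(
                    Connector(
                        connector_id=next_cid,
                        pre=(ln_id, site_node),
                        posts=posts,
                        location=(float(loc[0]), float(loc[1]), float(loc[2])),
                    )
                )
                next_cid += 1

        circuit = CircuitVolume(
            stage=label,
            skeletons=skeletons,
            connectors=connectors,
            calibration={
                "neuropile_width_um": spec.neuropile_width_um[stage],
                "segment_length_um": spec.segment_length_um[stage],
            },
        ).validate()
        circuits.append(circuit)
        generated.update(neurons)

        for ln_id in ln_ids:
            gn = neurons[ln_id]
            skel = gn.skeleton
            dend_cable = (
                sum(skel.edge_length_nm(n) for n in gn.dendrite_nodes) / NM_PER_UM
            )
            inputs = circuit.inputs_by_node(ln_id)
            truth_rows.append(
                {
                    "stage": label,
                    "neuron_id": ln_id,
                    "cell_type": skel.cell_type,
                    "side": skel.side,
                    "dendritic_cable_um": dend_cable,
                    "n_twigs": gn.n_twigs,
                    "n_inputs": sum(inputs.values()),
                    "n_inputs_on_twigs": sum(
                        c for n, c in inputs.items() if n in gn.twig_membership
                    ),
                }
            )

    truth = PairTruth(
        spec=spec,
        target_matrix=w_right,
        per_neuron=pd.DataFrame(truth_rows),
        source_counts=pd.DataFrame(source_rows),
        generated=generated,
    )
    return circuits[0], circuits[1], truth


# ---------------------------------------------------------------------------
# planted filling-fraction instance
# ---------------------------------------------------------------------------

def planted_filling_instance(
    q: float = 0.3,
    n_sites: int = 200,
    d_um: float = 2.0,
    seed: int = 0,
) -> tuple[CircuitVolume, str, str]:
    """A minimal two-neuron geometry with a known connection probability.

    The target neuron is a comb: a straight backbone with short side
    branches, so its Strahler-order>=2 core is the backbone itself.  The
    source neuron runs parallel at 1 um offset and hosts ``n_sites``
    presynaptic sites, every one of which is within ``d_um`` of the pruned
    target; each site independently contacts the target with probability q
    (otherwise it contacts a background neuron), so the measured filling
    fraction estimates q.
    """
    rng = np.random.default_rng(seed)
    length_um = 100.0

    post = _Builder()
    spine: list[int] = []
    prev = None
    for i in range(int(length_um) + 1):
        nid = post.add(prev, np.array([i * NM_PER_UM, 0.0, 0.0]))
        spine.append(nid)
        prev = nid
    for i in range(0, int(length_um) + 1, 2):  # side branches force order 2
        post.add(spine[i], np.array([i * NM_PER_UM, 500.0, 0.0]))
    post_skel = Skeleton("post", post.nodes, post.tags).validate()

    pre = _Builder()
    prev = None
    pre_nodes = []
    for i in range(int(length_um) + 1):
        nid = pre.add(prev, np.array([i * NM_PER_UM, 1000.0, 0.0]))
        pre_nodes.append(nid)
        prev = nid
    pre_skel = Skeleton("pre", pre.nodes, pre.tags).validate()

    bg = _Builder()
    b0 = bg.add(None, np.array([0.0, 5000.0, 0.0]))
    bg.add(b0, np.array([length_um * NM_PER_UM, 5000.0, 0.0]))
    bg_skel = Skeleton("bg", bg.nodes, bg.tags).validate()

    connectors = []
    xs = rng.uniform(2.0, length_um - 4.0, size=n_sites)
    for cid, x in enumerate(sorted(xs)):
        pre_node = pre_nodes[int(round(x))]
        loc = (x * NM_PER_UM, 1000.0, 0.0)
        if rng.random() < q:
            posts = [("post", spine[int(round(x))])]
        else:
            posts = [("bg", b0)]
        connectors.append(
            Connector(connector_id=cid, pre=("pre", pre_node), posts=posts,
                      location=loc)
        )
    circuit = CircuitVolume(
        stage="planted",
        skeletons={"pre": pre_skel, "post": post_skel, "bg": bg_skel},
        connectors=connectors,
    ).validate()
    return circuit, "pre", "post"
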