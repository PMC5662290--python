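"""Core data types and file I/O for skeletonized neurons and polyadic synapses.

A neuron is represented as a rooted tree of 3D points ("skeleton"): the
topology of the arbor without diameter or volume.  Synapses are polyadic
"connectors": a single presynaptic release site with one or more postsynaptic
contacts, each contact annotated on a specific skeleton node.  A
:class:`CircuitVolume` bundles the skeletons and connectors reconstructed from
one EM volume (one developmental stage) together with simple spatial
calibration metadata.

Coordinates are stored in nanometres throughout.  Cable lengths reported by
the analysis modules are in micrometres.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SkeletonError",
    "SkeletonNode",
    "Skeleton",
    "Connector",
    "CircuitVolume",
    "read_swc",
    "write_swc",
    "read_tags",
    "write_tags",
    "read_connectors",
    "write_connectors",
    "read_manifest",
    "write_manifest",
]

#: conventional SWC unit is micrometres; internal unit is nanometres
DEFAULT_SWC_SCALE = 1000.0


class SkeletonError(ValueError):
    """Structural problem in a skeleton, connector table, or circuit."""


@dataclass(frozen=True)
class SkeletonNode:
    node_id: int
    parent_id: int | None  # None marks the root
    x: float
    y: float
    z: float

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class Skeleton:
    """Rooted tree of 3D nodes with free-form per-node tags and metadata.

    Invariants (checked by :meth:`validate`): exactly one root, parent
    pointers form a tree, node ids unique, coordinates finite.
    """

    neuron_id: str
    nodes: dict[int, SkeletonNode]
    tags: dict[int, set[str]] = field(default_factory=dict)
    cell_type: str | None = None
    side: str | None = None
    segment: str | None = None
    stage: str | None = None

    def __post_init__(self) -> None:
        self._children: dict[int, list[int]] | None = None
        self._root: int | None = None

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> int:
        if self._root is None:
            roots = [n.node_id for n in self.nodes.values() if n.parent_id is None]
            if len(roots) != 1:
                raise SkeletonError(
                    f"skeleton {self.neuron_id!r}: expected exactly one root, "
                    f"found {sorted(roots)!r}"
                )
            self._root = roots[0]
        return self._root

    def children(self) -> dict[int, list[int]]:
        """Map node_id -> sorted list of child node ids (cached)."""
        if self._children is None:
            ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
            for n in self.nodes.values():
                if n.parent_id is not None:
                    ch[n.parent_id].append(n.node_id)
            for lst in ch.values():
                lst.sort()
            self._children = ch
        return self._children

    def invalidate_caches(self) -> None:
        self._children = None
        self._root = None

    def validate(self) -> "Skeleton":
        for nid, node in self.nodes.items():
            if nid != node.node_id:
                raise SkeletonError(
                    f"skeleton {self.neuron_id!r}: key {nid} != node_id {node.node_id}"
                )
            if not all(math.isfinite(v) for v in (node.x, node.y, node.z)):
                raise SkeletonError(
                    f"skeleton {self.neuron_id!r}: non-finite coordinate at node {nid}"
                )
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise SkeletonError(
                    f"skeleton {self.neuron_id!r}: node {nid} references "
                    f"missing parent {node.parent_id}"
                )
        root = self.root  # raises on 0 or >1 roots
        # reachability from root == acyclicity for a parent-pointer graph
        seen = {root}
        stack = [root]
        ch = self.children()
        while stack:
            cur = stack.pop()
            for c in ch[cur]:
                if c in seen:
                    raise SkeletonError(
                        f"skeleton {self.neuron_id!r}: cycle through node {c}"
                    )
                seen.add(c)
                stack.append(c)
        if len(seen) != len(self.nodes):
            missing = sorted(set(self.nodes) - seen)
            raise SkeletonError(
                f"skeleton {self.neuron_id!r}: nodes not reachable from root "
                f"(e.g. node {missing[0]}; cyclic parent pointers)"
            )
        return self

    # -- traversal helpers -------------------------------------------------

    def dfs_preorder(self, start: int | None = None) -> list[int]:
        """Node ids in deterministic depth-first preorder from ``start``."""
        start = self.root if start is None else start
        ch = self.children()
        out: list[int] = []
        stack = [start]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(reversed(ch[cur]))
        return out

    def subtree_nodes(self, node_id: int) -> set[int]:
        """All nodes in the subtree rooted at node_id (inclusive)."""
        return set(self.dfs_preorder(node_id))

    def edge_length_nm(self, child_id: int) -> float:
        """Euclidean length of the parent edge of ``child_id`` (nm); 0 at root."""
        node = self.nodes[child_id]
        if node.parent_id is None:
            return 0.0
        parent = self.nodes[node.parent_id]
        return float(np.linalg.norm(node.xyz - parent.xyz))

    def edges(self) -> Iterable[tuple[int, int]]:
        """(parent, child) pairs, one per non-root node."""
        for n in self.nodes.values():
            if n.parent_id is not None:
                yield n.parent_id, n.node_id

    def coords(self, node_ids: Sequence[int] | None = None) -> np.ndarray:
        """(n, 3) coordinate array in nm, in the order given."""
        ids = list(self.nodes) if node_ids is None else list(node_ids)
        return np.array([self.nodes[i].xyz for i in ids], dtype=float)

    def tagged(self, label: str) -> set[int]:
        return {nid for nid, labels in self.tags.items() if label in labels}

    def copy(self) -> "Skeleton":
        return Skeleton(
            neuron_id=self.neuron_id,
            nodes=dict(self.nodes),
            tags={k: set(v) for k, v in self.tags.items()},
            cell_type=self.cell_type,
            side=self.side,
            segment=self.segment,
            stage=self.stage,
        )

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class Connector:
    """One polyadic synapse: a presynaptic site with >= 1 postsynaptic contacts.

    ``pre`` and every entry of ``posts`` are (neuron_id, node_id) pairs.
    ``location`` is the release-site position in nm.
    """

    connector_id: int
    pre: tuple[str, int]
    posts: list[tuple[str, int]]
    location: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.posts) < 1:
            raise SkeletonError(
                f"connector {self.connector_id}: needs >= 1 postsynaptic contact"
            )

    @property
    def n_posts(self) -> int:
        return len(self.posts)


@dataclass
class CircuitVolume:
    """One stage's reconstruction: skeletons + connectors + calibration.

    ``calibration`` may carry ``neuropile_width_um`` and ``segment_length_um``.
    """

    stage: str
    skeletons: dict[str, Skeleton]
    connectors: list[Connector]
    calibration: dict[str, float] = field(default_factory=dict)

    def validate(self) -> "CircuitVolume":
        for skel in self.skeletons.values():
            skel.validate()
        for conn in self.connectors:
            for role, (nrn, node) in [("pre", conn.pre)] + [
                ("post", p) for p in conn.posts
            ]:
                if nrn not in self.skeletons:
                    raise SkeletonError(
                        f"connector {conn.connector_id}: {role} neuron {nrn!r} "
                        "not in circuit"
                    )
                if node not in self.skeletons[nrn].nodes:
                    raise SkeletonError(
                        f"connector {conn.connector_id}: {role} node {node} "
                        f"not in skeleton {nrn!r}"
                    )
        return self

    # -- synapse bookkeeping ----------------------------------------------

    def inputs_by_node(self, neuron_id: str) -> dict[int, int]:
        """Postsynaptic contact count per node of ``neuron_id``."""
        counts: dict[int, int] = defaultdict(int)
        for conn in self.connectors:
            for nrn, node in conn.posts:
                if nrn == neuron_id:
                    counts[node] += 1
        return dict(counts)

    def outputs_by_node(self, neuron_id: str) -> dict[int, int]:
        """Presynaptic site count per node of ``neuron_id``."""
        counts: dict[int, int] = defaultdict(int)
        for conn in self.connectors:
            if conn.pre[0] == neuron_id:
                counts[conn.pre[1]] += 1
        return dict(counts)

    def presynaptic_sites(self, neuron_id: str) -> list[Connector]:
        return [c for c in self.connectors if c.pre[0] == neuron_id]

    def neurons_of_type(
        self, cell_type: str, side: str | None = None
    ) -> list[Skeleton]:
        out = [
            s
            for s in self.skeletons.values()
            if s.cell_type == cell_type and (side is None or s.side == side)
        ]
        return sorted(out, key=lambda s: s.neuron_id)


# ---------------------------------------------------------------------------
# SWC
# ---------------------------------------------------------------------------

def read_swc(
    path: str | Path,
    neuron_id: str | None = None,
    unit_scale: float = DEFAULT_SWC_SCALE,
    **meta: str,
) -> Skeleton:
    """Read a standard 7-column SWC file into a :class:`Skeleton`.

    Columns: id, structure type, x, y, z, radius, parent (-1 for the root).
    Coordinates are multiplied by ``unit_scale`` (default converts the SWC
    convention of micrometres to internal nanometres).  The radius column is
    ignored; skeletons carry no volume.
    """
    path = Path(path)
    nodes: dict[int, SkeletonNode] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SkeletonError(
                    f"{path.name}:{lineno}: expected 7 SWC columns, got {len(parts)}"
                )
            nid = int(parts[0])
            if nid in nodes:
                raise SkeletonError(f"{path.name}:{lineno}: duplicate node id {nid}")
            parent = int(parts[6])
            nodes[nid] = SkeletonNode(
                node_id=nid,
                parent_id=None if parent == -1 else parent,
                x=float(parts[2]) * unit_scale,
                y=float(parts[3]) * unit_scale,
                z=float(parts[4]) * unit_scale,
            )
    skel = Skeleton(neuron_id=neuron_id or path.stem, nodes=nodes, **meta)
    return skel.validate()


def write_swc(
    skeleton: Skeleton, path: str | Path, unit_scale: float = DEFAULT_SWC_SCALE
) -> None:
    """Write a skeleton as 7-column SWC, dividing coordinates by ``unit_scale``."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(skeleton.nodes):
            n = skeleton.nodes[nid]
            parent = -1 if n.parent_id is None else n.parent_id
            fh.write(
                f"{nid} 0 {n.x / unit_scale:.6f} {n.y / unit_scale:.6f} "
                f"{n.z / unit_scale:.6f} 0.0 {parent}\n"
            )


def read_tags(path: str | Path) -> dict[int, set[str]]:
    """Read a node-tag CSV (columns node_id, tag) into a tag map."""
    df = pd.read_csv(path)
    tags: dict[int, set[str]] = defaultdict(set)
    for nid, tag in zip(df["node_id"], df["tag"]):
        tags[int(nid)].add(str(tag))
    return dict(tags)


def write_tags(tags: Mapping[int, set[str]], path: str | Path) -> None:
    rows = [
        {"node_id": nid, "tag": tag}
        for nid in sorted(tags)
        for tag in sorted(tags[nid])
    ]
    pd.DataFrame(rows, columns=["node_id", "tag"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Connector CSV
# ---------------------------------------------------------------------------

CONNECTOR_COLUMNS = [
    "connector_id",
    "pre_neuron",
    "pre_node",
    "post_neuron",
    "post_node",
    "x",
    "y",
    "z",
]


def read_connectors(path: str | Path) -> list[Connector]:
    """Read a connector CSV (one row per postsynaptic contact) and merge rows
    sharing a connector_id into polyadic :class:`Connector` objects.

    Raises on a connector whose rows disagree about the presynaptic endpoint
    or location.
    """
    df = pd.read_csv(path)
    if df.empty:
        return []
    missing = [c for c in CONNECTOR_COLUMNS if c not in df.columns]
    if missing:
        raise SkeletonError(f"connector CSV missing columns: {missing}")
    out: list[Connector] = []
    for cid, grp in df.groupby("connector_id", sort=True):
        pres = {(str(r.pre_neuron), int(r.pre_node)) for r in grp.itertuples()}
        if len(pres) != 1:
            raise SkeletonError(
                f"connector {cid}: inconsistent presynaptic endpoint across rows"
            )
        locs = {(float(r.x), float(r.y), float(r.z)) for r in grp.itertuples()}
        if len(locs) != 1:
            raise SkeletonError(f"connector {cid}: inconsistent location across rows")
        posts = [
            (str(r.post_neuron), int(r.post_node))
            for r in grp.sort_values(["post_neuron", "post_node"]).itertuples()
        ]
        out.append(
            Connector(
                connector_id=int(cid),
                pre=next(iter(pres)),
                posts=posts,
                location=next(iter(locs)),
            )
        )
    return out


def write_connectors(connectors: Iterable[Connector], path: str | Path) -> None:
    """Write connectors as CSV, one row per postsynaptic contact."""
    rows = []
    for c in sorted(connectors, key=lambda c: c.connector_id):
        for post_neuron, post_node in c.posts:
            rows.append(
                {
                    "connector_id": c.connector_id,
                    "pre_neuron": c.pre[0],
                    "pre_node": c.pre[1],
                    "post_neuron": post_neuron,
                    "post_node": post_node,
                    "x": c.location[0],
                    "y": c.location[1],
                    "z": c.location[2],
                }
            )
    pd.DataFrame(rows, columns=CONNECTOR_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Circuit manifest (flat key-value file)
# ---------------------------------------------------------------------------

def write_manifest(circuit: CircuitVolume, directory: str | Path) -> Path:
    """Write a circuit as SWC + tag CSVs + connector CSV + flat manifest.

    Returns the manifest path.  Relative paths inside the manifest are
    resolved against its own directory on read, so the bundle is relocatable.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = [f"stage = {circuit.stage}"]
    for key, val in sorted(circuit.calibration.items()):
        lines.append(f"calibration.{key} = {val}")
    for nid in sorted(circuit.skeletons):
        skel = circuit.skeletons[nid]
        swc = f"{nid}.swc"
        write_swc(skel, directory / swc)
        lines.append(f"skeleton.{nid}.file = {swc}")
        for attr in ("cell_type", "side", "segment"):
            val = getattr(skel, attr)
            if val is not None:
                lines.append(f"skeleton.{nid}.{attr} = {val}")
        if skel.tags:
            tag_file = f"{nid}.tags.csv"
            write_tags(skel.tags, directory / tag_file)
            lines.append(f"skeleton.{nid}.tags_file = {tag_file}")
    write_connectors(circuit.connectors, directory / "connectors.csv")
    lines.append("connectors = connectors.csv")
    manifest = directory / "manifest.cfg"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest


def read_manifest(path: str | Path) -> CircuitVolume:
    """Load a circuit from a flat key-value manifest written by write_manifest."""
    path = Path(path)
    base = path.parent
    kv: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SkeletonError(f"{path.name}:{lineno}: expected 'key = value'")
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()

    stage = kv.pop("stage", "unknown")
    calibration = {
        k.split(".", 1)[1]: float(v)
        for k, v in list(kv.items())
        if k.startswith("calibration.")
    }
    skel_keys: dict[str, dict[str, str]] = defaultdict(dict)
    for k, v in kv.items():
        if k.startswith("skeleton."):
            _, nid, attr = k.split(".", 2)
            skel_keys[nid][attr] = v
    skeletons: dict[str, Skeleton] = {}
    for nid, attrs in sorted(skel_keys.items()):
        if "file" not in attrs:
            raise SkeletonError(f"manifest: skeleton {nid!r} has no file entry")
        skel = read_swc(
            base / attrs["file"],
            neuron_id=nid,
            cell_type=attrs.get("cell_type"),
            side=attrs.get("side"),
            segment=attrs.get("segment"),
            stage=stage,
        )
        if "tags_file" in attrs:
            skel.tags = read_tags(base / attrs["tags_file"])
        skeletons[nid] = skel
    connectors = (
        read_connectors(base / kv["connectors"]) if "connectors" in kv else []
    )
    return CircuitVolume(
        stage=stage,
        skeletons=skeletons,
        connectors=connectors,
        calibration=calibration,
    ).validate()
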