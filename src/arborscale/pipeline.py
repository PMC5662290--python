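"""End-to-end two-stage comparison pipeline.

Runs every analysis stage on a pair of circuits (loaded from manifests or
generated synthetically), writes all result tables as CSV into an output
directory, and returns them in memory.  All randomness flows from the single
seed in the run configuration, so a rerun with the same inputs is
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .compartments import split_circuit
from .connectivity import (
    connection_matrix,
    fold_change,
    histogram_ks,
    lr_asymmetry,
    polyadic_histogram,
)
from .filling import DEFAULT_RADIUS_UM, filling_fraction, prune_terminal_branches
from .morphometry import decompose_twigs, morphometry_summary
from .orientation import OrientationFrame, orientation_table
from .robustness import (
    connection_rng,
    connection_twig_counts,
    max_tolerable_error,
    omission_simulation,
    twigs_per_connection,
)
from .skeletons import CircuitVolume, read_manifest
from .synthetic import MDIV_TYPES, GrowthSpec, generate_circuit_pair

__all__ = ["RunConfig", "run_compare", "read_config"]


@dataclass
class RunConfig:
    """Configuration for a two-stage comparison run."""

    out_dir: Path
    manifest_a: Path | None = None
    manifest_b: Path | None = None
    synthesize: bool = False
    seed: int = 0
    d_um: float = DEFAULT_RADIUS_UM
    p_step: float = 0.01
    n_instances: int = 5000
    min_synapses_robustness: int = 5
    pre_types: tuple[str, ...] = MDIV_TYPES
    twig_mode: str = "auto"  # auto | tags | proxy

    def validate(self) -> "RunConfig":
        if not self.synthesize:
            for m in (self.manifest_a, self.manifest_b):
                if m is None or not Path(m).exists():
                    raise FileNotFoundError(f"manifest not found: {m}")
        if self.d_um <= 0 or not 0 < self.p_step <= 1 or self.n_instances < 1:
            raise ValueError("parameters out of range (d_um, p_step, n_instances)")
        if self.twig_mode not in ("auto", "tags", "proxy"):
            raise ValueError("twig_mode must be auto, tags, or proxy")
        return self


def read_config(path: str | Path) -> RunConfig:
    """Parse a flat key = value config file into a RunConfig."""
    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        kv[key.strip()] = val.strip()
    out_dir = Path(kv.pop("out_dir", "arborscale_out"))
    cfg = RunConfig(out_dir=out_dir)
    if "manifest_a" in kv:
        cfg.manifest_a = Path(kv.pop("manifest_a"))
    if "manifest_b" in kv:
        cfg.manifest_b = Path(kv.pop("manifest_b"))
    if "synthesize" in kv:
        cfg.synthesize = kv.pop("synthesize").lower() in ("1", "true", "yes")
    for key, cast in [
        ("seed", int),
        ("d_um", float),
        ("p_step", float),
        ("n_instances", int),
        ("min_synapses_robustness", int),
    ]:
        if key in kv:
            setattr(cfg, key, cast(kv.pop(key)))
    if "pre_types" in kv:
        cfg.pre_types = tuple(t.strip() for t in kv.pop("pre_types").split(","))
    if "twig_mode" in kv:
        cfg.twig_mode = kv.pop("twig_mode")
    if kv:
        raise ValueError(f"unknown config keys: {sorted(kv)}")
    return cfg.validate()


def _resolve_twig_mode(circuit: CircuitVolume, mode: str) -> str:
    if mode != "auto":
        return mode
    has_tags = any(s.tags for s in circuit.skeletons.values())
    return "tags" if has_tags else "proxy"


def _frame_label(skel) -> str:
    return f"{skel.cell_type}_{skel.side}"


@dataclass
class CompareReport:
    """In-memory bundle of everything run_compare wrote to disk."""

    tables: dict[str, pd.DataFrame] = dc_field(default_factory=dict)
    scalars: dict[str, float] = dc_field(default_factory=dict)


def _stage_analysis(
    circuit: CircuitVolume, config: RunConfig, stage_key: str, report: CompareReport
) -> dict:
    """All single-stage analyses; returns intermediates for the comparison."""
    twig_mode = _resolve_twig_mode(circuit, config.twig_mode)
    morpho = morphometry_summary(circuit, twig_mode=twig_mode)
    report.tables[f"morphometry_{stage_key}"] = morpho

    splits = split_circuit(circuit)
    seg_rows, node_rows = [], []
    for nid, (dend, axon, res) in splits.items():
        seg_rows.append(
            {
                "neuron_id": nid,
                "segregation_index": res.segregation,
                "n_dendrite_contacts": res.n_dendrite,
                "p_dendrite_inputs": res.p_dendrite,
                "n_axon_contacts": res.n_axon,
                "p_axon_inputs": res.p_axon,
                "poorly_segregated": res.poorly_segregated,
            }
        )
        for n in sorted(dend):
            node_rows.append({"neuron_id": nid, "node_id": n, "compartment": "dendrite"})
        for n in sorted(axon):
            node_rows.append({"neuron_id": nid, "node_id": n, "compartment": "axon"})
    report.tables[f"segregation_{stage_key}"] = pd.DataFrame(seg_rows)
    report.tables[f"compartments_{stage_key}"] = pd.DataFrame(node_rows)
    dendrites = {nid: trio[0] for nid, trio in splits.items()}

    pre_ids = sorted(
        nid
        for nid, s in circuit.skeletons.items()
        if s.cell_type in config.pre_types
    )
    post_ids = sorted(
        nid
        for nid, s in circuit.skeletons.items()
        if s.cell_type not in config.pre_types and nid in splits
        and s.cell_type != "background"
    )
    matrix = connection_matrix(
        circuit, pre_ids, post_ids, restrict_to_dendrite=True,
        dendrite_nodes=dendrites,
    )
    report.tables[f"counts_{stage_key}"] = matrix.counts
    report.tables[f"normalized_input_{stage_key}"] = matrix.normalized

    hist = polyadic_histogram(circuit, pre_ids)
    report.tables[f"polyadic_{stage_key}"] = pd.DataFrame(
        {"n_posts": list(hist), "fraction": list(hist.values())}
    )

    # receptive-field orientation from the six sensory terminals
    frame = OrientationFrame()
    label_of = {nid: _frame_label(circuit.skeletons[nid]) for nid in pre_ids}
    counts = matrix.counts.copy()
    counts.index = [label_of[i] for i in counts.index]
    counts = counts[counts.index.isin(frame.labels)]
    if len(counts.index) == 6:
        counts = counts.loc[list(frame.labels)]
        report.tables[f"orientation_{stage_key}"] = orientation_table(counts, frame)

    # filling fraction for every sensory->LN pair
    ff_rows = []
    pruned = {p: prune_terminal_branches(circuit.skeletons[p]) for p in post_ids}
    for pre in pre_ids:
        for post in post_ids:
            r = filling_fraction(
                circuit, pre, post, d_um=config.d_um, post_pruned=pruned[post]
            )
            ff_rows.append(
                {
                    "pre_neuron": pre,
                    "post_neuron": post,
                    "d_um": r.d_um,
                    "n_potential": r.n_potential,
                    "n_actual": r.n_actual,
                    "fraction": r.fraction,
                    "n_actual_outside_potential": r.n_actual_outside_potential,
                }
            )
    report.tables[f"filling_fraction_{stage_key}"] = pd.DataFrame(ff_rows)

    # robustness to twig omission per connection
    decomps = {
        nid: decompose_twigs(
            circuit.skeletons[nid], mode=twig_mode,
            inputs_by_node=circuit.inputs_by_node(nid),
        )
        for nid in post_ids
    }
    conns = []
    for pre in pre_ids:
        for post in post_ids:
            c = connection_twig_counts(circuit, pre, post, decomps[post])
            if c.n_twigs:
                conns.append(c)
    tpc = twigs_per_connection(conns, min_synapses=config.min_synapses_robustness)
    report.tables[f"twigs_per_connection_{stage_key}"] = tpc
    report.scalars[f"twig_connection_slope_{stage_key}"] = tpc.attrs["slope"]

    p_grid = np.round(np.arange(0.0, 1.0 + 1e-9, config.p_step), 6)
    rob_rows = []
    for c in conns:
        if c.n_synapses < config.min_synapses_robustness:
            continue
        rng = connection_rng(config.seed, c.pre_neuron, c.post_neuron)
        p_max = max_tolerable_error(
            c, p_grid=p_grid, n_instances=config.n_instances, rng=rng
        )
        sample = omission_simulation(
            c, 0.12, config.n_instances,
            connection_rng(config.seed + 1, c.pre_neuron, c.post_neuron),
        )
        rob_rows.append(
            {
                "pre_neuron": c.pre_neuron,
                "post_neuron": c.post_neuron,
                "n_twigs": c.n_twigs,
                "n_synapses": c.n_synapses,
                "p_max": p_max,
                "median_recovered_at_p12": sample.median,
                "p5_recovered_at_p12": sample.p5,
                "p95_recovered_at_p12": sample.p95,
            }
        )
    report.tables[f"robustness_{stage_key}"] = pd.DataFrame(rob_rows)

    # per-neuron metric table used by the stage comparison
    rows = []
    for nid in post_ids:
        skel = circuit.skeletons[nid]
        dend = dendrites[nid]
        inputs = circuit.inputs_by_node(nid)
        n_dend_inputs = sum(c for n, c in inputs.items() if n in dend)
        mdiv_inputs = int(matrix.counts[nid].sum())
        dec = decomps[nid]
        dend_cable = sum(
            circuit.skeletons[nid].edge_length_nm(n)
            for n in dend
            if skel.nodes[n].parent_id in dend
        ) / 1000.0
        rows.append(
            {
                "neuron_id": nid,
                "cell_type": skel.cell_type,
                "side": skel.side,
                "dendritic_cable_um": dend_cable,
                "dendritic_inputs": n_dend_inputs,
                "outputs": sum(circuit.outputs_by_node(nid).values()),
                "twig_count": dec.n_twigs,
                "mdiv_input_count": mdiv_inputs,
                "normalized_mdiv_input": (
                    mdiv_inputs / n_dend_inputs if n_dend_inputs else math.nan
                ),
            }
        )
    metrics = pd.DataFrame(rows)
    report.tables[f"ln_metrics_{stage_key}"] = metrics
    posts_per_site = [
        c.n_posts for c in circuit.connectors if c.pre[0] in set(pre_ids)
    ]
    return {"metrics": metrics, "posts_per_site": posts_per_site}


METRIC_COLUMNS = [
    "dendritic_cable_um",
    "dendritic_inputs",
    "outputs",
    "twig_count",
    "mdiv_input_count",
    "normalized_mdiv_input",
]


def run_compare(config: RunConfig) -> CompareReport:
    """Run the full two-stage comparison and write the report bundle.

    Emits per-stage morphometry, compartment, connectivity, filling-fraction,
    orientation and robustness tables, plus fold-change and left/right
    asymmetry summaries, into ``config.out_dir``.
    """
    config.validate()
    report = CompareReport()
    if config.synthesize:
        spec = GrowthSpec(seed=config.seed)
        circuit_a, circuit_b, _ = generate_circuit_pair(spec)
    else:
        circuit_a = read_manifest(config.manifest_a)
        circuit_b = read_manifest(config.manifest_b)

    stage_out = {}
    for key, circuit in (("a", circuit_a), ("b", circuit_b)):
        stage_out[key] = _stage_analysis(circuit, config, key, report)

    # fold changes per metric
    fold_rows = []
    for metric in METRIC_COLUMNS:
        va = stage_out["a"]["metrics"][["neuron_id", "cell_type", "side", metric]]
        vb = stage_out["b"]["metrics"][["neuron_id", "cell_type", "side", metric]]
        va = va.rename(columns={metric: "value"})
        vb = vb.rename(columns={metric: "value"})
        if va.empty or vb.empty:
            continue
        fc = fold_change(va, vb, metric=metric)
        report.tables[f"fold_{metric}"] = fc
        fold_rows.append(
            {
                "metric": metric,
                "mean_fold": fc.attrs["mean_fold"],
                "sd_fold": fc.attrs["sd_fold"],
                "n_types": len(fc),
            }
        )
        report.scalars[f"fold_{metric}"] = fc.attrs["mean_fold"]
    report.tables["fold_summary"] = pd.DataFrame(fold_rows)

    # left/right asymmetry of normalized sensory input, per type and stage
    asym_rows = []
    for key in ("a", "b"):
        m = stage_out[key]["metrics"]
        for ct, grp in m.groupby("cell_type"):
            per_side = grp.groupby("side")["normalized_mdiv_input"].mean()
            if {"L", "R"} <= set(per_side.index):
                cv = lr_asymmetry(per_side["L"], per_side["R"])
                asym_rows.append({"stage": key, "cell_type": ct, "cv": cv})
    asym = pd.DataFrame(asym_rows)
    report.tables["lr_asymmetry"] = asym
    for key in ("a", "b"):
        sub = asym[asym["stage"] == key]["cv"].dropna()
        report.scalars[f"mean_lr_cv_{key}"] = (
            float(sub.mean()) if len(sub) else math.nan
        )

    # polyadic structure comparison (plumbing statistic)
    ks = histogram_ks(
        stage_out["a"]["posts_per_site"], stage_out["b"]["posts_per_site"]
    )
    report.scalars["polyadic_ks_statistic"] = float(ks.statistic)
    report.scalars["polyadic_ks_pvalue"] = float(ks.pvalue)

    _write_report(report, config)
    return report


def _write_report(report: CompareReport, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in report.tables.items():
        idx = name.startswith(("counts_", "normalized_input_"))
        table.to_csv(out / f"{name}.csv", index=idx, float_format="%.10g")
    pd.DataFrame(
        [{"quantity": k, "value": v} for k, v in sorted(report.scalars.items())]
    ).to_csv(out / "summary.csv", index=False, float_format="%.10g")
    log = [
        f"arborscale {__version__}",
        f"seed = {config.seed}",
        f"d_um = {config.d_um}",
        f"p_step = {config.p_step}",
        f"n_instances = {config.n_instances}",
        f"twig_mode = {config.twig_mode}",
        f"pre_types = {','.join(config.pre_types)}",
        f"synthesize = {config.synthesize}",
    ]
    (out / "run.log").write_text("\n".join(log) + "\n")
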