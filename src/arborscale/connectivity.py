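"""Synaptic connectivity matrices, polyadic structure, and stage comparisons.

A "synapse" in all counts is one postsynaptic contact, i.e. one edge of a
polyadic connector.  The normalized synaptic input of a connection is its
contact count divided by the postsynaptic neuron's total number of dendritic
input contacts, so a postsynaptic cell's normalized inputs over an exhaustive
set of presynaptic partners sum to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .skeletons import CircuitVolume

__all__ = [
    "ConnectionMatrix",
    "connection_matrix",
    "polyadic_histogram",
    "histogram_ks",
    "fold_change",
    "lr_asymmetry",
    "by_type_matrix",
]


@dataclass
class ConnectionMatrix:
    """Contact counts and normalized inputs for ordered pre x post entities.

    ``counts``: DataFrame, rows = presynaptic entities, columns = postsynaptic
    entities, integer contact counts.  ``normalized``: counts divided
    column-wise by ``total_inputs`` (the post neuron's total dendritic input
    contacts); NaN where that total is zero.
    """

    counts: pd.DataFrame
    total_inputs: pd.Series
    dendrite_restricted: bool = False
    normalized: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        denom = self.total_inputs.reindex(self.counts.columns)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            norm = self.counts / denom.replace(0, np.nan)
        self.normalized = norm


def connection_matrix(
    circuit: CircuitVolume,
    pre_set: Sequence[str],
    post_set: Sequence[str],
    restrict_to_dendrite: bool = False,
    dendrite_nodes: Mapping[str, set[int]] | None = None,
) -> ConnectionMatrix:
    """Contact-count matrix for connectors presynaptic on ``pre_set`` landing
    on ``post_set``.

    With ``restrict_to_dendrite`` only contacts on each post neuron's
    dendrite nodes are counted, and the normalization denominator is the post
    neuron's total dendritic inputs from *all* partners; ``dendrite_nodes``
    (from the compartment split) is then required.  Without the flag the
    denominator is the neuron's total input count.
    """
    if restrict_to_dendrite and dendrite_nodes is None:
        raise ValueError("restrict_to_dendrite requires dendrite_nodes")
    pre_set = list(pre_set)
    post_set = list(post_set)
    counts = pd.DataFrame(0, index=pre_set, columns=post_set, dtype=int)
    total = pd.Series(0, index=post_set, dtype=int)
    pre_lookup = set(pre_set)
    post_lookup = set(post_set)

    def on_dendrite(neuron: str, node: int) -> bool:
        if not restrict_to_dendrite:
            return True
        return node in dendrite_nodes.get(neuron, set())

    for conn in circuit.connectors:
        pre_neuron = conn.pre[0]
        for post_neuron, post_node in conn.posts:
            if post_neuron in post_lookup and on_dendrite(post_neuron, post_node):
                total[post_neuron] += 1
                if pre_neuron in pre_lookup:
                    counts.loc[pre_neuron, post_neuron] += 1
    return ConnectionMatrix(
        counts=counts,
        total_inputs=total,
        dendrite_restricted=restrict_to_dendrite,
    )


def by_type_matrix(
    matrix: ConnectionMatrix,
    pre_types: Mapping[str, str],
    post_types: Mapping[str, str],
) -> pd.DataFrame:
    """Average a cell-level normalized-input matrix into cell-type level by
    taking the mean over member cells on both axes (NaN-aware)."""
    norm = matrix.normalized.copy()
    norm.index = [pre_types[i] for i in norm.index]
    norm.columns = [post_types[c] for c in norm.columns]
    by_post = norm.T.groupby(level=0).mean().T
    return by_post.groupby(level=0).mean()


def polyadic_histogram(
    circuit: CircuitVolume, pre_set: Iterable[str] | None = None
) -> dict[int, float]:
    """Normalized histogram of postsynaptic contacts per presynaptic site.

    Restricted to connectors presynaptic on ``pre_set`` when given.  Bins are
    integer contact counts; values sum to 1.
    """
    pre_lookup = None if pre_set is None else set(pre_set)
    sizes = [
        c.n_posts
        for c in circuit.connectors
        if pre_lookup is None or c.pre[0] in pre_lookup
    ]
    if not sizes:
        raise ValueError("polyadic_histogram: no connectors in selection")
    vals, counts = np.unique(sizes, return_counts=True)
    total = counts.sum()
    return {int(v): float(c) / total for v, c in zip(vals, counts)}


def histogram_ks(sample_a: Sequence[int], sample_b: Sequence[int]):
    """Two-sided two-sample Kolmogorov-Smirnov test (plumbing around scipy)
    for comparing posts-per-site samples between stages."""
    return stats.ks_2samp(sample_a, sample_b, alternative="two-sided")


def _average_sides(values: pd.DataFrame) -> pd.Series:
    """Mean value per cell_type, averaging left/right homologs within a stage.

    ``values``: columns neuron_id, cell_type, side, value.  Averaging is first
    within (cell_type, side) — cell types with several indistinguishable
    members — then across sides.
    """
    per_side = values.groupby(["cell_type", "side"])["value"].mean()
    return per_side.groupby(level="cell_type").mean()


def fold_change(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    metric: str = "value",
) -> pd.DataFrame:
    """Per-cell-type ratio of a metric between two stages (B over A).

    Each input frame has columns neuron_id, cell_type, side, value.  Homologs
    are matched by cell type after averaging left and right cells within each
    stage; unmatched types are excluded with a warning.  Returns a frame with
    columns cell_type, value_a, value_b, fold; summary mean/sd are attached
    in ``DataFrame.attrs['mean_fold']`` / ``attrs['sd_fold']``.
    """
    mean_a = _average_sides(values_a)
    mean_b = _average_sides(values_b)
    shared = sorted(set(mean_a.index) & set(mean_b.index))
    dropped = sorted(set(mean_a.index) ^ set(mean_b.index))
    if dropped:
        warnings.warn(
            f"fold_change ({metric}): unmatched cell types excluded: {dropped}",
            stacklevel=2,
        )
    rows = []
    for ct in shared:
        a, b = mean_a[ct], mean_b[ct]
        rows.append(
            {
                "cell_type": ct,
                "value_a": a,
                "value_b": b,
                "fold": (b / a) if a else math.nan,
            }
        )
    out = pd.DataFrame(rows, columns=["cell_type", "value_a", "value_b", "fold"])
    folds = out["fold"].dropna()
    out.attrs["metric"] = metric
    out.attrs["mean_fold"] = float(folds.mean()) if len(folds) else math.nan
    out.attrs["sd_fold"] = float(folds.std(ddof=1)) if len(folds) > 1 else math.nan
    return out


def lr_asymmetry(value_left: float, value_right: float) -> float:
    """Coefficient of variation of a left/right homolog pair.

    Sample sd with the n-1 denominator over the two values divided by their
    mean; for a pair this is sqrt(2)*|a-b|/(a+b).  NaN when the mean is 0.
    """
    if value_left < 0 or value_right < 0:
        raise ValueError("lr_asymmetry: values must be nonnegative")
    mean = (value_left + value_right) / 2.0
    if mean == 0:
        return math.nan
    sd = math.sqrt(2) * abs(value_left - value_right) / 2.0
    return sd / mean
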