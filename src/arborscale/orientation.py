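"""Body-wall receptive-field orientation of interneurons.

Each body-wall hemisegment is tiled by the dendrites of six nociceptive
sensory neurons (three per side), so their receptive-field centers sit at
hexagonal positions around the circumference.  An interneuron's mean input
orientation is the synapse-weighted average of unit vectors pointing at those
centers:

    r = sum_j A_j u_j / sum_j A_j,   u_j = (cos(j*pi/3), sin(j*pi/3))

with j = 0 at the right v'ada field and the fields ordered counterclockwise.
|r| <= 1, with equality iff all input comes from a single field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OrientationFrame", "OrientationResult", "mean_orientation"]

#: counterclockwise from right v'ada (ventral right) around the body wall
DEFAULT_FIELD_ORDER = (
    "v'ada_R",
    "vdaB_R",
    "ddaC_R",
    "ddaC_L",
    "vdaB_L",
    "v'ada_L",
)


@dataclass(frozen=True)
class OrientationFrame:
    """Six receptive-field labels at angles j*pi/3, j = 0..5.

    The default order follows the counterclockwise-from-v'ada-right
    convention; pass a different label order to produce e.g. a clockwise
    frame.
    """

    labels: tuple[str, ...] = DEFAULT_FIELD_ORDER

    def __post_init__(self) -> None:
        if len(self.labels) != 6 or len(set(self.labels)) != 6:
            raise ValueError("orientation frame needs 6 distinct field labels")

    @property
    def angles(self) -> np.ndarray:
        return np.arange(6) * math.pi / 3.0

    @property
    def unit_vectors(self) -> np.ndarray:
        th = self.angles
        return np.column_stack([np.cos(th), np.sin(th)])

    def rotated(self, phi: float) -> np.ndarray:
        """Unit vectors of the frame rotated rigidly by phi radians."""
        th = self.angles + phi
        return np.column_stack([np.cos(th), np.sin(th)])


@dataclass
class OrientationResult:
    neuron_id: str
    vector: tuple[float, float]
    magnitude: float
    angle: float  # radians in [-pi, pi)


def mean_orientation(
    weights: Mapping[str, float] | Sequence[float],
    frame: OrientationFrame | None = None,
    neuron_id: str = "",
    rotation: float = 0.0,
) -> OrientationResult:
    """Synapse-weighted mean orientation vector for one interneuron.

    ``weights`` is either a mapping from frame labels to nonnegative synapse
    counts (missing labels count 0) or a sequence of six values in frame
    order.  All-zero weights leave the orientation undefined (NaN result).
    """
    frame = frame or OrientationFrame()
    if isinstance(weights, Mapping):
        unknown = set(weights) - set(frame.labels)
        if unknown:
            raise ValueError(f"weights for labels outside the frame: {sorted(unknown)}")
        w = np.array([float(weights.get(lbl, 0.0)) for lbl in frame.labels])
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (6,):
            raise ValueError("expected six weights in frame order")
    if np.any(w < 0):
        raise ValueError("orientation weights must be nonnegative")
    total = w.sum()
    if total == 0:
        return OrientationResult(
            neuron_id=neuron_id,
            vector=(math.nan, math.nan),
            magnitude=math.nan,
            angle=math.nan,
        )
    vec = (w @ frame.rotated(rotation)) / total
    angle = math.atan2(vec[1], vec[0])
    if angle >= math.pi:  # fold the boundary case to [-pi, pi)
        angle -= 2 * math.pi
    return OrientationResult(
        neuron_id=neuron_id,
        vector=(float(vec[0]), float(vec[1])),
        magnitude=float(np.linalg.norm(vec)),
        angle=angle,
    )


def orientation_table(
    counts: pd.DataFrame, frame: OrientationFrame | None = None
) -> pd.DataFrame:
    """Orientation of every column of a pre-field x post-neuron count matrix.

    Rows of ``counts`` must be labeled with the frame's field labels.
    """
    frame = frame or OrientationFrame()
    rows = []
    for post in counts.columns:
        res = mean_orientation(counts[post].to_dict(), frame, neuron_id=str(post))
        rows.append(
            {
                "neuron_id": res.neuron_id,
                "rx": res.vector[0],
                "ry": res.vector[1],
                "magnitude": res.magnitude,
                "angle_rad": res.angle,
            }
        )
    return pd.DataFrame(rows, columns=["neuron_id", "rx", "ry", "magnitude", "angle_rad"])
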