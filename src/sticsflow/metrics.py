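"""Summary statistics over STICS vector fields.

The headline quantity is the *alignment percentage*: 100 × the median
cosine of the angular difference between each valid flow vector and a
reference axis (0° horizontal, 90° vertical).  100% means perfect
alignment, 0% orthogonality; anti-aligned fields come out negative (the
cosine is kept signed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .stics import FlowVector, VectorField

__all__ = ["FieldSummary", "alignment_percentage", "summarize"]


@dataclass
class FieldSummary:
    """Valid-vector statistics of one vector field (speeds in µm/min)."""

    n_valid: int
    mean_speed: float
    median_speed: float
    max_speed: float
    alignment_pct_horizontal: float
    alignment_pct_vertical: float


def _valid_vectors(field: VectorField | Iterable[FlowVector]) -> list[FlowVector]:
    vectors: Sequence[FlowVector]
    if isinstance(field, VectorField):
        vectors = field.vectors
    else:
        vectors = list(field)
    return [v for v in vectors if v.valid]


def alignment_percentage(
    field: VectorField | Iterable[FlowVector], reference_angle: float
) -> float:
    """100 × median over valid vectors of cos(angle − reference_angle).

    Signed: a field pointing opposite the reference yields −100.  Invalid
    vectors are excluded; an even count takes the midpoint of the two
    central cosines.
    """
    valid = _valid_vectors(field)
    if not valid:
        raise ValueError("no valid vectors to summarize")
    cosines = [np.cos(np.deg2rad(v.angle - reference_angle)) for v in valid]
    return 100.0 * float(np.median(cosines))


def summarize(field: VectorField | Iterable[FlowVector]) -> FieldSummary:
    """Valid-vector speed statistics plus horizontal/vertical alignment."""
    valid = _valid_vectors(field)
    if not valid:
        return FieldSummary(0, np.nan, np.nan, np.nan, np.nan, np.nan)
    speeds = np.array([v.speed for v in valid])
    return FieldSummary(
        n_valid=len(valid),
        mean_speed=float(speeds.mean()),
        median_speed=float(np.median(speeds)),
        max_speed=float(speeds.max()),
        alignment_pct_horizontal=alignment_percentage(valid, 0.0),
        alignment_pct_vertical=alignment_percentage(valid, 90.0),
    )
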