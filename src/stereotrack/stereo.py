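"""Left/right correspondence and 3D reconstruction.

Matching is a globally optimal one-to-one assignment (Hungarian algorithm)
over a feature-combination cost; infeasible pairs (epipolar row violation or
implied depth outside the DOF) are excluded via a finite sentinel cost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import Detection2D
from .optics import OpticsConfig, DEFAULT_OPTICS, disparity_to_depth

__all__ = [
    "Particle3D",
    "MatchWeights",
    "correspondence_cost",
    "match_stereo",
    "reconstruct_3d",
]

logger = logging.getLogger(__name__)

INFEASIBLE = np.inf
_SENTINEL = 1e9  # finite stand-in inside the assignment matrix


@dataclass(frozen=True)
class MatchWeights:
    """Weights of the match cost terms; must be non-negative and sum to 1."""

    w_y: float = 0.5
    w_r: float = 0.25
    w_e: float = 0.25

    def __post_init__(self) -> None:
        if min(self.w_y, self.w_r, self.w_e) < 0:
            raise ValueError("match weights must be non-negative")
        if abs(self.w_y + self.w_r + self.w_e - 1.0) > 1e-9:
            raise ValueError("match weights must sum to 1")


@dataclass(frozen=True)
class Particle3D:
    """A depth-resolved particle reconstructed from one stereo match."""

    frame_index: int
    x_um: float
    y_um: float
    z_um: float
    disparity_px: float
    match_cost: float
    left_id: int
    right_id: int


def _mad_scale(values: np.ndarray) -> float:
    """Robust spread (MAD); falls back to 1.0 for degenerate spreads."""
    if len(values) == 0:
        return 1.0
    s = float(np.median(np.abs(values - np.median(values))))
    return s if s > 1e-9 else 1.0


def default_scales(
    left: list[Detection2D], right: list[Detection2D]
) -> tuple[float, float, float]:
    """Per-frame robust feature spreads making the cost terms dimensionless."""
    both = left + right
    cy = np.array([d.cy_px for d in both])
    rr = np.array([d.radius_px for d in both])
    ee = np.array([d.encircled_energy for d in both])
    return _mad_scale(cy), _mad_scale(rr), _mad_scale(ee)


def correspondence_cost(
    a: Detection2D,
    b: Detection2D,
    weights: MatchWeights = MatchWeights(),
    scales: tuple[float, float, float] = (1.0, 1.0, 1.0),
    row_tol_px: float = 2.0,
    cfg: OpticsConfig = DEFAULT_OPTICS,
) -> float:
    """Cost of pairing left detection ``a`` with right detection ``b``.

    Returns ``inf`` when the pair is infeasible: row mismatch beyond
    ``row_tol_px`` (the views share the epipolar row up to jitter) or an
    implied depth outside the DOF.  Otherwise a weighted sum of the scaled
    row, radius and encircled-energy differences.
    """
    if a.view != "left" or b.view != "right":
        raise ValueError("correspondence_cost expects (left, right) detections")
    if a.frame_index != b.frame_index:
        raise ValueError("detections must come from the same frame")
    if abs(a.cy_px - b.cy_px) > row_tol_px:
        return INFEASIBLE
    z = disparity_to_depth(a.cx_px - b.cx_px, cfg)
    if abs(z) > cfg.dof_um / 2.0 + 1.0:
        return INFEASIBLE
    s_y, s_r, s_e = scales
    return (
        weights.w_y * abs(a.cy_px - b.cy_px) / s_y
        + weights.w_r * abs(a.radius_px - b.radius_px) / s_r
        + weights.w_e * abs(a.encircled_energy - b.encircled_energy) / s_e
    )


def match_stereo(
    left_dets: list[Detection2D],
    right_dets: list[Detection2D],
    weights: MatchWeights = MatchWeights(),
    row_tol_px: float = 2.0,
    cfg: OpticsConfig = DEFAULT_OPTICS,
    scales: tuple[float, float, float] | None = None,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Optimal one-to-one left/right assignment over feasible pairs.

    Returns ``(matches, unmatched_left, unmatched_right)`` where each match is
    ``(left_index, right_index, cost)``.  Assignments landing on infeasible
    pairs are discarded, so those detections appear in the unmatched lists.
    """
    if not left_dets or not right_dets:
        return [], list(range(len(left_dets))), list(range(len(right_dets)))
    if scales is None:
        scales = default_scales(left_dets, right_dets)
    cost = np.empty((len(left_dets), len(right_dets)))
    for i, a in enumerate(left_dets):
        for j, b in enumerate(right_dets):
            cost[i, j] = correspondence_cost(a, b, weights, scales, row_tol_px, cfg)
    matrix = np.where(np.isfinite(cost), cost, _SENTINEL)
    rows, cols = linear_sum_assignment(matrix)
    matches = [
        (int(i), int(j), float(cost[i, j]))
        for i, j in zip(rows, cols)
        if np.isfinite(cost[i, j])
    ]
    used_l = {m[0] for m in matches}
    used_r = {m[1] for m in matches}
    unmatched_l = [i for i in range(len(left_dets)) if i not in used_l]
    unmatched_r = [j for j in range(len(right_dets)) if j not in used_r]
    return matches, unmatched_l, unmatched_r


def reconstruct_3d(
    matches: list[tuple[int, int, float]],
    left_dets: list[Detection2D],
    right_dets: list[Detection2D],
    cfg: OpticsConfig = DEFAULT_OPTICS,
) -> list[Particle3D]:
    """Convert matched detection pairs to 3D positions in micrometers.

    ``x`` and ``y`` are the mean of the two views' centroids converted at the
    pixel pitch; ``z`` comes from the disparity ``cx_left - cx_right``.
    Matches whose depth falls outside the DOF (+1 μm tolerance) are dropped
    with a warning.
    """
    px = cfg.pixel_size_um
    out: list[Particle3D] = []
    for i, j, c in matches:
        a, b = left_dets[i], right_dets[j]
        disparity = a.cx_px - b.cx_px
        z = float(disparity_to_depth(disparity, cfg))
        if abs(z) > cfg.dof_um / 2.0 + 1.0:
            logger.warning(
                "match (%d, %d) implies z=%.1f μm outside DOF; dropped", i, j, z
            )
            continue
        out.append(
            Particle3D(
                frame_index=a.frame_index,
                x_um=px * (a.cx_px + b.cx_px) / 2.0,
                y_um=px * (a.cy_px + b.cy_px) / 2.0,
                z_um=z,
                disparity_px=float(disparity),
                match_cost=float(c),
                left_id=i,
                right_id=j,
            )
        )
    return out
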