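"""Trajectory building: frame-to-frame Hungarian linking plus gap closing.

The linker creates optimal one-to-one links between consecutive frames with a
distance gate; a second pass bridges track ends to later track starts
(within a frame-gap and distance gate) by another optimal assignment, so
trajectories interrupted by missed detections are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .stereo import Particle3D

__all__ = [
    "TrackingParams",
    "Trajectory",
    "link_frame_pair",
    "close_gaps",
    "build_trajectories",
]

_SENTINEL = 1e9


@dataclass(frozen=True)
class TrackingParams:
    """Gating parameters of the linker; all distances in micrometers."""

    max_link_dist_um: float = 5.0
    max_gap_frames: int = 2
    max_gap_dist_um: float = 7.0
    z_scale: float = 1.0
    min_length: int = 3


@dataclass
class Trajectory:
    """Time-ordered sequence of 3D particles with recorded gap bridges."""

    track_id: int
    points: list[tuple[int, Particle3D]] = field(default_factory=list)
    gap_links: list[tuple[int, int]] = field(default_factory=list)

    @property
    def frames(self) -> list[int]:
        return [f for f, _ in self.points]

    @property
    def length(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        """(n, 3) array of x, y, z in μm."""
        return np.array([[p.x_um, p.y_um, p.z_um] for _, p in self.points])

    def times(self, volume_rate_hz: float) -> np.ndarray:
        return np.array(self.frames, dtype=float) / volume_rate_hz

    @property
    def is_short(self) -> bool:
        """Flag for downstream filtering; short tracks are kept, not deleted."""
        return self.length < 3


def _scaled_dist(p: Particle3D, q: Particle3D, z_scale: float) -> float:
    """Euclidean 3D distance with the z component scaled by ``z_scale``
    (values < 1 de-emphasize the noisier axial coordinate)."""
    return float(
        np.sqrt(
            (p.x_um - q.x_um) ** 2
            + (p.y_um - q.y_um) ** 2
            + (z_scale * (p.z_um - q.z_um)) ** 2
        )
    )


def link_frame_pair(
    particles_t: list[Particle3D],
    particles_t1: list[Particle3D],
    max_link_dist_um: float = 5.0,
    z_scale: float = 1.0,
) -> list[tuple[int, int, float]]:
    """Optimal assignment between consecutive frames.

    Returns ``(source_index, target_index, distance)`` triples; pairs beyond
    ``max_link_dist_um`` are left unassigned (track death/birth).  Ties are
    resolved deterministically by the assignment solver's stable lexicographic
    ordering over (source, target).
    """
    if not particles_t or not particles_t1:
        return []
    cost = np.empty((len(particles_t), len(particles_t1)))
    for i, p in enumerate(particles_t):
        for j, q in enumerate(particles_t1):
            cost[i, j] = _scaled_dist(p, q, z_scale)
    matrix = np.where(cost <= max_link_dist_um, cost, _SENTINEL)
    rows, cols = linear_sum_assignment(matrix)
    return [
        (int(i), int(j), float(cost[i, j]))
        for i, j in zip(rows, cols)
        if cost[i, j] <= max_link_dist_um
    ]


def _link_all_frames(
    per_frame: dict[int, list[Particle3D]], params: TrackingParams
) -> list[Trajectory]:
    """First pass: chain frame-pair links into track segments."""
    tracks: list[Trajectory] = []
    # open_by_index maps particle index in the current frame -> track
    open_by_index: dict[int, Trajectory] = {}
    frames = sorted(per_frame)
    prev_frame: int | None = None
    for f in frames:
        particles = per_frame[f]
        new_open: dict[int, Trajectory] = {}
        if prev_frame is not None and prev_frame == f - 1:
            links = link_frame_pair(
                per_frame[prev_frame], particles, params.max_link_dist_um, params.z_scale
            )
            for i, j, _ in links:
                trk = open_by_index.get(i)
                if trk is not None:
                    trk.points.append((f, particles[j]))
                    new_open[j] = trk
        for j, p in enumerate(particles):
            if j not in new_open:
                trk = Trajectory(track_id=len(tracks), points=[(f, p)])
                tracks.append(trk)
                new_open[j] = trk
        open_by_index = new_open
        prev_frame = f
    return tracks


def close_gaps(
    open_tracks: list[Trajectory],
    max_gap_frames: int = 2,
    max_gap_dist_um: float = 7.0,
    z_scale: float = 1.0,
) -> list[Trajectory]:
    """Bridge track ends to later track starts by optimal assignment.

    A bridge is feasible when the start lies 1..``max_gap_frames`` frames
    after the end and within ``max_gap_dist_um``; accepted bridges merge the
    two tracks and record the (end_frame, start_frame) gap.  With no feasible
    bridges the input is returned unchanged (no-op).
    """
    n = len(open_tracks)
    if n < 2:
        return open_tracks
    ends = [(t.points[-1][0], t.points[-1][1]) for t in open_tracks]
    starts = [(t.points[0][0], t.points[0][1]) for t in open_tracks]
    cost = np.full((n, n), np.inf)
    feasible = False
    for i, (ef, ep) in enumerate(ends):
        for j, (sf, sp) in enumerate(starts):
            if i == j:
                continue
            gap = sf - ef
            if not (1 <= gap <= max_gap_frames):
                continue
            d = _scaled_dist(ep, sp, z_scale)
            if d <= max_gap_dist_um:
                cost[i, j] = d
                feasible = True
    if not feasible:
        return open_tracks
    matrix = np.where(np.isfinite(cost), cost, _SENTINEL)
    rows, cols = linear_sum_assignment(matrix)
    successor = {
        int(i): int(j) for i, j in zip(rows, cols) if np.isfinite(cost[i, j])
    }
    has_predecessor = set(successor.values())
    merged: list[Trajectory] = []
    for idx, trk in enumerate(open_tracks):
        if idx in has_predecessor:
            continue  # will be absorbed into its predecessor's chain
        chain = Trajectory(track_id=len(merged), points=list(trk.points),
                           gap_links=list(trk.gap_links))
        cur = idx
        while cur in successor:
            nxt = successor[cur]
            chain.gap_links.append(
                (open_tracks[cur].points[-1][0], open_tracks[nxt].points[0][0])
            )
            chain.points.extend(open_tracks[nxt].points)
            chain.gap_links.extend(open_tracks[nxt].gap_links)
            cur = nxt
        merged.append(chain)
    return merged


def build_trajectories(
    per_frame_particles: dict[int, list[Particle3D]] | list[list[Particle3D]],
    params: TrackingParams = TrackingParams(),
) -> list[Trajectory]:
    """Full tracker: frame-pair linking over all consecutive frames, then gap
    closing.  Every input particle ends up in exactly one trajectory
    (singletons allowed)."""
    if isinstance(per_frame_particles, list):
        per_frame = {f: lst for f, lst in enumerate(per_frame_particles)}
    else:
        per_frame = dict(per_frame_particles)
    per_frame = {f: lst for f, lst in per_frame.items() if lst}
    if not per_frame:
        return []
    tracks = _link_all_frames(per_frame, params)
    return close_gaps(
        tracks, params.max_gap_frames, params.max_gap_dist_um, params.z_scale
    )
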