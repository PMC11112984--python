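"""End-to-end orchestration: stereo frames -> restored views -> detections ->
matches -> 3D particles -> trajectories, with per-stage bookkeeping."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .config import PipelineConfig
from .detection import Detection2D, detect_view
from .restoration import restore_view
from .stereo import MatchWeights, Particle3D, match_stereo, reconstruct_3d
from .tracking import TrackingParams, Trajectory, build_trajectories

__all__ = ["StageCounts", "PipelineResult", "reconstruct_frame", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class StageCounts:
    """Per-frame counts logged at each stage."""

    frame_index: int
    n_left: int
    n_right: int
    n_matched: int


@dataclass
class PipelineResult:
    per_frame_particles: dict[int, list[Particle3D]] = field(default_factory=dict)
    trajectories: list[Trajectory] = field(default_factory=list)
    counts: list[StageCounts] = field(default_factory=list)
    detections: dict[int, tuple[list[Detection2D], list[Detection2D]]] = field(
        default_factory=dict
    )

    @property
    def n_gaps_closed(self) -> int:
        return sum(len(t.gap_links) for t in self.trajectories)


def reconstruct_frame(
    pair, cfg: PipelineConfig
) -> tuple[list[Particle3D], list[Detection2D], list[Detection2D]]:
    """Run restoration, detection and stereo matching on one stereo pair."""
    optics = cfg.optics
    psf_sigma_px = cfg.restoration.psf_sigma_um / optics.pixel_size_um
    d = cfg.detection
    dets: dict[str, list[Detection2D]] = {}
    for view, img in (("left", pair.left), ("right", pair.right)):
        try:
            restored = restore_view(
                img, psf_sigma_px, cfg.restoration.lowpass_cutoff,
                cfg.restoration.rl_iterations,
            )
            dets[view] = detect_view(
                restored, pair.frame_index, view,  # type: ignore[arg-type]
                mode=d.mode, r_min_px=d.r_min_px, r_max_px=d.r_max_px,
                sensitivity=d.sensitivity, block_size_px=d.block_size_px,
                offset_nsigma=d.offset_nsigma, r_blob_px=d.r_blob_px,
            )
        except Exception as exc:
            raise RuntimeError(
                f"stage=detection frame={pair.frame_index} view={view}: {exc}"
            ) from exc
    m = cfg.matching
    weights = MatchWeights(w_y=m.w_y, w_r=m.w_r, w_e=m.w_e)
    try:
        matches, _, _ = match_stereo(
            dets["left"], dets["right"], weights, m.row_tol_px, optics
        )
        particles = reconstruct_3d(matches, dets["left"], dets["right"], optics)
    except Exception as exc:
        raise RuntimeError(
            f"stage=stereo_matching frame={pair.frame_index}: {exc}"
        ) from exc
    return particles, dets["left"], dets["right"]


def run_pipeline(
    sequence: list, cfg: PipelineConfig | None = None, keep_detections: bool = False
) -> PipelineResult:
    """Run the full reconstruction + tracking pipeline on a stereo sequence.

    Deterministic given identical inputs and config; all randomness in the
    system lives in the simulator.
    """
    cfg = cfg or PipelineConfig()
    result = PipelineResult()
    for pair in sequence:
        particles, ldets, rdets = reconstruct_frame(pair, cfg)
        result.per_frame_particles[pair.frame_index] = particles
        result.counts.append(
            StageCounts(pair.frame_index, len(ldets), len(rdets), len(particles))
        )
        if keep_detections:
            result.detections[pair.frame_index] = (ldets, rdets)
        logger.info(
            "frame %d: %d left, %d right, %d matched",
            pair.frame_index, len(ldets), len(rdets), len(particles),
        )
    t = cfg.tracking
    result.trajectories = build_trajectories(
        result.per_frame_particles,
        TrackingParams(
            max_link_dist_um=t.max_link_dist_um,
            max_gap_frames=t.max_gap_frames,
            max_gap_dist_um=t.max_gap_dist_um,
            z_scale=t.z_scale,
            min_length=t.min_length,
        ),
    )
    logger.info(
        "pipeline done: %d trajectories, %d gaps closed",
        len(result.trajectories), result.n_gaps_closed,
    )
    return result
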