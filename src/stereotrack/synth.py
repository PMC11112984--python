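"""Synthetic stereo-pair generator: scenes, motion, rendering, sequences.

Every downstream stage (restoration, detection, matching, tracking, analysis)
is validated against images produced here, so the renderer is first-class,
tested code — not a fixture.

Rendering model
---------------
Each view is a parallel projection of the volume along an axis tilted by
±θ/2 from the optical axis.  A particle at ``(x, y, z)`` therefore appears in
view ``v`` (left = +1, right = -1) centered at ``(x + v·z·tan(θ/2), y)``.
Within the extended depth of field the axial response is modeled as a
top-hat: uniform inside ``|z| <= dof/2``, zero outside, so blob photometry is
depth-invariant.  The blob itself is a disc of the particle's physical radius
convolved with an isotropic 2D Gaussian (lateral PSF).  Blobs are rendered on
a 4x oversampled grid and box-binned to keep centroid quantization below
0.05 px.  Noise: Poisson photon sampling on (signal + background), optional
view crosstalk, then additive Gaussian read noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator
from scipy.ndimage import gaussian_filter

from .optics import OpticsConfig, DEFAULT_OPTICS

__all__ = [
    "ParticleState",
    "MotionModel",
    "NoiseModel",
    "StereoPair",
    "make_scene",
    "step_motion",
    "render_stereo_pair",
    "simulate_sequence",
]

OVERSAMPLE = 4


@dataclass(frozen=True)
class ParticleState:
    """Ground-truth state of one particle at one time point."""

    id: int
    x_um: float
    y_um: float
    z_um: float
    radius_um: float
    brightness: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be > 0")
        if self.brightness <= 0:
            raise ValueError("brightness must be > 0")
        if not np.all(np.isfinite([self.x_um, self.y_um, self.z_um])):
            raise ValueError("particle position must be finite")


class MotionModel(BaseModel):
    """Brownian diffusion plus constant drift (gravity settling is -z)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    diffusion_um2_per_s: float = 0.0
    drift_um_per_s: tuple[float, float, float] = (0.0, 0.0, 0.0)
    boundary: Literal["reflect", "absorb"] = "reflect"

    @model_validator(mode="after")
    def _check(self) -> "MotionModel":
        if self.diffusion_um2_per_s < 0:
            raise ValueError("diffusion coefficient must be >= 0")
        return self


class NoiseModel(BaseModel):
    """Detection noise: background, read noise, demultiplexing crosstalk."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    background_photons: float = 10.0
    read_noise_sd: float = 1.0
    crosstalk_fraction: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "NoiseModel":
        if self.background_photons < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if not (0.0 <= self.crosstalk_fraction < 0.5):
            raise ValueError("crosstalk_fraction must be in [0, 0.5)")
        return self


NOISELESS = NoiseModel(background_photons=0.0, read_noise_sd=0.0)


@dataclass
class StereoPair:
    """One left/right view pair; the unit of acquisition."""

    left: np.ndarray
    right: np.ndarray
    frame_index: int = 0
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError(
                f"view shapes differ: {self.left.shape} vs {self.right.shape}"
            )
        for name, img in (("left", self.left), ("right", self.right)):
            if not np.all(np.isfinite(img)):
                raise ValueError(f"{name} view contains non-finite pixels")
            if np.any(img < 0):
                raise ValueError(f"{name} view contains negative pixels")


def make_scene(
    n_particles: int,
    radius_um: float = 2.23,
    brightness: float = 1000.0,
    bounds: tuple[tuple[float, float], ...] | None = None,
    seed: int | None = None,
    min_separation_um: float = 0.0,
    min_projected_separation_um: float = 0.0,
    cfg: OpticsConfig = DEFAULT_OPTICS,
    max_attempts: int = 2000,
) -> list[ParticleState]:
    """Place ``n_particles`` uniformly at random inside ``bounds``.

    ``bounds`` is ``((x_lo, x_hi), (y_lo, y_hi), (z_lo, z_hi))`` in μm;
    defaults to the full FOV laterally and ``[-dof/2, +dof/2]`` axially.
    With ``min_separation_um > 0`` placement is by rejection sampling; an
    infeasible packing raises after ``max_attempts`` tries per particle.
    ``min_projected_separation_um`` additionally enforces the separation in
    each view's projected (x', y) plane, so that particles well separated in
    3D cannot still overlap as rendered blobs (depths shear x differently).
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    if bounds is None:
        bounds = (
            (0.0, cfg.fov_x_um),
            (0.0, cfg.fov_y_um),
            (-cfg.dof_um / 2.0, cfg.dof_um / 2.0),
        )
    rng = np.random.default_rng(seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    tan_half = np.tan(np.radians(cfg.parallax_angle_deg) / 2.0)

    def _ok(p: np.ndarray, q: np.ndarray) -> bool:
        if min_separation_um > 0 and np.linalg.norm(p - q) < min_separation_um:
            return False
        if min_projected_separation_um > 0:
            for v in (+1.0, -1.0):
                dx = (p[0] + v * p[2] * tan_half) - (q[0] + v * q[2] * tan_half)
                if np.hypot(dx, p[1] - q[1]) < min_projected_separation_um:
                    return False
        return True

    placed: list[np.ndarray] = []
    for i in range(n_particles):
        for _ in range(max_attempts):
            p = lo + rng.random(3) * (hi - lo)
            if all(_ok(p, q) for q in placed):
                placed.append(p)
                break
        else:
            raise RuntimeError(
                f"could not place particle {i} with min_separation_um="
                f"{min_separation_um} after {max_attempts} attempts"
            )
    return [
        ParticleState(
            id=i, x_um=p[0], y_um=p[1], z_um=p[2],
            radius_um=radius_um, brightness=brightness,
        )
        for i, p in enumerate(placed)
    ]


def step_motion(
    scene: Sequence[ParticleState],
    model: MotionModel,
    dt_s: float,
    rng: np.random.Generator,
    bounds: tuple[tuple[float, float], ...] | None = None,
    cfg: OpticsConfig = DEFAULT_OPTICS,
) -> list[ParticleState]:
    """Advance the scene by one time step of ``dt_s`` seconds.

    Displacement per axis is ``drift·dt + N(0, sqrt(2·D·dt))``.  The boundary
    rule (reflect or absorb) is applied against ``bounds`` (default: FOV x DOF
    box).  Particle ids are preserved; absorbed particles are removed.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be > 0")
    if bounds is None:
        bounds = (
            (0.0, cfg.fov_x_um),
            (0.0, cfg.fov_y_um),
            (-cfg.dof_um / 2.0, cfg.dof_um / 2.0),
        )
    drift = np.asarray(model.drift_um_per_s, dtype=float)
    sigma = np.sqrt(2.0 * model.diffusion_um2_per_s * dt_s)
    out: list[ParticleState] = []
    for p in scene:
        pos = np.array([p.x_um, p.y_um, p.z_um])
        pos = pos + drift * dt_s
        if sigma > 0:
            pos = pos + rng.normal(0.0, sigma, size=3)
        if model.boundary == "reflect":
            for ax, (lo, hi) in enumerate(bounds):
                span = hi - lo
                # fold into [lo, hi] by reflection (handles multi-bounce)
                v = (pos[ax] - lo) % (2.0 * span)
                pos[ax] = lo + (v if v <= span else 2.0 * span - v)
        else:  # absorb
            if any(pos[ax] < lo or pos[ax] > hi for ax, (lo, hi) in enumerate(bounds)):
                continue
        out.append(replace(p, x_um=pos[0], y_um=pos[1], z_um=pos[2]))
    return out


def _render_view(
    scene: Sequence[ParticleState],
    cfg: OpticsConfig,
    view_sign: int,
    psf_sigma_um: float,
) -> np.ndarray:
    """Noiseless expected photon image for one view (left=+1, right=-1)."""
    px = cfg.pixel_size_um
    sub = px / OVERSAMPLE
    h, w = cfg.frame_h_px * OVERSAMPLE, cfg.frame_w_px * OVERSAMPLE
    canvas = np.zeros((h, w), dtype=float)
    tan_half = np.tan(np.radians(cfg.parallax_angle_deg) / 2.0)
    half_dof = cfg.dof_um / 2.0
    drawn_box = [h, w, 0, 0]  # y0, x0, y1, x1 of touched region
    for p in scene:
        if abs(p.z_um) > half_dof:
            continue
        # detector pixel j is centered at j*px μm and covers subpixels
        # 4j..4j+3, so subpixel s is centered at (s - 1.5)*sub μm
        cx = (p.x_um + view_sign * p.z_um * tan_half) / sub + 1.5
        cy = p.y_um / sub + 1.5
        r_sub = p.radius_um / sub
        # draw disc indicator scaled to brightness into a local window
        pad = int(np.ceil(r_sub + 4.0 * psf_sigma_um / sub)) + 2
        x0, x1 = int(np.floor(cx)) - pad, int(np.floor(cx)) + pad + 1
        y0, y1 = int(np.floor(cy)) - pad, int(np.floor(cy)) + pad + 1
        xs0, xs1 = max(x0, 0), min(x1, w)
        ys0, ys1 = max(y0, 0), min(y1, h)
        if xs0 >= xs1 or ys0 >= ys1:
            continue
        yy, xx = np.mgrid[ys0:ys1, xs0:xs1]
        dist2 = (xx - cx) ** 2 + (yy - cy) ** 2
        if r_sub >= 1.0:
            blob = (dist2 <= r_sub**2).astype(float)
        else:
            # sub-grid particle: deposit total disc flux as a narrow Gaussian
            # (disc ⊛ PSF degenerates to the PSF in this limit)
            amp = np.pi * r_sub**2
            s = max(r_sub / 2.0, 0.3)
            blob = amp / (2 * np.pi * s**2) * np.exp(-dist2 / (2 * s**2))
        canvas[ys0:ys1, xs0:xs1] += p.brightness * blob
        drawn_box = [min(drawn_box[0], ys0), min(drawn_box[1], xs0),
                     max(drawn_box[2], ys1), max(drawn_box[3], xs1)]
    if drawn_box[2] > drawn_box[0] and psf_sigma_um > 0:
        # blur only the touched region (plus blur margin); everything else is 0
        s_sub = psf_sigma_um / sub
        m = int(np.ceil(4.0 * s_sub)) + 1
        y0 = max(drawn_box[0] - m, 0)
        x0 = max(drawn_box[1] - m, 0)
        y1 = min(drawn_box[2] + m, h)
        x1 = min(drawn_box[3] + m, w)
        canvas[y0:y1, x0:x1] = gaussian_filter(
            canvas[y0:y1, x0:x1], sigma=s_sub, mode="constant"
        )
    # box-bin back to detector pixels; mean keeps amplitude (peak ≈ brightness)
    binned = canvas.reshape(
        cfg.frame_h_px, OVERSAMPLE, cfg.frame_w_px, OVERSAMPLE
    ).mean(axis=(1, 3))
    return binned


def render_stereo_pair(
    scene: Sequence[ParticleState],
    cfg: OpticsConfig = DEFAULT_OPTICS,
    noise: NoiseModel = NOISELESS,
    psf_sigma_um: float = 0.4,
    frame_index: int = 0,
    rng: np.random.Generator | None = None,
) -> StereoPair:
    """Render one noisy stereo pair of the scene.

    ``psf_sigma_um`` is the lateral PSF standard deviation (an assumed
    value — 0.4 μm is plausible for a 0.8 NA two-photon system; configurable).
    If ``rng`` is omitted a fresh generator seeded from ``noise.seed`` and
    ``frame_index`` is used, making single-frame renders reproducible.
    """
    if psf_sigma_um <= 0:
        raise ValueError("psf_sigma_um must be > 0")
    if rng is None:
        rng = np.random.default_rng((noise.seed, frame_index))
    left = _render_view(scene, cfg, +1, psf_sigma_um)
    right = _render_view(scene, cfg, -1, psf_sigma_um)
    eps = noise.crosstalk_fraction
    if eps > 0:
        left, right = (1 - eps) * left + eps * right, (1 - eps) * right + eps * left
    left = left + noise.background_photons
    right = right + noise.background_photons
    # Poisson shot noise applies in any stochastic regime; a fully-zero noise
    # model returns the deterministic expected-photon image.
    stochastic = noise.background_photons > 0 or noise.read_noise_sd > 0 or eps > 0
    if stochastic:
        left = rng.poisson(left).astype(float)
        right = rng.poisson(right).astype(float)
        if noise.read_noise_sd > 0:
            left = left + rng.normal(0.0, noise.read_noise_sd, left.shape)
            right = right + rng.normal(0.0, noise.read_noise_sd, right.shape)
    left = np.clip(left, 0.0, None)
    right = np.clip(right, 0.0, None)
    return StereoPair(
        left=left,
        right=right,
        frame_index=frame_index,
        time_s=frame_index / cfg.volume_rate_hz,
    )


def simulate_sequence(
    scene0: Sequence[ParticleState],
    motion: MotionModel,
    cfg: OpticsConfig = DEFAULT_OPTICS,
    noise: NoiseModel = NOISELESS,
    n_frames: int = 1,
    psf_sigma_um: float = 0.4,
    dropout_frames: dict[int, set[int]] | None = None,
) -> tuple[list[StereoPair], pd.DataFrame]:
    """Simulate ``n_frames`` stereo pairs plus a tidy ground-truth table.

    Returns ``(pairs, truth)`` where ``truth`` has columns
    ``frame, id, x_um, y_um, z_um``.  ``dropout_frames`` maps particle id to
    the set of frames in which it is omitted from rendering (but not from the
    ground truth), to exercise gap closing.
    """
    if n_frames < 0:
        raise ValueError("n_frames must be >= 0")
    rng = np.random.default_rng((noise.seed, 0))
    motion_rng = np.random.default_rng((noise.seed, 1))
    scene = list(scene0)
    pairs: list[StereoPair] = []
    records: list[tuple[int, int, float, float, float]] = []
    dt = 1.0 / cfg.volume_rate_hz
    for f in range(n_frames):
        visible = scene
        if dropout_frames:
            visible = [p for p in scene if f not in dropout_frames.get(p.id, ())]
        pairs.append(
            render_stereo_pair(
                visible, cfg, noise, psf_sigma_um, frame_index=f, rng=rng
            )
        )
        records.extend((f, p.id, p.x_um, p.y_um, p.z_um) for p in scene)
        if f < n_frames - 1:
            scene = step_motion(scene, motion, dt, motion_rng, cfg=cfg)
    truth = pd.DataFrame(records, columns=["frame", "id", "x_um", "y_um", "z_um"])
    return pairs, truth
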