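"""Shared fixtures: default configs and the expensive rendered scenes reused
across module and acceptance tests (session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

import stereotrack as st
from stereotrack.config import PipelineConfig
from stereotrack.pipeline import reconstruct_frame, run_pipeline

# lateral margins keep full blobs inside the frame at any depth
# (max parallax shift at |z|=50 μm is ~12.5 μm plus bead radius and blur)
BEAD_BOUNDS = ((16.0, 94.0), (4.0, 106.0), (-48.0, 48.0))


def bead_pipeline_config() -> PipelineConfig:
    """Pipeline config tuned for 4.46 μm beads (radius ~10.4 px)."""
    cfg = PipelineConfig()
    cfg.detection.r_min_px = 7.0
    cfg.detection.r_max_px = 14.0
    return cfg


def make_bead_scene(seed: int = 42, n: int = 13) -> list[st.ParticleState]:
    return st.make_scene(
        n,
        radius_um=2.23,
        brightness=1000.0,
        bounds=BEAD_BOUNDS,
        seed=seed,
        min_separation_um=12.0,
        min_projected_separation_um=12.0,
    )


@pytest.fixture(scope="session")
def optics() -> st.OpticsConfig:
    return st.OpticsConfig()


@pytest.fixture(scope="session")
def small_optics() -> st.OpticsConfig:
    """Quarter-size frames at the same pixel pitch, for fast noisy sims."""
    return st.OpticsConfig(fov_x_um=27.5, fov_y_um=27.5, frame_w_px=128, frame_h_px=128)


@pytest.fixture(scope="session")
def bead_cfg() -> PipelineConfig:
    return bead_pipeline_config()


@pytest.fixture(scope="session")
def bead_scene() -> list[st.ParticleState]:
    """The 13-bead characterization scene (4.46 μm beads, seed 42)."""
    return make_bead_scene()


@pytest.fixture(scope="session")
def bead_pair(bead_scene, optics):
    noise = st.NoiseModel(background_photons=10.0, seed=42)
    return st.render_stereo_pair(bead_scene, optics, noise, psf_sigma_um=0.4)


@pytest.fixture(scope="session")
def bead_recon(bead_pair, bead_cfg):
    """(particles_3d, left_detections, right_detections) of the 13-bead pair."""
    return reconstruct_frame(bead_pair, bead_cfg)


@pytest.fixture(scope="session")
def stationary_sequence(bead_cfg):
    """60-frame noisy sequence of one stationary bright bead at z = 10 μm
    (peak 1000 photons, background 10 photons/px, seed 7)."""
    bead = [st.ParticleState(0, 55.0, 55.0, 10.0, 2.23, 1000.0)]
    noise = st.NoiseModel(background_photons=10.0, seed=7)
    pairs, truth = st.simulate_sequence(
        bead, st.MotionModel(), bead_cfg.optics, noise, 60, psf_sigma_um=0.4
    )
    return pairs, truth


@pytest.fixture(scope="session")
def stationary_result(stationary_sequence, bead_cfg):
    pairs, _ = stationary_sequence
    return run_pipeline(pairs, bead_cfg)


@pytest.fixture(scope="session")
def depth_sweep(bead_cfg):
    """One bead rendered per depth across the DOF; returns (true_z, est_z)."""
    optics = bead_cfg.optics
    true_z = np.arange(-50.0, 50.1, 5.0)
    est_z = []
    for i, z in enumerate(true_z):
        bead = [st.ParticleState(0, 55.0, 55.0, float(z), 2.23, 1000.0)]
        noise = st.NoiseModel(background_photons=10.0, seed=100 + i)
        pair = st.render_stereo_pair(bead, optics, noise, psf_sigma_um=0.4)
        particles, _, _ = reconstruct_frame(pair, bead_cfg)
        assert len(particles) == 1, f"depth sweep failed at z={z}"
        est_z.append(particles[0].z_um)
    return np.asarray(true_z), np.asarray(est_z)
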