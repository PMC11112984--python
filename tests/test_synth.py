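import itertools

import numpy as np
import pytest
from scipy.ndimage import center_of_mass

import stereotrack as st
from stereotrack.synth import NOISELESS


def _centroid_x(img: np.ndarray) -> float:
    """Intensity-weighted centroid column of an image (oracle measurement)."""
    return center_of_mass(img)[1]


class TestMakeScene:
    def test_empty_scene(self):
        assert st.make_scene(0) == []

    def test_thirteen_beads_min_separation_brute_force(self):
        scene = st.make_scene(
            13, radius_um=2.23, seed=11, min_separation_um=12.0
        )
        assert len(scene) == 13
        for a, b in itertools.combinations(scene, 2):
            d = np.linalg.norm(
                [a.x_um - b.x_um, a.y_um - b.y_um, a.z_um - b.z_um]
            )
            assert d >= 12.0

    def test_projected_separation_enforced(self, optics):
        scene = st.make_scene(
            20, seed=3, min_projected_separation_um=10.0, cfg=optics
        )
        tan_half = np.tan(np.radians(optics.parallax_angle_deg) / 2)
        for v in (+1, -1):
            for a, b in itertools.combinations(scene, 2):
                dx = (a.x_um + v * a.z_um * tan_half) - (b.x_um + v * b.z_um * tan_half)
                assert np.hypot(dx, a.y_um - b.y_um) >= 10.0

    def test_containment_in_default_volume(self):
        scene = st.make_scene(40, seed=5)
        for p in scene:
            assert 0.0 <= p.x_um <= 110.0
            assert 0.0 <= p.y_um <= 110.0
            assert -50.0 <= p.z_um <= 50.0

    def test_infeasible_packing_raises(self):
        with pytest.raises(RuntimeError, match="min_separation"):
            st.make_scene(50, seed=1, min_separation_um=60.0, max_attempts=50)

    def test_reproducible_given_seed(self):
        a = st.make_scene(7, seed=99)
        b = st.make_scene(7, seed=99)
        assert a == b

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            st.make_scene(-1)


class TestParticleState:
    def test_invalid_radius(self):
        with pytest.raises(ValueError):
            st.ParticleState(0, 1, 1, 1, radius_um=0.0, brightness=1.0)

    def test_invalid_position(self):
        with pytest.raises(ValueError):
            st.ParticleState(0, np.nan, 1, 1, radius_um=1.0, brightness=1.0)


class TestStepMotion:
    def test_no_motion_is_identity(self):
        scene = st.make_scene(5, seed=0)
        rng = np.random.default_rng(0)
        out = st.step_motion(scene, st.MotionModel(), 1 / 30, rng)
        assert out == scene

    def test_pure_drift_deterministic(self):
        scene = st.make_scene(5, seed=0)
        model = st.MotionModel(drift_um_per_s=(0.0, 0.0, -3.0))
        out = st.step_motion(scene, model, 1 / 30, np.random.default_rng(0))
        for before, after in zip(scene, out):
            assert after.z_um == pytest.approx(before.z_um - 0.1, abs=1e-12)
            assert after.x_um == before.x_um
            assert after.id == before.id

    def test_diffusion_variance_matches_2Ddt(self):
        # Monte-Carlo oracle: sample displacement variance vs closed form
        D, dt = 1.0, 1 / 30
        scene = [st.ParticleState(0, 55.0, 55.0, 0.0, 1.0, 1.0)]
        model = st.MotionModel(diffusion_um2_per_s=D)
        rng = np.random.default_rng(12345)
        # huge box so reflection never triggers
        bounds = ((-1e6, 1e6),) * 3
        disp = []
        cur = scene
        for _ in range(10_000):
            nxt = st.step_motion(cur, model, dt, rng, bounds=bounds)
            disp.append(
                [nxt[0].x_um - cur[0].x_um, nxt[0].y_um - cur[0].y_um,
                 nxt[0].z_um - cur[0].z_um]
            )
            cur = nxt
        var = np.var(np.asarray(disp), axis=0)
        np.testing.assert_allclose(var, 2 * D * dt, rtol=0.05)

    def test_reflecting_boundary_conserves_and_contains(self):
        scene = st.make_scene(20, seed=2)
        model = st.MotionModel(
            diffusion_um2_per_s=50.0, drift_um_per_s=(0, 0, -30.0)
        )
        rng = np.random.default_rng(7)
        cur = scene
        for _ in range(50):
            cur = st.step_motion(cur, model, 1 / 30, rng)
        assert len(cur) == 20
        for p in cur:
            assert 0.0 <= p.x_um <= 110.0 and -50.0 <= p.z_um <= 50.0

    def test_absorbing_boundary_removes(self):
        scene = [st.ParticleState(0, 55.0, 55.0, -49.9, 1.0, 1.0)]
        model = st.MotionModel(
            drift_um_per_s=(0, 0, -10.0), boundary="absorb"
        )
        out = st.step_motion(scene, model, 1.0, np.random.default_rng(0))
        assert out == []

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            st.step_motion([], st.MotionModel(), 0.0, np.random.default_rng(0))


class TestRenderStereoPair:
    def test_midplane_particle_identical_views(self, optics):
        scene = [st.ParticleState(0, 55.0, 55.0, 0.0, 2.23, 1000.0)]
        pair = st.render_stereo_pair(scene, optics)
        np.testing.assert_array_equal(pair.left, pair.right)
        assert pair.left.max() > 0

    def test_disparity_matches_optics_model(self, optics):
        scene = [st.ParticleState(0, 55.0, 55.0, 10.0, 2.23, 1000.0)]
        pair = st.render_stereo_pair(scene, optics)
        measured = _centroid_x(pair.left) - _centroid_x(pair.right)
        expected = st.depth_to_disparity(10.0, optics)
        assert measured == pytest.approx(expected, abs=0.2)

    def test_outside_dof_contributes_nothing(self, optics):
        scene = [st.ParticleState(0, 55.0, 55.0, 51.0, 2.23, 1000.0)]
        pair = st.render_stereo_pair(scene, optics)
        assert pair.left.max() == 0.0 and pair.right.max() == 0.0

    def test_disparity_linear_across_dof_sweep(self, optics):
        """Rendered-blob disparity follows the linear transform to sub-pixel
        accuracy at 21 depths across the DOF."""
        for z in np.linspace(-50, 50, 21):
            scene = [st.ParticleState(0, 55.0, 55.0, float(z), 2.23, 1000.0)]
            pair = st.render_stereo_pair(scene, optics)
            measured = _centroid_x(pair.left) - _centroid_x(pair.right)
            assert measured == pytest.approx(
                st.depth_to_disparity(float(z), optics), abs=0.3
            ), f"z={z}"

    def test_flux_conserved_across_depth(self, optics):
        sums = []
        for z in (-40.0, -10.0, 0.0, 25.0, 45.0):
            scene = [st.ParticleState(0, 55.0, 55.0, z, 2.23, 1000.0)]
            pair = st.render_stereo_pair(scene, optics)
            sums.append(pair.left.sum())
        np.testing.assert_allclose(sums, sums[0], rtol=1e-3)

    def test_subresolution_particle_renders_as_spot(self, optics):
        # 500 nm nanoparticle: much smaller than the PSF, still detectable
        scene = [st.ParticleState(0, 55.0, 55.0, 0.0, 0.25, 5000.0)]
        pair = st.render_stereo_pair(scene, optics)
        assert pair.left.max() > 0
        cy, cx = center_of_mass(pair.left)
        assert cx == pytest.approx(55.0 / optics.pixel_size_um, abs=0.2)

    def test_crosstalk_mixes_views(self, optics):
        scene = [st.ParticleState(0, 40.0, 55.0, 30.0, 2.23, 1000.0)]
        clean = st.render_stereo_pair(scene, optics)
        noise = st.NoiseModel(
            background_photons=0.0, read_noise_sd=0.0, crosstalk_fraction=0.2, seed=1
        )
        mixed = st.render_stereo_pair(scene, optics, noise)
        # the left blob position now also shows up (attenuated) in the right view
        lx = int(round(_centroid_x(clean.left)))
        assert mixed.right[:, lx - 2 : lx + 3].sum() > 0

    def test_same_seed_bit_identical(self, optics):
        scene = st.make_scene(3, seed=0)
        noise = st.NoiseModel(background_photons=5.0, read_noise_sd=1.0, seed=9)
        a = st.render_stereo_pair(scene, optics, noise)
        b = st.render_stereo_pair(scene, optics, noise)
        np.testing.assert_array_equal(a.left, b.left)
        np.testing.assert_array_equal(a.right, b.right)

    def test_invalid_psf_rejected(self, optics):
        with pytest.raises(ValueError):
            st.render_stereo_pair([], optics, NOISELESS, psf_sigma_um=0.0)

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            st.NoiseModel(crosstalk_fraction=0.6)
        with pytest.raises(ValueError):
            st.NoiseModel(background_photons=-1.0)


class TestStereoPairType:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            st.StereoPair(left=np.zeros((4, 4)), right=np.zeros((4, 5)))

    def test_negative_pixels_rejected(self):
        with pytest.raises(ValueError):
            st.StereoPair(left=-np.ones((4, 4)), right=np.zeros((4, 4)))


class TestSimulateSequence:
    def test_single_frame_matches_scene(self, small_optics):
        scene = [st.ParticleState(0, 13.0, 14.0, 5.0, 1.0, 100.0)]
        pairs, truth = st.simulate_sequence(
            scene, st.MotionModel(), small_optics, NOISELESS, 1
        )
        assert len(pairs) == 1
        assert len(truth) == 1
        row = truth.iloc[0]
        assert (row.frame, row.id) == (0, 0)
        assert (row.x_um, row.y_um, row.z_um) == (13.0, 14.0, 5.0)

    def test_120_frames_span_four_seconds(self, small_optics):
        scene = [st.ParticleState(0, 13.0, 14.0, 0.0, 1.0, 100.0)]
        pairs, truth = st.simulate_sequence(
            scene, st.MotionModel(), small_optics, NOISELESS, 120
        )
        assert len(pairs) == st.frames_in_duration(4.0, small_optics) == 120
        assert pairs[-1].time_s == pytest.approx(119 / 30)
        assert truth.frame.nunique() == 120

    def test_static_noiseless_frames_bit_identical(self, small_optics):
        scene = [st.ParticleState(0, 13.0, 14.0, 0.0, 1.0, 100.0)]
        pairs, _ = st.simulate_sequence(
            scene, st.MotionModel(), small_optics, NOISELESS, 10
        )
        for p in pairs[1:]:
            np.testing.assert_array_equal(p.left, pairs[0].left)

    def test_dropout_frames_hide_particle(self, small_optics):
        scene = [st.ParticleState(0, 13.0, 14.0, 0.0, 1.0, 100.0)]
        pairs, truth = st.simulate_sequence(
            scene, st.MotionModel(), small_optics, NOISELESS, 3,
            dropout_frames={0: {1}},
        )
        assert pairs[0].left.max() > 0
        assert pairs[1].left.max() == 0.0  # hidden in frame 1
        assert pairs[2].left.max() > 0
        assert len(truth) == 3  # ground truth still has all frames
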