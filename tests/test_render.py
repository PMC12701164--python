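import math

import numpy as np
import pytest

from ctviz.errors import ValidationError
from ctviz.render import (
    Camera,
    ClippingPlane,
    RenderSettings,
    analytic_homogeneous_intensity,
    composite_ray,
    default_camera,
    gradient_at,
    gradient_field,
    opacity_step_correction,
    render,
    write_png,
)
from ctviz.transfer import ColorNode, GaussianNode, TransferFunction
from ctviz.volume_io import Volume


def flat_tf(alpha=0.05, value=100.0, color=(1.0, 1.0, 1.0)):
    """Constant-alpha, constant-colour transfer function near `value`."""
    return TransferFunction(
        opacity_nodes=(GaussianNode(value, 1e6, alpha),),
        color_nodes=(ColorNode(value - 200, color), ColorNode(value + 200, color)),
    )


class TestCompositeRay:
    def test_opaque_first_sample_occludes(self):
        rgb, a = composite_ray([(1, 0, 0), (0, 1, 0)], [1.0, 1.0])
        assert tuple(rgb) == (1.0, 0.0, 0.0) and a == 1.0

    def test_two_half_transparent_samples(self):
        rgb, a = composite_ray([(1, 0, 0), (0, 1, 0)], [0.5, 0.5], background=(0, 0, 0))
        assert tuple(rgb) == pytest.approx((0.5, 0.25, 0.0))
        assert a == pytest.approx(0.75)

    def test_matches_direct_sum_oracle(self, rng):
        colors = rng.random((100, 3))
        alphas = rng.random(100)
        rgb, acc = composite_ray(colors, alphas)
        # direct evaluation of the sum/product formula
        expected = np.zeros(3)
        for i in range(100):
            trans = np.prod(1.0 - alphas[:i])
            expected += colors[i] * alphas[i] * trans
        np.testing.assert_allclose(rgb, expected, atol=1e-10)
        assert acc == pytest.approx(1.0 - np.prod(1.0 - alphas), abs=1e-10)

    def test_early_termination_close_to_full_sum(self, rng):
        colors = rng.random((200, 3))
        alphas = rng.uniform(0.1, 0.5, 200)
        full, _ = composite_ray(colors, alphas)
        truncated, _ = composite_ray(colors, alphas, early_termination_alpha=0.99)
        assert np.all(np.abs(full - truncated) <= 0.01 + 1e-12)

    def test_background_shows_through(self):
        rgb, _ = composite_ray([(1, 1, 1)], [0.25], background=(0.0, 1.0, 0.0))
        assert tuple(rgb) == pytest.approx((0.25, 1.0, 0.25))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValidationError):
            composite_ray([(1, 1, 1)], [1.5])


class TestAnalyticIntensity:
    def test_unit_optical_depth(self):
        out = analytic_homogeneous_intensity(1.0, (1, 1, 1), 1.0)
        assert out == pytest.approx([1 - math.exp(-1)] * 3)

    def test_zero_tau_transmits(self):
        assert np.all(analytic_homogeneous_intensity(0.0, (1, 1, 1), 5.0) == 0.0)

    def test_saturates_to_color(self):
        out = analytic_homogeneous_intensity(2.0, (0.3, 0.6, 0.9), 1e6)
        assert out == pytest.approx([0.3, 0.6, 0.9])


class TestStepCorrection:
    def test_identity_at_reference_step(self):
        assert opacity_step_correction(0.37, 1.0, 1.0) == pytest.approx(0.37)

    def test_zero_and_one_fixed_points(self):
        assert opacity_step_correction(0.0, 0.3, 1.0) == 0.0
        assert opacity_step_correction(1.0, 0.3, 1.0) == 1.0

    def test_halved_step_preserves_accumulated_alpha(self):
        # oracle: transmittance (1-a)^(D/ref) is step-invariant by construction
        alpha, ref, depth = 0.2, 1.0, 16.0
        for step in (1.0, 0.5):
            a_step = opacity_step_correction(alpha, step, ref)
            n = int(depth / step)
            accumulated = 1.0 - (1.0 - a_step) ** n
            expected = 1.0 - (1.0 - alpha) ** (depth / ref)
            assert accumulated == pytest.approx(expected, rel=1e-2)


class TestGradient:
    def test_linear_ramp_constant_gradient(self):
        x = np.arange(10, dtype=float)
        vol = Volume(np.broadcast_to(3.0 * x[:, None, None], (10, 6, 6)).copy(),
                     spacing=(0.5, 1.0, 1.0))
        g = gradient_at(vol, (4, 3, 3))
        assert g == pytest.approx([3.0 / 0.5, 0.0, 0.0])

    def test_constant_volume_zero_gradient(self):
        vol = Volume(np.full((5, 5, 5), 7.0))
        assert gradient_at(vol, (2, 2, 2)) == pytest.approx([0, 0, 0])

    def test_matches_numpy_gradient_field(self, random_volume):
        field = gradient_field(random_volume)
        ref = np.stack(
            np.gradient(random_volume.data.astype(float), *random_volume.spacing), axis=-1
        )
        np.testing.assert_allclose(field, ref)
        # pointwise helper agrees with the field, borders included
        for idx in [(0, 0, 0), (4, 3, 5), (8, 6, 10)]:
            np.testing.assert_allclose(gradient_at(random_volume, idx), field[idx])


class TestRender:
    def test_transparent_tf_gives_background(self, phantom_small):
        _, vol, _ = phantom_small
        tf = flat_tf(alpha=0.0)
        settings = RenderSettings(background=(0.0, 0.5, 1.0))
        img = render(vol, tf, default_camera(vol, image_size=(16, 16)), settings)
        assert np.all(img[..., 0] == 0)
        assert np.all(img[..., 2] == 255)

    def test_homogeneous_cube_matches_ray_integral(self):
        """Discrete front-to-back compositing converges to c·(1−exp(−τD))."""
        alpha = 0.05
        vol = Volume(np.full((21, 20, 20), 100.0), spacing=(1.0, 1.0, 1.0))
        tf = flat_tf(alpha=alpha, value=100.0)
        cam = default_camera(vol, view="anterior", image_size=(21, 21))
        depth = 20.0  # y extent in mm
        tau = -math.log(1.0 - alpha)  # per mm at ref step 1 mm
        expected = analytic_homogeneous_intensity(tau, (1, 1, 1), depth)

        errors = []
        for sd in (0.5, 0.1):
            img = render(vol, tf, cam, RenderSettings(sample_distance=sd,
                                                      early_termination_alpha=1.0))
            center = img[10, 10, 0] / 255.0
            errors.append(abs(center - expected[0]) / expected[0])
        assert errors[-1] < 0.02
        assert errors[1] <= errors[0] + 0.005

    def test_clipping_plane_blanks_half(self, phantom_small):
        _, vol, _ = phantom_small
        lo, hi = vol.world_bounds()
        mid = (lo + hi) / 2.0
        from ctviz.transfer import preset_tf

        tf = preset_tf("ct-vascular")
        cam = default_camera(vol, image_size=(24, 24))
        plane = ClippingPlane(point=tuple(mid), normal=(1.0, 0.0, 0.0))
        img = render(vol, tf, cam, RenderSettings(sample_distance=1.0,
                                                  clipping_planes=(plane,),
                                                  background=(0, 0, 0)))
        # columns left of centre view world x < mid: all clipped to background
        assert np.all(img[:, :8, :3] == 0)
        assert img[:, 16:, :3].max() > 0

    def test_away_facing_camera_gives_background(self, phantom_small):
        _, vol, _ = phantom_small
        cam = default_camera(vol, image_size=(8, 8))
        away = Camera(position=cam.position,
                      view_dir=tuple(-v for v in cam.view_dir),
                      up=cam.up, view_size=cam.view_size, image_size=(8, 8))
        img = render(vol, flat_tf(alpha=0.5), away,
                     RenderSettings(background=(1, 0, 0)))
        assert np.all(img[..., 0] == 255) and np.all(img[..., 1] == 0)

    def test_deterministic_png_bytes(self, tmp_path, phantom_small):
        _, vol, _ = phantom_small
        from ctviz.transfer import preset_tf

        tf = preset_tf("ct-vascular")
        cam = default_camera(vol, image_size=(20, 20))
        settings = RenderSettings(sample_distance=1.0, shading=True,
                                  gradient_opacity_scale=0.6)
        p1 = write_png(render(vol, tf, cam, settings), tmp_path / "a.png")
        p2 = write_png(render(vol, tf, cam, settings), tmp_path / "b.png")
        assert p1.read_bytes() == p2.read_bytes()

    def test_mip_picks_brightest_structure(self, phantom_small):
        """Max-intensity blending maps the ray maximum through the colour map."""
        spec, vol, _ = phantom_small
        from ctviz.transfer import color_at, opacity_at, preset_tf

        tf = preset_tf("ct-bone")
        cam = default_camera(vol, view="superior", image_size=(40, 40))
        img = render(vol, tf, cam, RenderSettings(blend_mode="max-intensity",
                                                  sample_distance=1.0))
        vmax = float(vol.data.max())  # bone cylinder dominates
        expected = np.asarray(color_at(tf, vmax)) * opacity_at(tf, vmax) * 255
        brightest = img[..., :3].reshape(-1, 3).sum(axis=1).argmax()
        got = img[..., :3].reshape(-1, 3)[brightest]
        assert np.all(np.abs(got.astype(float) - expected) <= 10.0)

    def test_accumulated_alpha_bounded(self, rng):
        colors = rng.random((50, 3))
        alphas = rng.random(50)
        _, acc = composite_ray(colors, alphas)
        assert 0.0 <= acc <= 1.0

    def test_sample_distance_range_validated(self):
        with pytest.raises(ValidationError):
            RenderSettings(sample_distance=0.05)
        with pytest.raises(ValidationError):
            RenderSettings(sample_distance=1.5)
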