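import numpy as np
import pytest

import voxmark as vm
from voxmark.render import composite_ray, gradient, opacity, shade


def oblique_view(vol, degrees=30.0, image_size=(48, 48), pitch=1.0):
    th = np.deg2rad(degrees)
    forward = np.array([np.sin(th), 0.0, np.cos(th)])
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(up, forward)
    return vm.ViewState(right=right, up=up, forward=forward, center=vol.center,
                        image_size=image_size, pixel_pitch=pitch)


class TestTransferFunction:
    @pytest.mark.parametrize(
        "intensity,expected",
        [(50, 0.0), (100, 0.0), (150, 0.5), (200, 1.0), (250, 1.0)],
    )
    def test_piecewise_linear_ramp(self, intensity, expected):
        tf = vm.TransferFunction(low_intensity=100, high_intensity=200, max_opacity=1.0)
        assert opacity(tf, intensity) == pytest.approx(expected)

    def test_max_opacity_caps_the_ramp(self):
        tf = vm.TransferFunction(100, 200, max_opacity=0.3)
        assert opacity(tf, 1000) == pytest.approx(0.3)
        assert opacity(tf, 150) == pytest.approx(0.15)

    def test_invalid_ramp_rejected(self):
        with pytest.raises(ValueError):
            vm.TransferFunction(low_intensity=200, high_intensity=100)


class TestGradient:
    def test_constant_volume_has_zero_gradient(self):
        v = vm.Volume(data=np.full((5, 5, 5), 3.0))
        for idx in [(0, 0, 0), (2, 2, 2), (4, 4, 4)]:
            np.testing.assert_allclose(gradient(v, idx), 0.0)

    def test_linear_ramp_gradient_is_exact(self):
        sx = 0.5
        i = np.arange(6, dtype=float)
        data = np.broadcast_to(i[:, None, None] * sx, (6, 6, 6)).copy()
        v = vm.Volume(data=data, spacing=(sx, 1.0, 1.0))
        for idx in [(0, 2, 2), (3, 3, 3), (5, 2, 2)]:  # border one-sided, interior central
            np.testing.assert_allclose(gradient(v, idx), [1.0, 0.0, 0.0], atol=1e-12)

    def test_sphere_surface_gradient_is_radial(self, sphere32):
        vol, truth = sphere32
        center = truth["center"]
        # voxels straddling the surface along each axis
        for idx in [(25, 16, 16), (16, 25, 16), (16, 16, 25)]:
            g = gradient(vol, idx)
            outward = vol.index_to_world(idx) - center
            # intensity falls outward, so -gradient points along the outward normal
            cosang = (-g @ outward) / (np.linalg.norm(g) * np.linalg.norm(outward))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) < 15.0


class TestShade:
    def test_zero_reflectivity_is_ambient_only(self):
        lights = vm.LightSet(lights=(vm.Light((0, 0, 1)),), ambient=0.3)
        np.testing.assert_allclose(
            shade((0, 0, 1), 0.0, lights, base_colour=(1.0, 0.5, 0.25)),
            [0.3, 0.15, 0.075],
        )

    def test_headon_white_light_returns_base_colour(self):
        lights = vm.LightSet(lights=(vm.Light((0, 0, 1), intensity=1.0),), ambient=0.0)
        np.testing.assert_allclose(
            shade((0, 0, 1), 1.0, lights, base_colour=(0.2, 0.4, 0.8)), [0.2, 0.4, 0.8]
        )

    def test_perpendicular_light_contributes_nothing(self):
        lights = vm.LightSet(lights=(vm.Light((1, 0, 0)),), ambient=0.1)
        np.testing.assert_allclose(shade((0, 0, 1), 1.0, lights, (1, 1, 1)), [0.1, 0.1, 0.1])


class TestCompositeRay:
    def test_all_transparent_gives_black_and_zero_alpha(self):
        rgb, a = composite_ray([((1, 1, 1), 0.0)] * 5)
        np.testing.assert_allclose(rgb, 0.0)
        assert a == 0.0

    def test_opaque_first_sample_occludes_the_rest(self):
        rgb, a = composite_ray([((0.2, 0.4, 0.6), 1.0), ((1, 1, 1), 1.0)])
        np.testing.assert_allclose(rgb, [0.2, 0.4, 0.6])
        assert a == 1.0

    def test_two_half_opaque_samples_hand_computed(self):
        c1, c2 = np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
        rgb, a = composite_ray([(c1, 0.5), (c2, 0.5)])
        np.testing.assert_allclose(rgb, 0.5 * c1 + 0.25 * c2)
        assert a == pytest.approx(0.75)

    def test_accumulated_opacity_monotone_and_bounded(self):
        rng = np.random.default_rng(1)
        samples = [((0.5, 0.5, 0.5), a) for a in rng.uniform(0, 1, 50)]
        prev = 0.0
        acc = 0.0
        for colour, alpha in samples:
            acc = acc + (1 - acc) * alpha
            assert prev <= acc <= 1.0
            prev = acc

    def test_rejects_out_of_range_opacity(self):
        with pytest.raises(ValueError):
            composite_ray([((1, 1, 1), 1.5)])


class TestRaycast:
    def test_zero_opacity_tf_shows_pure_background(self, two_shell32):
        vol, _ = two_shell32
        view = vm.ViewState.along_axis(vol, "z", image_size=(16, 16))
        tf = vm.TransferFunction(1e6, 2e6)  # nothing reaches the ramp
        lights = vm.LightSet.headlight(view, background=(0.1, 0.2, 0.3))
        img = vm.render_raycast(vol, view, tf, lights)
        np.testing.assert_allclose(img.pixels, np.broadcast_to([0.1, 0.2, 0.3], (16, 16, 3)))

    def test_opaque_uniform_cube_renders_uniform_interior(self):
        vol = vm.Volume(data=np.full((16, 16, 16), 100.0))
        view = vm.ViewState.along_axis(vol, "z", image_size=(12, 12), pixel_pitch=1.0)
        tf = vm.TransferFunction(0.0, 50.0)
        lights = vm.LightSet.headlight(view)
        img = vm.render_raycast(vol, view, tf, lights)
        interior = img.pixels[4:8, 4:8].reshape(-1, 3)
        assert np.ptp(interior, axis=0).max() < 1e-9

    def test_sphere_silhouette_matches_analytic_projection(self, tmp_path):
        spec = vm.PhantomSpec(kind="solid_sphere", dims=(32, 32, 32), radius=10.0,
                              antialias=True)
        vol, truth = vm.generate(spec)
        view = vm.ViewState.along_axis(vol, "z", image_size=(48, 48), pixel_pitch=1.0)
        tf = vm.TransferFunction.surface(40, 90)
        lights = vm.LightSet.headlight(view)
        img = vm.render_raycast(vol, view, tf, lights)
        bg = np.asarray(lights.background_colour)
        differs = np.abs(img.pixels - bg).max(axis=2) > 1e-6
        w, h = view.image_size
        cc, rr = np.meshgrid(np.arange(w), np.arange(h))
        # pixel -> world offset from sphere center in the image plane
        dx = (cc - w / 2) * view.pixel_pitch
        dy = (h / 2 - rr) * view.pixel_pitch
        r_pix = np.hypot(dx, dy)
        inside = r_pix <= 10.0
        band = np.abs(r_pix - 10.0) <= 1.0  # 1-pixel boundary band excluded
        assert np.array_equal(differs[~band], inside[~band])
        img.save(tmp_path / "sphere.png")  # PNG export stays exercised

    def test_invariant_to_zero_light_and_light_permutation(self, two_shell32_aa):
        vol, _ = two_shell32_aa
        view = vm.ViewState.along_axis(vol, "z", image_size=(24, 24), pixel_pitch=1.5)
        tf = vm.TransferFunction.surface(40, 90)
        l1 = vm.Light((0, 0, -1), 0.8)
        l2 = vm.Light((1, 1, 0), 0.5, colour=(1.0, 0.7, 0.4))
        zero = vm.Light((0, 1, 0), 0.0)
        a = vm.render_raycast(vol, view, tf, vm.LightSet(lights=(l1, l2), ambient=0.1))
        b = vm.render_raycast(vol, view, tf, vm.LightSet(lights=(l2, l1, zero), ambient=0.1))
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    def test_quarter_turn_view_of_symmetric_phantom_matches(self, two_shell32_aa):
        vol, _ = two_shell32_aa
        view = vm.ViewState.along_axis(vol, "z", image_size=(40, 40), pixel_pitch=1.0)
        rotated = vm.ViewState(right=(0, 1, 0), up=(-1, 0, 0), forward=(0, 0, 1),
                               center=vol.center, image_size=(40, 40), pixel_pitch=1.0)
        tf = vm.TransferFunction.surface(40, 90)
        lights = vm.LightSet.headlight(view)
        a = vm.render_raycast(vol, view, tf, lights)
        b = vm.render_raycast(vol, rotated, tf, lights)
        assert np.abs(a.pixels - b.pixels).max() <= 5 / 255


class TestShearWarp:
    def test_zero_opacity_identical_to_raycast(self, two_shell32):
        vol, _ = two_shell32
        view = vm.ViewState.along_axis(vol, "z", image_size=(16, 16))
        tf = vm.TransferFunction(1e6, 2e6)
        lights = vm.LightSet.headlight(view, background=(0.3, 0.1, 0.6))
        a = vm.render_raycast(vol, view, tf, lights)
        b = vm.render_shearwarp(vol, view, tf, lights)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_axis_aligned_opaque_slab_within_2_of_255(self):
        data = np.zeros((24, 24, 24))
        data[6:18, 6:18, 6:18] = 100.0
        vol = vm.Volume(data=data)
        view = vm.ViewState.along_axis(vol, "z", image_size=(32, 32), pixel_pitch=1.0)
        tf = vm.TransferFunction(0.0, 50.0)
        lights = vm.LightSet.headlight(view)
        a = vm.render_raycast(vol, view, tf, lights)
        b = vm.render_shearwarp(vol, view, tf, lights)
        assert np.abs(a.pixels - b.pixels).max() <= 2 / 255

    def test_rotated_sphere_view_within_5_of_255(self):
        spec = vm.PhantomSpec(kind="solid_sphere", dims=(32, 32, 32), radius=10.0,
                              antialias=True)
        vol, _ = vm.generate(spec)
        view = oblique_view(vol, degrees=30.0)
        tf = vm.TransferFunction.surface(40, 90)
        lights = vm.LightSet.headlight(view)
        a = vm.render_raycast(vol, view, tf, lights)
        b = vm.render_shearwarp(vol, view, tf, lights)
        assert np.abs(a.pixels - b.pixels).max() <= 5 / 255


class TestRenderConfig:
    def test_round_trip(self, tmp_path):
        tf = vm.TransferFunction.translucent(20, 120, max_opacity=0.2, reflectivity_gain=0.7)
        lights = vm.LightSet(
            lights=(vm.Light((0, 0, -1), 0.9), vm.Light((1, 0, 0), 0.4, (1, 0.5, 0.2))),
            ambient=0.15,
            background_colour=(0.0, 0.1, 0.3),
        )
        path = tmp_path / "preset.cfg"
        vm.render.save_render_config(tf, lights, path, base_colour=(0.9, 0.9, 1.0))
        tf2, lights2, base2 = vm.render.load_render_config(path)
        assert tf2 == tf
        assert lights2.ambient == pytest.approx(lights.ambient)
        assert len(lights2.lights) == 2
        np.testing.assert_allclose(lights2.lights[0].direction, lights.lights[0].direction)
        np.testing.assert_allclose(base2, (0.9, 0.9, 1.0))

    def test_missing_required_key_raises(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("ambient=0.2\n")
        with pytest.raises(ValueError, match="opacity_low"):
            vm.render.load_render_config(path)
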