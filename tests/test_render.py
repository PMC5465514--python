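"""Transfer lookups, merging attenuation, compositing, full renders."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioviz.render import (
    PotentialColorScale, RaySample, RenderConfig, RenderMode, TransferLUT,
    composite_ray, lut_map, merged_emission, merging_attenuation,
    render_volume,
)


@pytest.fixture
def lut_a():
    return TransferLUT(values=(0.0, 40.0, 50.0), alphas=(0.0, 0.9, 0.6),
                       colors=((0, 0, 0), (0, 0.85, 0.85), (0.94, 0.55, 0.55)),
                       kind="anatomy")


@pytest.fixture
def lut_e():
    return PotentialColorScale().to_lut()


class TestTransferLUT:
    def test_control_points_exact(self, lut_a):
        a, c = lut_map(lut_a, 40.0)
        assert a == 0.9
        assert c == (0.0, 0.85, 0.85)

    def test_midpoint_is_mean_of_neighbours(self, lut_a):
        a, c = lut_map(lut_a, 45.0)
        assert a == pytest.approx((0.9 + 0.6) / 2)
        assert np.allclose(c, (np.array([0, 0.85, 0.85])
                               + np.array([0.94, 0.55, 0.55])) / 2)

    def test_clamps_outside_domain(self, lut_a):
        assert lut_map(lut_a, -10.0) == lut_map(lut_a, 0.0)
        assert lut_map(lut_a, 99.0) == lut_map(lut_a, 50.0)

    def test_rest_maps_to_blue_peak_to_red(self, lut_e):
        _, rest = lut_map(lut_e, -86.0)
        _, peak = lut_map(lut_e, 45.0)
        assert rest == (0.0, 0.0, 1.0)
        assert peak == (1.0, 0.0, 0.0)

    def test_empty_lut_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TransferLUT(values=(), alphas=(), colors=())

    def test_nonfinite_sample_rejected(self, lut_a):
        with pytest.raises(ValueError, match="non-finite"):
            lut_map(lut_a, float("nan"))


class TestMergingAttenuation:
    def test_transparent_anatomy_kills_attenuation(self, lut_a, lut_e):
        s = RaySample(0.0, anatomy_value=0.0, potential_value=10.0)
        assert merging_attenuation(s, lut_a, lut_e) == 0.0

    def test_product_with_ep_data(self, lut_e):
        la = TransferLUT(values=(0.0,), alphas=(0.5,), colors=((1, 1, 1),))
        le = TransferLUT(values=(0.0,), alphas=(0.4,), colors=((1, 0, 0),))
        s = RaySample(0.0, anatomy_value=0.0, potential_value=0.0)
        assert merging_attenuation(s, la, le) == pytest.approx(0.2)

    def test_no_ep_zero_gradient_transparent(self, lut_a, lut_e):
        """Homogeneous interiors without EP data attenuate nothing."""
        s = RaySample(0.0, anatomy_value=40.0, potential_value=None,
                      anatomy_gradient=(0.0, 0.0, 0.0))
        assert merging_attenuation(s, lut_a, lut_e) == 0.0

    def test_no_ep_strong_gradient_keeps_anatomy_alpha(self, lut_a, lut_e):
        s = RaySample(0.0, anatomy_value=40.0, potential_value=None,
                      anatomy_gradient=(10.0, 0.0, 0.0))
        assert merging_attenuation(s, lut_a, lut_e, grad_scale=5.0) == \
            pytest.approx(lut_a.alpha_of(40.0))


class TestMergedEmission:
    def test_zero_ep_opacity_collapses_to_anatomy(self, lut_a):
        le = TransferLUT(values=(0.0,), alphas=(0.0,), colors=((1, 0, 0),))
        s = RaySample(0.0, anatomy_value=40.0, potential_value=0.0)
        out = merged_emission(s, lut_a, le)
        assert np.allclose(out, np.array([0, 0.85, 0.85]) * 0.9)

    def test_equal_opacities_average(self):
        la = TransferLUT(values=(0.0,), alphas=(0.5,), colors=((1, 0, 0),))
        le = TransferLUT(values=(0.0,), alphas=(0.5,), colors=((0, 0, 1),))
        s = RaySample(0.0, anatomy_value=0.0, potential_value=0.0)
        out = merged_emission(s, la, le)
        expect = (np.array([0, 0, 1]) * 0.5 + np.array([1, 0, 0]) * 0.5) / 2
        assert np.allclose(out, expect)

    @settings(deadline=None, max_examples=100)
    @given(ae=st.floats(0.001, 1), aa=st.floats(0.001, 1))
    def test_weights_sum_to_one(self, ae, aa):
        w_e = ae / (ae + aa)
        w_a = aa / (ae + aa)
        assert w_e + w_a == pytest.approx(1.0, abs=1e-12)
        la = TransferLUT(values=(0.0,), alphas=(aa,), colors=((1, 0, 0),))
        le = TransferLUT(values=(0.0,), alphas=(ae,), colors=((0, 0, 1),))
        s = RaySample(0.0, anatomy_value=0.0, potential_value=0.0)
        out = merged_emission(s, la, le)
        assert np.allclose(out, w_e * ae * np.array([0, 0, 1])
                           + w_a * aa * np.array([1, 0, 0]))


def _const_luts(aa, ae, ca=(1.0, 0.5, 0.2), ce=(0.1, 0.9, 0.3)):
    la = TransferLUT(values=(0.0,), alphas=(aa,), colors=(ca,))
    le = TransferLUT(values=(0.0,), alphas=(ae,), colors=(ce,))
    return la, le


class TestCompositeRay:
    def test_all_transparent_gives_background(self):
        la, le = _const_luts(0.0, 0.0)
        samples = [RaySample(k * 0.1, 0.0, 0.0) for k in range(10)]
        out = composite_ray(samples, la, le, background=(0.2, 0.3, 0.4))
        assert np.allclose(out, (0.2, 0.3, 0.4))

    def test_single_opaque_sample_returns_emission(self):
        la, le = _const_luts(1.0, 1.0)
        s = [RaySample(0.0, 0.0, 0.0)]
        out = composite_ray(s, la, le)
        # alpha_a = alpha_e = 1: emission = blend of premultiplied colors
        expect = merged_emission(s[0], la, le)
        assert np.allclose(out, expect)
        # and nothing behind it contributes
        out2 = composite_ray(s + [RaySample(1.0, 0.0, 0.0)], la, le,
                             background=(1, 1, 1))
        assert np.allclose(out2, expect)

    def test_unordered_samples_rejected(self):
        la, le = _const_luts(0.5, 0.5)
        samples = [RaySample(1.0, 0.0, 0.0), RaySample(0.5, 0.0, 0.0)]
        with pytest.raises(ValueError, match="ordered"):
            composite_ray(samples, la, le)

    def test_transmittance_monotone_nonincreasing(self, rng):
        """Each added sample with tau' > 0 only darkens what is behind."""
        la, le = _const_luts(0.3, 0.6)
        bg = np.array([1.0, 1.0, 1.0])
        prev_bg_term = 1.0
        samples = []
        for k in range(20):
            samples.append(RaySample(float(k), 0.0, 0.0))
            out_white = composite_ray(samples, la, le, background=(1, 1, 1))
            out_black = composite_ray(samples, la, le, background=(0, 0, 0))
            bg_term = (out_white - out_black)[0]  # transmittance
            assert bg_term <= prev_bg_term + 1e-12
            prev_bg_term = bg_term

    def test_matches_fine_quadrature_of_attenuated_emission(self, rng):
        """Discrete compositing equals the continuous ray integral.

        The continuous model: piecewise-constant per-sample opacity a_k over
        segments of length ds, attenuation coefficient tau = -ln(1-a_k)/ds,
        emission density E_k * tau; the pixel is the attenuated emission
        integral plus background transmitted through the total depth.
        """
        for trial in range(50):
            n = 12
            ds = 0.25
            alphas = rng.uniform(0.0, 0.95, n)
            emis = rng.uniform(0.0, 1.0, (n, 3))
            # discrete front-to-back
            color = np.zeros(3)
            T = 1.0
            for k in range(n):
                color += T * alphas[k] * emis[k]
                T *= 1 - alphas[k]
            # fine quadrature of the continuous integral
            m = 400
            quad = np.zeros(3)
            depth = 0.0
            for k in range(n):
                tau = -np.log(max(1 - alphas[k], 1e-300)) / ds
                for j in range(m):
                    x = j * ds / m
                    quad += emis[k] * tau * np.exp(-(depth + tau * x)) * (ds / m) \
                        * np.exp(-tau * ds / (2 * m))  # midpoint-in-exponent
                depth += tau * ds
            assert np.allclose(quad, color, rtol=2e-5, atol=1e-7)


class TestRenderVolume:
    def test_deterministic(self, small_phantom):
        vol, _ = small_phantom
        cfg = RenderConfig(image_size=(48, 48), mode=RenderMode.LTM_ANATOMY)
        a = render_volume(vol, config=cfg)
        b = render_volume(vol, config=cfg)
        assert np.array_equal(a, b)

    def test_anatomy_hues_within_palette_bounds(self, small_phantom):
        """Rendered colors are convex combinations of palette entries + bg."""
        vol, _ = small_phantom
        cfg = RenderConfig(image_size=(48, 48), mode=RenderMode.LTM_ANATOMY)
        img = render_volume(vol, config=cfg)
        palette = np.array([i.color for i in vol.class_table.values()]
                           + [[0, 0, 0]])
        for c in range(3):
            assert img[..., c].max() <= palette[:, c].max() + 1e-9

    def test_merged_at_rest_blue_dominates(self, small_phantom):
        vol, _ = small_phantom
        pot = np.full(vol.dims, -86.0)
        cfg = RenderConfig(image_size=(48, 48), mode=RenderMode.MERGED)
        img = render_volume(vol, potential=pot, config=cfg)
        pix = img.reshape(-1, 3)
        lit = pix.sum(axis=1) > 0.05
        assert lit.any()
        assert np.all(pix[lit, 2] >= pix[lit, 0])  # blue channel >= red

    def test_transparent_ep_lut_equals_baseline_pixelwise(self, small_phantom):
        vol, _ = small_phantom
        pot = np.full(vol.dims, -70.0)
        lut_e0 = TransferLUT(values=(-86.0, 45.0), alphas=(0.0, 0.0),
                             colors=((0, 0, 1), (1, 0, 0)), kind="potential")
        base = render_volume(vol, config=RenderConfig(
            image_size=(48, 48), mode=RenderMode.LTM_ANATOMY))
        merged = render_volume(vol, potential=pot, lut_e=lut_e0,
                               config=RenderConfig(image_size=(48, 48),
                                                   mode=RenderMode.MERGED))
        assert np.array_equal(base, merged)

    def test_dim_mismatch_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError, match="dims"):
            render_volume(vol, potential=np.zeros((4, 4, 4)),
                          config=RenderConfig(mode=RenderMode.MERGED))

    def test_oversized_ray_step_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError, match="half the voxel"):
            render_volume(vol, config=RenderConfig(step=1.0,
                                                   mode=RenderMode.LTM_ANATOMY))

    def test_potential_only_mode_renders_rest_as_blue(self, small_phantom):
        vol, _ = small_phantom
        pot = np.full(vol.dims, -86.0)
        img = render_volume(vol, potential=pot, config=RenderConfig(
            image_size=(48, 48), mode=RenderMode.LTM_POTENTIAL))
        pix = img.reshape(-1, 3)
        lit = pix.sum(axis=1) > 0.05
        assert lit.any()
        assert np.all(pix[lit, 2] > pix[lit, 0])

    def test_sentinel_marks_no_data_voxels(self, small_phantom):
        """Voxels at the imported -1 sentinel drop out of the EP support."""
        vol, _ = small_phantom
        cfg = RenderConfig(image_size=(48, 48), mode=RenderMode.MERGED)
        pot_rest = np.full(vol.dims, -86.0)
        with_sentinel = render_volume(vol, potential=np.full(vol.dims, -1.0),
                                      config=cfg, sentinel_no_data=-1.0)
        without = render_volume(vol, potential=pot_rest, config=cfg)
        assert not np.array_equal(with_sentinel, without)


class TestColorbar:
    def test_strip_spans_lut_endpoints(self, lut_e):
        from cardioviz.render import colorbar_image
        bar = colorbar_image(lut_e, width=8, height=64)
        assert bar.shape == (64, 8, 3)
        assert np.allclose(bar[0, 0], (1, 0, 0))    # peak (red) on top
        assert np.allclose(bar[-1, 0], (0, 0, 1))   # rest (blue) at bottom
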