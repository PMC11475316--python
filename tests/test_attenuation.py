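"""Attenuation estimator: closed-form exactness, compensation, recovery."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mmoct import CPOCTStack, attenuation, phantom, render
from mmoct.attenuation import (
    closed_form_estimate,
    compensate_signal,
    estimate_attenuation,
    locate_layer_boundary,
)

from conftest import DZ_TISSUE, PITCH_AIR, noiseless_exponential_stack


class TestCompensation:
    def test_zero_floor_flat_profile_is_identity(self, uniform_speckled_stack):
        _, stack, _ = uniform_speckled_stack
        out = compensate_signal(stack, 0.0, "flat")
        assert np.array_equal(out.co, stack.co)
        assert np.array_equal(out.cross, stack.cross)

    def test_exact_cancellation_yields_zero_with_warning(self):
        img = np.full((32, 8), 3.0)
        stack = CPOCTStack(co=img, cross=img, axial_pitch_air=PITCH_AIR)
        with pytest.warns(UserWarning, match="all-zero"):
            out = compensate_signal(stack, 3.0)
        assert np.all(out.co == 0.0)

    def test_known_floor_and_rolloff_restore_beer_lambert_mean(self):
        """Correcting a phantom with noise + sensitivity roll-off recovers
        the noiseless Beer-Lambert ensemble mean within Monte-Carlo error."""
        spec = phantom.uniform_phantom(2.0, width_px=8000, depth_px=128, seed=3,
                                       noise_floor=0.01)
        spec = phantom.PhantomSpec(**{**spec.__dict__, "sensitivity_decay": 0.8})
        stack, gt = phantom.generate_cpoct_stack(spec)
        profile = np.exp(-0.8 * PITCH_AIR * np.arange(128))
        out = compensate_signal(stack, 0.01, profile)
        expected = np.exp(-2.0 * 2.0 * DZ_TISSUE * np.arange(128))
        mean = out.co.mean(axis=1)
        se = expected * np.sqrt(2.0 / 8000) + 0.01 / profile / np.sqrt(8000)
        # allowance of 1% of signal for the subtract-then-clip residual
        assert np.all(np.abs(mean - expected) < 5 * se + 0.01 * expected)

    def test_auto_floor_matches_known_floor_on_noise_dominated_tail(self):
        rng = np.random.default_rng(0)
        img = 0.01 * rng.exponential(size=(200, 64))
        img[:40] += 5.0  # shallow signal, deep 160 rows pure noise
        stack = CPOCTStack(co=img, cross=img, axial_pitch_air=PITCH_AIR)
        out = compensate_signal(stack, "auto")
        # median of deepest 5% of an Exp(0.01) field ~ 0.0069
        assert out.co[-50:].mean() < img[-50:].mean()

    def test_negative_floor_rejected(self, uniform_speckled_stack):
        _, stack, _ = uniform_speckled_stack
        with pytest.raises(ValueError, match="noise_floor"):
            compensate_signal(stack, -1.0)


class TestEstimatorClosedForm:
    def test_two_pixel_arithmetic(self):
        stack = CPOCTStack(
            co=np.ones((2, 1)), cross=np.ones((2, 1)),
            axial_pitch_air=0.5, n_tissue=1.0,
        )
        amap = estimate_attenuation(stack, "co", smooth=None, tail="none",
                                    energy_fraction=0.0)
        assert amap.values[0, 0] == pytest.approx(1.0)  # 1/(2*0.5*1)

    @pytest.mark.parametrize("mu", [0.5, 1.73, 3.0, 6.0])
    def test_tail_extended_estimator_equals_infinite_closed_form(self, mu):
        stack = noiseless_exponential_stack(mu)
        amap = estimate_attenuation(stack, "co", smooth=None)
        expected = closed_form_estimate(mu, DZ_TISSUE)
        err = np.abs(amap.values[amap.valid_mask] - expected)
        assert err.max() < 1e-9

    def test_truncated_estimator_matches_geometric_sum_closed_form(self):
        """Without tail extension the estimate carries the exact finite-tail
        bias factor 1/(1 - exp(-2 mu dz m))."""
        mu, depth = 3.0, 256
        stack = noiseless_exponential_stack(mu, depth=depth)
        amap = estimate_attenuation(stack, "co", smooth=None, tail="none")
        i = np.arange(depth)
        expected = closed_form_estimate(mu, DZ_TISSUE, n_tail=depth - 1 - i)
        sel = amap.valid_mask[:, 0]
        np.testing.assert_allclose(
            amap.values[sel, 0], expected[sel], rtol=1e-9
        )

    def test_small_mu_dz_bias_vanishes_with_pitch(self):
        """The discretization bias of the ratio estimator is ~mu*dz to
        first order and vanishes as the pitch shrinks."""
        mu = 0.004 / DZ_TISSUE  # mu*dz = 0.004
        cf = closed_form_estimate(mu, DZ_TISSUE)
        assert abs(cf - mu) / mu < 0.005
        finer = closed_form_estimate(mu, DZ_TISSUE / 8)
        assert abs(finer - mu) < abs(cf - mu) / 4

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance_is_exact(self, scale):
        stack = noiseless_exponential_stack(2.0, depth=64)
        scaled = CPOCTStack(
            co=stack.co * scale, cross=stack.cross * scale,
            axial_pitch_air=stack.axial_pitch_air,
        )
        a = estimate_attenuation(stack, "co", smooth=None)
        b = estimate_attenuation(scaled, "co", smooth=None)
        np.testing.assert_array_equal(a.valid_mask, b.valid_mask)
        np.testing.assert_allclose(
            a.values[a.valid_mask], b.values[b.valid_mask], rtol=1e-12
        )

    def test_zero_tail_is_invalid_not_an_error(self):
        img = np.zeros((16, 4))
        img[0] = 1.0
        stack = CPOCTStack(co=img, cross=img, axial_pitch_air=PITCH_AIR)
        amap = estimate_attenuation(stack, "co", smooth=None, tail="none")
        assert not amap.valid_mask[1:].any()
        assert np.isnan(amap.values[5, 0])


class TestSpeckledRecovery:
    def test_monotone_recovery_of_increasing_attenuation(self):
        medians = []
        for mu in (1.0, 2.0, 4.0, 6.0):
            spec = phantom.uniform_phantom(mu, width_px=256, depth_px=256, seed=21)
            stack, _ = phantom.generate_cpoct_stack(spec)
            corrected = compensate_signal(stack, spec.noise_floor)
            amap = estimate_attenuation(corrected, "co")
            medians.append(np.nanmedian(amap.values[amap.valid_mask]))
        assert np.all(np.diff(medians) > 0)

    def test_median_recovery_within_five_percent(self, uniform_speckled_stack):
        spec, stack, _ = uniform_speckled_stack
        corrected = compensate_signal(stack, spec.noise_floor)
        amap = estimate_attenuation(corrected, "co")
        med = np.nanmedian(amap.values[amap.valid_mask])
        assert med == pytest.approx(2.0, rel=0.05)


class TestBoundaryLocalization:
    def test_two_layer_boundary_found_at_interface(self):
        spec = phantom.PhantomSpec(
            layers=[phantom.Layer("sup", 112, 4.0, 2.0),
                    phantom.Layer("deep", 144, 6.0, 3.0)],
            width_px=2048, depth_px=256, seed=4, noise_floor=1e-5,
        )
        stack, _ = phantom.generate_cpoct_stack(spec)
        corrected = compensate_signal(stack, 1e-5)
        amap = estimate_attenuation(corrected, "co", energy_fraction=1e-3)
        assert abs(locate_layer_boundary(amap) - 112) <= 3


class TestRendering:
    def _map(self, values, valid):
        from mmoct import AttenuationMap

        return AttenuationMap(values=values, channel="co", valid_mask=valid,
                              delta_z_mm=DZ_TISSUE)

    def test_scale_extremes_blue_to_red(self):
        vals = np.array([[0.0, 12.0]])
        rgb = render.render_map(self._map(vals, np.ones_like(vals, bool)))
        b, r = rgb[0, 0], rgb[0, 1]
        assert b[2] > b[0]  # vmin renders blue
        assert r[0] > r[2]  # vmax renders red

    def test_out_of_range_values_clamp(self):
        vals = np.array([[15.0, 12.0]])
        rgb = render.render_map(self._map(vals, np.ones_like(vals, bool)))
        assert np.array_equal(rgb[0, 0], rgb[0, 1])

    def test_invalid_pixels_render_neutral(self):
        vals = np.array([[np.nan, 5.0]])
        valid = np.array([[False, False]])
        rgb = render.render_map(self._map(np.nan_to_num(vals), valid))
        assert np.all(rgb == np.array(render.INVALID_GRAY))

    def test_degenerate_color_range_rejected(self):
        vals = np.zeros((2, 2))
        with pytest.raises(ValueError, match="vmin"):
            render.render_map(self._map(vals, np.ones_like(vals, bool)), 5.0, 5.0)
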