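"""Elastography: vector-method strain, stress calibration, tangent modulus."""

import numpy as np
import pytest

from mmoct import elastography as el
from mmoct import phantom
from mmoct.containers import StressStrainCurve
from mmoct.elastography import StrainWrapError

from conftest import PITCH_AIR


def tissue_interior(series, top=16, bottom=24, side=8):
    r1 = series.reference_region[1]
    mask = np.zeros(series.frames.shape[1:], dtype=bool)
    mask[r1 + top : series.frames.shape[1] - bottom, side:-side] = True
    return mask


class TestInterframePhasor:
    def test_identical_frames_zero_phase(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        b = el.interframe_phasor(f, f)
        assert np.allclose(np.angle(b), 0.0)

    def test_global_phase_shift_recovered(self):
        rng = np.random.default_rng(1)
        f = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        b = el.interframe_phasor(f, f * np.exp(1j * np.pi / 4))
        assert np.allclose(np.angle(b), np.pi / 4)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            el.interframe_phasor(np.ones((4, 4), complex), np.ones((4, 5), complex))

    def test_phantom_pair_phase_equals_displacement_phase(self):
        spec = phantom.PhantomSpec(
            layers=[phantom.Layer("t", 120, 2, 1, phantom.LinearLaw(100.0))],
            reference_layer=phantom.ReferenceLayer(40, 100.0),
            width_px=16, depth_px=192, seed=3, noise_floor=0.0,
        )
        series, gt = phantom.generate_compression_series(spec, [0.0, 1.0])
        b = el.interframe_phasor(series.frames[0], series.frames[1])
        du = gt.displacement_fields[1] - gt.displacement_fields[0]
        expected = np.angle(
            np.exp(-1j * 4 * np.pi * spec.n_tissue * du / spec.wavelength_um)
        )
        np.testing.assert_allclose(np.angle(b), expected, atol=1e-9)


class TestVectorStrain:
    def _uniform_series(self, strain, seed=0, noise=0.0):
        e_t = 1.0 / strain  # sigma=1 kPa gives the requested strain
        spec = phantom.PhantomSpec(
            layers=[phantom.Layer("t", 256, 2, 1, phantom.LinearLaw(e_t))],
            reference_layer=phantom.ReferenceLayer(32, e_t),
            width_px=32, depth_px=288, seed=seed, noise_floor=noise,
        )
        return phantom.generate_compression_series(spec, [0.0, 1.0])

    def test_zero_displacement_zero_strain(self):
        rng = np.random.default_rng(0)
        f = rng.standard_normal((64, 32)) + 1j * rng.standard_normal((64, 32))
        s = el.vector_strain(
            el.interframe_phasor(f, f),
            axial_pitch_air_mm=PITCH_AIR, wavelength_um=1.3,
        )
        assert np.allclose(s.strain, 0.0)
        assert np.allclose(s.quality[s.valid], 1.0)

    def test_uniform_strain_recovered_noiselessly(self):
        series, _ = self._uniform_series(1e-3)
        f = el.estimate_strain_series(series)
        interior = np.zeros(series.frames.shape[1:], bool)
        interior[8:270, 8:24] = True
        err = np.abs(f.interframe[0][interior & f.valid[0]] - 1e-3)
        assert err.max() < 1e-5

    def test_linearity_in_displacement(self):
        s1, _ = self._uniform_series(5e-4)
        s2, _ = self._uniform_series(1e-3)  # doubled displacement everywhere
        f1 = el.estimate_strain_series(s1)
        f2 = el.estimate_strain_series(s2)
        interior = np.zeros(s1.frames.shape[1:], bool)
        interior[8:270, 8:24] = True
        sel = interior & f1.valid[0] & f2.valid[0]
        np.testing.assert_allclose(
            f2.interframe[0][sel], 2.0 * f1.interframe[0][sel], rtol=1e-6
        )

    def test_wrap_limit_raises_hard_error(self):
        """A synthetic phase ramp beyond the unwrap-free limit must not be
        silently averaged away."""
        depth, lag = 128, 4
        limit = phantom.max_step_strain(PITCH_AIR, 1.3, lag)
        k = 4 * np.pi * PITCH_AIR * 1000.0 / 1.3  # phase per unit strain-px
        phase = -k * limit * np.arange(depth)  # exactly pi across the lag
        frame0 = np.ones((depth, 16), complex)
        frame1 = np.exp(1j * phase)[:, None] * frame0
        b = el.interframe_phasor(frame0, frame1)
        with pytest.raises(StrainWrapError, match="load"):
            el.vector_strain(
                b, axial_pitch_air_mm=PITCH_AIR, wavelength_um=1.3, lag=lag
            )

    def test_quality_decreases_with_noise(self):
        clean, _ = self._uniform_series(1e-3, noise=0.0)
        noisy, _ = self._uniform_series(1e-3, noise=0.05)
        fc = el.estimate_strain_series(clean)
        fn = el.estimate_strain_series(noisy)
        interior = np.zeros(clean.frames.shape[1:], bool)
        interior[8:270, 8:24] = True
        assert fc.quality[0][interior].mean() > fn.quality[0][interior].mean()
        assert fn.quality[0][interior].mean() < 1.0


class TestAccumulation:
    def test_single_transition_cumulative_equals_interframe(self):
        s = el.StrainSlice(np.full((4, 4), 2e-4), np.ones((4, 4)), np.ones((4, 4), bool))
        f = el.accumulate([s])
        np.testing.assert_array_equal(f.cumulative, f.interframe[0][None])

    def test_three_equal_steps_sum(self):
        s = el.StrainSlice(np.full((4, 4), 2e-4), np.ones((4, 4)), np.ones((4, 4), bool))
        f = el.accumulate([s, s, s])
        assert f.cumulative[-1][0, 0] == pytest.approx(6e-4)

    def test_quality_propagates_as_minimum(self):
        mk = lambda q: el.StrainSlice(
            np.zeros((2, 2)), np.full((2, 2), q), np.ones((2, 2), bool)
        )
        f = el.accumulate([mk(0.9), mk(0.5), mk(0.7)])
        assert np.all(f.quality[-1] == 0.5)

    def test_phantom_cumulative_matches_analytic_layer_strain(
        self, small_compression_series
    ):
        spec, series, gt = small_compression_series
        f = el.estimate_strain_series(series)
        mask = tissue_interior(series)
        truth = gt.layer_cumulative_strains["tissue"]
        for k in range(f.n_transitions):
            est = f.cumulative[k][mask & f.valid[k]].mean()
            assert est == pytest.approx(truth[k + 1], rel=0.02)


class TestStressCalibration:
    def test_hookes_law_conversion(self, small_compression_series):
        _, series, gt = small_compression_series
        f = el.estimate_strain_series(series)
        stress = el.stress_from_reference(f, series)
        np.testing.assert_allclose(
            stress, gt.applied_stress_per_frame[1:], rtol=0.02
        )

    def test_zero_strain_zero_stress(self, small_compression_series):
        _, series, _ = small_compression_series
        f = el.estimate_strain_series(series)
        f.cumulative[...] = 0.0
        assert np.all(el.stress_from_reference(f, series) == 0.0)


class TestTangentModulus:
    def test_linear_tissue_exact(self):
        eps = np.linspace(0, 0.02, 9)
        curve = StressStrainCurve(strain=eps, stress_kpa=100.0 * eps)
        assert el.tangent_modulus(curve) == pytest.approx(100.0)

    def test_exponential_law_matches_closed_form_tangent(self):
        """Windowed least squares vs the analytic tangent E_inf * e^{k eps}."""
        law = phantom.ExponentialLaw(E_inf=102.0, k=20.0)
        sigma = np.linspace(0, 2.0, 17)
        eps = np.array([law.strain(s) for s in sigma])
        est = el.tangent_modulus(StressStrainCurve(strain=eps, stress_kpa=sigma))
        analytic = law.E_inf * np.exp(law.k * law.strain(1.0))  # = 122 kPa
        assert analytic == pytest.approx(122.0)
        assert est == pytest.approx(analytic, rel=0.02)

    def test_insufficient_range_rejected(self):
        eps = np.linspace(0, 0.004, 5)
        curve = StressStrainCurve(strain=eps, stress_kpa=100.0 * eps)  # to 0.4 kPa
        with pytest.raises(ValueError, match="insufficient compression range"):
            el.tangent_modulus(curve)

    def test_stiffness_map_recovers_layered_truth(self):
        spec = phantom.PhantomSpec(
            layers=[phantom.Layer("soft", 80, 2, 1, phantom.LinearLaw(50.0)),
                    phantom.Layer("stiff", 100, 2, 1, phantom.LinearLaw(300.0))],
            reference_layer=phantom.ReferenceLayer(48, 100.0),
            width_px=48, depth_px=240, seed=5, noise_floor=1e-4,
        )
        series, _ = phantom.generate_compression_series(
            spec, np.linspace(0, 2.0, 13)
        )
        f = el.estimate_strain_series(series)
        stress = el.stress_from_reference(f, series)
        smap = el.stiffness_map(f, stress)
        soft = np.nanmedian(smap.values[64:112][smap.valid_mask[64:112]])
        stiff = np.nanmedian(smap.values[144:200][smap.valid_mask[144:200]])
        assert soft == pytest.approx(50.0, rel=0.1)
        assert stiff == pytest.approx(300.0, rel=0.1)


class TestStiffnessRendering:
    def test_polarity_stiff_blue_soft_red_and_clamp(self):
        from mmoct import StiffnessMap
        from mmoct.render import render_stiffness

        vals = np.array([[0.0, 600.0, 700.0]])
        smap = StiffnessMap(values=np.maximum(vals, 1e-6),
                            valid_mask=np.ones_like(vals, bool))
        rgb = render_stiffness(smap)
        soft, stiff, over = rgb[0]
        assert soft[0] > soft[2]      # 0 kPa -> red
        assert stiff[2] > stiff[0]    # 600 kPa -> blue
        assert np.array_equal(stiff, over)  # clamped above vmax
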