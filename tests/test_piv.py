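"""PIV displacement estimation and strain metrics."""
import numpy as np
import pytest

from beatkit import piv
from beatkit import synthetic as syn


def _affine_field(k=0.01, n=8, spacing=8.0):
    gx = np.arange(n) * spacing
    gy = np.arange(n) * spacing
    xx, yy = np.meshgrid(gx, gy)
    u = -k * xx
    v = -k * yy
    return piv.VelocityField(gx, gy, u, v, np.ones((n, n), bool))


class TestDisplacement:
    def test_identical_frames_give_exactly_zero(self):
        a, _, _ = syn.gen_speckle_pair((0.0, 0.0), seed=1)
        vf = piv.compute_displacement(a, a)
        assert np.all(vf.u == 0.0) and np.all(vf.v == 0.0)

    @pytest.mark.parametrize("shift", [(0.5, 0.0), (3.0, -2.0)])
    def test_known_shift_recovered(self, shift):
        a, b, _ = syn.gen_speckle_pair(shift, seed=4)
        vf = piv.compute_displacement(a, b)
        assert np.median(vf.v) == pytest.approx(shift[0], abs=0.05)
        assert np.median(vf.u) == pytest.approx(shift[1], abs=0.05)

    def test_frame_swap_antisymmetry(self):
        a, b, _ = syn.gen_speckle_pair((2.3, -1.2), seed=5)
        fwd = piv.compute_displacement(a, b)
        bwd = piv.compute_displacement(b, a)
        assert abs(np.median(fwd.u) + np.median(bwd.u)) <= 0.1
        assert abs(np.median(fwd.v) + np.median(bwd.v)) <= 0.1

    def test_static_noisy_speckle_null(self):
        # independent per-frame noise at SNR 10 (texture std / noise sd)
        a0, _, _ = syn.gen_speckle_pair((0.0, 0.0), seed=0)
        noise = a0.std() / 10.0
        a, b, _ = syn.gen_speckle_pair((0.0, 0.0), seed=6, noise_sd=noise,
                                       independent_noise=True)
        vf = piv.compute_displacement(a, b)
        assert np.median(np.hypot(vf.u, vf.v)) <= 0.1

    def test_window_larger_than_image_rejected(self):
        a, b, _ = syn.gen_speckle_pair((0.0, 0.0), seed=0, image_size=(48, 48))
        with pytest.raises(ValueError):
            piv.compute_displacement(a, b, piv.InterrogationPlan((64, 32)))

    def test_mask_invalidates_outside_vectors(self):
        a, b, _ = syn.gen_speckle_pair((1.0, 0.0), seed=2)
        mask = np.zeros(a.shape, bool)
        mask[:, :64] = True
        vf = piv.compute_displacement(a, b, piv.InterrogationPlan(mask=mask))
        sel = vf.grid_x > 70
        assert not vf.valid[:, sel].any()

    def test_pass_sizes_must_decrease(self):
        with pytest.raises(ValueError):
            piv.InterrogationPlan((32, 32, 16))


class TestStrainRate:
    def test_uniform_translation_has_zero_strain(self):
        field = _affine_field(k=0.0)
        field.u += 3.0
        field.v -= 1.5
        srf = piv.velocity_to_strain_rate(field, frame_interval=0.1)
        np.testing.assert_allclose(srf.scalar, 0.0, atol=1e-12)

    def test_radial_inflow_matches_closed_form(self):
        # u = -k x, v = -k y  ->  contraction-positive scalar = 2k / dt
        k, dt = 0.013, 1.0 / 30
        srf = piv.velocity_to_strain_rate(_affine_field(k=k), dt)
        np.testing.assert_allclose(srf.scalar, 2.0 * k / dt, rtol=1e-6)

    def test_degenerate_grid_rejected(self):
        field = piv.VelocityField(np.array([0.0]), np.array([0.0]),
                                  np.zeros((1, 1)), np.zeros((1, 1)),
                                  np.ones((1, 1), bool))
        with pytest.raises(ValueError):
            piv.velocity_to_strain_rate(field, 0.1)

    def test_video_strain_rate_matches_analytic_truth(self):
        spec = syn.SyntheticVideoSpec(
            beat=(syn.BeatWaveformSpec(1.0, amplitude=0.08),),
            duration=1.2, frame_rate=30.0, image_size=(128, 128),
            base_radius=(45.0,), noise_sd=0.0, seed=11)
        stack, truth = syn.gen_contraction_video(spec)
        sr_truth = np.asarray(truth.truths["strain_rate_1_per_s"][0])
        k = int(np.argmax(np.abs(sr_truth)))  # mid-contraction pair
        vf = piv.compute_displacement(stack.frames[k], stack.frames[k + 1])
        srf = piv.velocity_to_strain_rate(vf, stack.frame_interval)
        lam = np.asarray(truth.truths["lam"][0])
        cy, cx = truth.truths["centers"][0]
        R = min(lam[k], lam[k + 1]) * spec.base_radius[0]
        gy, gx = np.meshgrid(srf.grid_y, srf.grid_x, indexing="ij")
        inside = (gy - cy) ** 2 + (gx - cx) ** 2 <= (R - 12) ** 2
        measured = srf.scalar[inside].mean()
        assert measured == pytest.approx(sr_truth[k], rel=0.15)


class TestStrainTrace:
    def _const_field(self, c, n=4):
        g = np.arange(n) * 8.0
        z = np.zeros((n, n))
        return piv.StrainRateField(g, g, np.full((n, n), c), z, z, z, z)

    def test_zero_fields_give_zero_trace(self):
        trace = piv.strain_trace([self._const_field(0.0)] * 3, 0.1)
        np.testing.assert_array_equal(trace.mean_strain_rate, 0.0)

    def test_constant_scalar_passes_through(self):
        trace = piv.strain_trace([self._const_field(0.7)] * 2, 0.1)
        np.testing.assert_allclose(trace.mean_strain_rate, 0.7)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            piv.strain_trace([self._const_field(1.0)], 0.1,
                             mask=np.zeros((64, 64), bool))

    def test_trace_periodicity_matches_beat_rate(self):
        spec = syn.SyntheticVideoSpec(
            beat=(syn.BeatWaveformSpec(1.0, amplitude=0.08),),
            duration=3.0, frame_rate=15.0, image_size=(96, 96),
            base_radius=(32.0,), noise_sd=0.0, seed=13)
        stack, _ = syn.gen_contraction_video(spec)
        _, trace = piv.analyze_stack_strain(stack)
        x = trace.mean_strain_rate - trace.mean_strain_rate.mean()
        ac = np.correlate(x, x, mode="full")[len(x) - 1:]
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(ac)
        # the strongest nonzero-lag peak sits at the beat period
        lag_s = peaks[np.argmax(ac[peaks])] / 15.0
        assert lag_s == pytest.approx(1.0, abs=1.5 / 15.0)


class TestContractionMetrics:
    def test_negative_rates_contribute_nothing(self):
        trace = piv.StrainTrace(np.arange(5) * 0.1, np.full(5, -0.3))
        m = piv.contraction_metrics(trace, n_beats=2)
        assert m.cumulative_strain == 0.0

    def test_rectangular_pulse_arithmetic(self):
        # height 0.2 /s for 0.5 s -> cumulative 0.1; one beat -> 0.1 per beat
        dt = 0.05
        t = np.arange(40) * dt
        rate = np.where((t >= 1.0) & (t < 1.5), 0.2, 0.0)
        m = piv.contraction_metrics(piv.StrainTrace(t, rate), n_beats=1)
        assert m.cumulative_strain == pytest.approx(0.1, abs=1e-12)
        assert m.strain_per_beat == pytest.approx(0.1, abs=1e-12)

    def test_no_beats_leaves_per_beat_absent(self):
        trace = piv.StrainTrace(np.arange(5) * 0.1, np.full(5, 0.2))
        m = piv.contraction_metrics(trace, n_beats=0)
        assert m.strain_per_beat is None and m.cumulative_strain > 0

    def test_cumulative_strain_stable_under_resampling(self):
        # same synthetic motion sampled at 15 and 30 fps; inter-frame
        # motion kept above the ~0.1 px subpixel floor at both rates
        vals = {}
        for fps in (15.0, 30.0):
            spec = syn.SyntheticVideoSpec(
                beat=(syn.BeatWaveformSpec(0.5, duty_fraction=0.5,
                                           amplitude=0.15),),
                duration=2.0, frame_rate=fps, image_size=(128, 128),
                base_radius=(44.0,), noise_sd=0.0, seed=17)
            stack, _ = syn.gen_contraction_video(spec)
            _, trace = piv.analyze_stack_strain(stack)
            vals[fps] = piv.contraction_metrics(trace, 1).cumulative_strain
        assert vals[30.0] == pytest.approx(vals[15.0], rel=0.10)


class TestHeatmap:
    def _uniform_field(self, speed_px):
        g = np.arange(4) * 8.0
        u = np.full((4, 4), speed_px)
        return piv.VelocityField(g, g, u, np.zeros((4, 4)),
                                 np.ones((4, 4), bool))

    def test_zero_field_is_uniform_bottom_of_scale(self):
        r = piv.render_velocity_heatmap(self._uniform_field(0.0), 1.0, 1 / 30)
        assert np.all(r.clipped == 0.0) and r.clip_fraction == 0.0

    def test_top_of_scale_speed_saturates(self):
        r = piv.render_velocity_heatmap(self._uniform_field(28.0 / 30), 1.0,
                                        1 / 30)
        np.testing.assert_allclose(r.clipped, 28.0)

    def test_overspeed_clipped_and_reported(self):
        r = piv.render_velocity_heatmap(self._uniform_field(56.0 / 30), 1.0,
                                        1 / 30)
        np.testing.assert_allclose(r.clipped, 28.0)
        assert r.clip_fraction == 1.0
        assert r.speed_um_s.max() == pytest.approx(56.0)

    def test_missing_units_rejected(self):
        with pytest.raises(ValueError):
            piv.render_velocity_heatmap(self._uniform_field(1.0), None, 1 / 30)
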