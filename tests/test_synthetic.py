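"""Generator self-consistency: every ground-truth value must be re-derivable
from the generated artifact by brute force."""
import numpy as np
import pytest
from scipy import signal, stats

from beatkit import synthetic as syn


class TestBeatWaveform:
    def test_pulse_count_matches_frequency(self):
        spec = syn.BeatWaveformSpec(frequency=1.0, duty_fraction=0.3)
        t = np.arange(0.0, 10.0, 0.01)
        s = syn.gen_beat_waveform(spec, t)
        assert s.min() >= 0.0 and s.max() == pytest.approx(1.0)
        interior = (s[1:-1] > s[:-2]) & (s[1:-1] > s[2:]) & (s[1:-1] > 0.5)
        assert interior.sum() == 10

    def test_amplitude_does_not_affect_normalized_waveform(self):
        t = np.arange(0.0, 4.0, 0.01)
        s1 = syn.gen_beat_waveform(syn.BeatWaveformSpec(1.0, amplitude=0.05), t)
        s2 = syn.gen_beat_waveform(syn.BeatWaveformSpec(1.0, amplitude=0.4), t)
        np.testing.assert_array_equal(s1, s2)

    def test_autocorrelation_peak_at_beat_period(self):
        # brute-force autocorrelation of a 2 Hz train peaks first at 0.5 s
        spec = syn.BeatWaveformSpec(frequency=2.0)
        dt = 0.01
        s = syn.gen_beat_waveform(spec, np.arange(0.0, 5.0, dt))
        s = s - s.mean()
        ac = signal.correlate(s, s, mode="full")[len(s) - 1:]
        peaks, _ = signal.find_peaks(ac)
        assert peaks[0] * dt == pytest.approx(0.5, abs=dt)

    def test_asymmetric_shape_rises_faster_than_it_relaxes(self):
        spec = syn.BeatWaveformSpec(1.0, duty_fraction=0.4,
                                    waveform_shape="asymmetric")
        t = np.arange(0.0, 1.0, 0.001)
        s = syn.gen_beat_waveform(spec, t)
        t_peak = t[np.argmax(s)]
        assert t_peak < 0.5 * spec.duty_fraction / spec.frequency

    @pytest.mark.parametrize("bad", [
        dict(frequency=0.0), dict(frequency=-1.0),
        dict(frequency=1.0, duty_fraction=1.2),
        dict(frequency=1.0, amplitude=0.0),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.BeatWaveformSpec(**bad)


class TestContractionVideo:
    def test_no_motion_when_amplitude_is_negligible(self):
        spec = syn.SyntheticVideoSpec(
            beat=(syn.BeatWaveformSpec(1.0, amplitude=1e-9),),
            duration=1.0, frame_rate=10.0, noise_sd=0.0, seed=0)
        stack, _ = syn.gen_contraction_video(spec)
        assert np.abs(stack.frames - stack.frames[0]).max() < 1e-6

    def test_area_ratio_follows_disk_geometry(self, one_hz_video):
        # min over t of bright area / max area = (1 - amplitude)^2
        stack, truth = one_hz_video
        areas = (stack.frames > 0.27).sum(axis=(1, 2)).astype(float)
        ratio = areas.min() / areas.max()
        assert ratio == pytest.approx(0.81, abs=0.01)

    def test_mask_area_tracks_analytic_radius(self, one_hz_video):
        stack, truth = one_hz_video
        areas = (stack.frames > 0.27).sum(axis=(1, 2)).astype(float)
        expected = np.asarray(truth.truths["area_px2"][0])
        np.testing.assert_allclose(areas, expected, rtol=0.03)

    def test_seed_determinism(self):
        spec = syn.SyntheticVideoSpec(
            beat=(syn.BeatWaveformSpec(1.0),), duration=1.0, frame_rate=10.0,
            noise_sd=0.02, seed=5)
        s1, _ = syn.gen_contraction_video(spec)
        s2, _ = syn.gen_contraction_video(spec)
        assert s1.frames.tobytes() == s2.frames.tobytes()

    def test_overlapping_foci_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            syn.SyntheticVideoSpec(
                beat=(syn.BeatWaveformSpec(1.0), syn.BeatWaveformSpec(2.0)),
                base_radius=(30.0, 30.0),
                centers=((48.0, 40.0), (48.0, 60.0)))


class TestSpecklePair:
    def test_zero_shift_gives_identical_frames(self):
        a, b, _ = syn.gen_speckle_pair((0.0, 0.0), seed=1)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_integer_shift_recovered_by_bruteforce_correlation(self):
        a, b, truth = syn.gen_speckle_pair((3.0, -2.0), seed=2)
        am, bm = a - a.mean(), b - b.mean()
        c = signal.fftconvolve(bm, am[::-1, ::-1], mode="full")
        iy, ix = np.unravel_index(np.argmax(c), c.shape)
        assert (iy - (a.shape[0] - 1), ix - (a.shape[1] - 1)) == (3, -2)

    def test_subpixel_shift_peak_lies_between_integer_lags(self):
        a, b, _ = syn.gen_speckle_pair((0.5, 0.0), seed=3)
        am, bm = a - a.mean(), b - b.mean()
        c = signal.fftconvolve(bm, am[::-1, ::-1], mode="full")
        iy, ix = np.unravel_index(np.argmax(c), c.shape)
        lag_y = iy - (a.shape[0] - 1)
        assert lag_y in (0, 1)
        # 3-point parabolic refinement lands strictly between 0 and 1
        cm, c0, cp = c[iy - 1, ix], c[iy, ix], c[iy + 1, ix]
        frac = (cm - cp) / (2.0 * (cm - 2.0 * c0 + cp))
        assert 0.0 < lag_y + frac < 1.0

    def test_shift_beyond_quarter_image_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_speckle_pair((40.0, 0.0), image_size=(128, 128))


class TestCalciumTrace:
    def test_peak_level_is_baseline_times_one_plus_dF(self):
        spec = syn.SyntheticCalciumSpec(baseline=100.0, peak_dF=1.0,
                                        noise_sd=0.0, bleach_rate=0.0)
        _, trace, _ = syn.gen_calcium_trace(spec)
        assert trace.max() == pytest.approx(200.0)
        assert trace.min() == pytest.approx(100.0, rel=1e-6)

    def test_decay_is_exponential_with_requested_tau(self):
        # log(trace - asymptote) regresses to slope -1/tau = -4 /s
        spec = syn.SyntheticCalciumSpec(tau_decay=0.25, noise_sd=0.0)
        t, trace, _ = syn.gen_calcium_trace(spec)
        period, rise = 1.0 / spec.beat_frequency, spec.rise_time
        e_end = np.exp(-(period - rise) / spec.tau_decay)
        asym = spec.baseline * (1.0 - spec.peak_dF * e_end / (1.0 - e_end))
        seg = (t > rise + 0.01) & (t < period - 0.01)
        slope = stats.linregress(t[seg], np.log(trace[seg] - asym)).slope
        assert slope == pytest.approx(-4.0, rel=1e-6)

    def test_unresolvable_transients_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            syn.SyntheticCalciumSpec(beat_frequency=1.0, tau_decay=0.5)

    def test_stack_wraps_trace_with_disjoint_rois(self):
        spec = syn.SyntheticCalciumSpec(duration=2.0, noise_sd=0.0)
        stack, roi, bg, _ = syn.gen_calcium_stack(spec)
        assert not (roi & bg).any()
        assert stack.n_frames == 200


class TestAPTrace:
    def test_voltage_spans_mdp_to_peak(self):
        spec = syn.ap_spec_for_morphology("ventricular_like", n_beats=3)
        _, v, _ = syn.gen_ap_trace(spec)
        assert v.min() == pytest.approx(-60.0, abs=1e-6)
        assert v.max() == pytest.approx(30.0, abs=0.01)

    def test_upstroke_velocity_matches_request(self):
        # finite differences on the generated rapid-depolarizer upstroke
        spec = syn.ap_spec_for_morphology("rapid_depolarizer", n_beats=2)
        t, v, _ = syn.gen_ap_trace(spec)
        dvdt = np.diff(v) / np.diff(t) / 1000.0
        assert dvdt.max() == pytest.approx(88.0, rel=0.02)

    def test_one_upstroke_per_beat(self):
        spec = syn.ap_spec_for_morphology("ventricular_like", n_beats=5,
                                          rate=1.0)
        t, v, _ = syn.gen_ap_trace(spec)
        assert t[-1] == pytest.approx(5.0, abs=1e-3)
        dvdt = np.diff(v) / np.diff(t) / 1000.0
        ups, _ = signal.find_peaks(dvdt, height=10.0, distance=1000)
        assert len(ups) == 5

    def test_apd_crossings_at_requested_times(self):
        spec = syn.ap_spec_for_morphology("ventricular_like", n_beats=2)
        t, v, truth = syn.gen_ap_trace(spec)
        t_up = truth.truths["upstroke_time_s"][0]
        amp = spec.peak - spec.mdp
        for apd_ms, frac in [(spec.apd30, 0.3), (spec.apd50, 0.5),
                             (spec.apd90, 0.9)]:
            level = spec.peak - frac * amp
            after = (t > t_up + 0.005) & (t < t_up + 1.0 / spec.rate)
            idx = np.nonzero((v[after][:-1] > level) & (v[after][1:] <= level))[0]
            t_cross = t[after][idx[0]]
            assert (t_cross - t_up) * 1000.0 == pytest.approx(apd_ms, abs=0.5)

    def test_infeasible_morphology_rejected(self):
        with pytest.raises(ValueError):
            syn.SyntheticAPSpec(apd90=900.0, rate=1.0, apd30=200.0,
                                apd50=400.0)
        with pytest.raises(ValueError):
            syn.SyntheticAPSpec(apd30=300.0, apd50=200.0, apd90=400.0)


class TestCohortAndCt:
    def test_no_outliers_when_none_planted(self):
        df, truth = syn.gen_cohort(20, 24.0, 3.0, [], seed=0)
        assert not any(truth.truths["planted_flags"])

    def test_planted_value_exceeds_tukey_fence(self):
        from conftest import tukey_flags_bruteforce
        df, truth = syn.gen_cohort(20, 24.0, 3.0, [88.0], seed=1)
        flags = tukey_flags_bruteforce(df.dvdt_max.to_numpy())
        assert flags[-1]

    def test_cohort_determinism(self):
        d1, _ = syn.gen_cohort(10, 24.0, 3.0, [88.0], seed=9)
        d2, _ = syn.gen_cohort(10, 24.0, 3.0, [88.0], seed=9)
        assert d1.equals(d2)

    def test_ct_table_encodes_fold_as_cycle_shift(self):
        df, _ = syn.gen_ct_table(
            ["REF", "GENE"], ["control", "stim"],
            {"GENE": {"stim": 2.0}}, "REF", "control",
            n_replicates=2, ct_noise_sd=0.0, seed=0)
        dct = (df[df.gene == "GENE"].set_index("sample_id").ct
               - df[df.gene == "REF"].set_index("sample_id").ct)
        delta = (dct[dct.index.str.startswith("stim")].mean()
                 - dct[dct.index.str.startswith("control")].mean())
        assert delta == pytest.approx(-1.0)  # fold 2 = one cycle earlier

    def test_reference_gene_must_have_unit_fold(self):
        with pytest.raises(ValueError):
            syn.gen_ct_table(["REF", "G"], ["control", "s"],
                             {"REF": {"s": 2.0}}, "REF", "control")
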