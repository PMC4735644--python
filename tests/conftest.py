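import numpy as np
import pytest

from beatkit import synthetic as syn


@pytest.fixture(scope="session")
def one_hz_video():
    """Noise-free 1 Hz contraction video with ground truth (shared, read-only)."""
    spec = syn.SyntheticVideoSpec(
        beat=(syn.BeatWaveformSpec(frequency=1.0, amplitude=0.1),),
        duration=5.0, frame_rate=30.0, image_size=(96, 96),
        base_radius=(30.0,), noise_sd=0.0, seed=42)
    return syn.gen_contraction_video(spec)


@pytest.fixture(scope="session")
def calcium_trace_clean():
    """Noise-free 1 Hz calcium transient train (10 beats) with truth."""
    spec = syn.SyntheticCalciumSpec(beat_frequency=1.0, tau_decay=0.3,
                                    rise_time=0.05, duration=10.0,
                                    frame_rate=100.0, noise_sd=0.0, seed=7)
    return syn.gen_calcium_trace(spec)


@pytest.fixture(scope="session")
def ventricular_ap_clean():
    spec = syn.ap_spec_for_morphology("ventricular_like", n_beats=3, seed=3)
    t, v, truth = syn.gen_ap_trace(spec)
    return spec, t, v, truth


def tukey_flags_bruteforce(values):
    """Independent Tukey-fence oracle: sort, interpolate type-7 quartiles,
    threshold strictly above Q3 + 1.5*IQR."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return x[lo] + (h - lo) * (x[hi] - x[lo])

    q1, q3 = quantile(0.25), quantile(0.75)
    cutoff = q3 + 1.5 * (q3 - q1)
    return np.asarray(values) > cutoff
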