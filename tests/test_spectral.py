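"""Morlet CWT, wavelet coherence, phase-based directionality."""

import numpy as np
import pytest

from dynconn.errors import InsufficientDataError, ShapeMismatchError
from dynconn.spectral import (
    coherence_connectivity_regression,
    cwt_morlet,
    direction_estimate,
    dominant_frequency,
    time_averaged_coherence,
    wavelet_coherence,
)
from conftest import make_dff


def sinusoid(freq, duration, fs, phase=0.0, noise=0.0, seed=0):
    t = np.arange(int(duration * fs)) / fs
    x = np.sin(2 * np.pi * freq * t + phase)
    if noise:
        x = x + noise * np.random.default_rng(seed).normal(size=t.size)
    return make_dff(x, fs)


class TestCwt:
    def test_sinusoid_ridge_at_its_frequency(self, fs):
        s = cwt_morlet(sinusoid(0.3, 600, fs))
        f = dominant_frequency(s)
        assert f == pytest.approx(0.3, rel=2 ** (1 / 12) - 1)

    def test_zero_signal_zero_power(self, fs):
        s = cwt_morlet(make_dff(np.zeros(int(120 * fs)), fs))
        assert np.max(np.abs(s.coeffs)) < 1e-10

    def test_two_tone_has_two_ridges(self, fs):
        t = np.arange(int(600 * fs)) / fs
        x = make_dff(np.sin(2 * np.pi * 0.1 * t) + np.sin(2 * np.pi * 1.0 * t), fs)
        s = cwt_morlet(x)
        power = np.where(s.valid, s.power, np.nan)
        # flatten the 1/f scale weighting so equal-amplitude tones give
        # comparable ridge heights
        profile = np.nanmean(power, axis=1) * s.freqs
        from scipy.signal import find_peaks

        pk, _ = find_peaks(profile, height=0.2 * np.nanmax(profile))
        found = sorted(s.freqs[pk])
        assert any(abs(f - 0.1) / 0.1 < 0.1 for f in found)
        assert any(abs(f - 1.0) / 1.0 < 0.1 for f in found)

    def test_chirp_ridge_increases(self, fs):
        t = np.arange(int(600 * fs)) / fs
        f_inst = 0.2 + (0.4 - 0.2) * t / t[-1]
        x = make_dff(np.sin(2 * np.pi * np.cumsum(f_inst) / fs), fs)
        s = cwt_morlet(x)
        early = dominant_frequency(s, 60, 180)
        late = dominant_frequency(s, 420, 540)
        assert late > early

    def test_freqs_decreasing_and_in_range(self, fs):
        s = cwt_morlet(sinusoid(0.3, 120, fs))
        assert np.all(np.diff(s.freqs) < 0)
        f = dominant_frequency(s)
        assert s.freqs.min() <= f <= s.freqs.max()


class TestCoherence:
    def test_self_coherence_near_one(self, fs):
        x = sinusoid(0.3, 300, fs, noise=0.3, seed=1)
        m = wavelet_coherence(x, make_dff(x.values.copy(), fs, cell_id="b"))
        assert m.coherence[m.valid].min() >= 0.99

    def test_bounds_on_random_inputs(self, fs, rng):
        for _ in range(3):
            a = make_dff(rng.normal(size=int(120 * fs)), fs)
            b = make_dff(rng.normal(size=int(120 * fs)), fs)
            m = wavelet_coherence(a, b)
            assert np.all(m.coherence >= 0.0) and np.all(m.coherence <= 1.0)

    def test_phase_delay_identity_across_frequencies(self, fs):
        # phase at the oscillation frequency = 2*pi*f*tau (tau chosen so < pi)
        for f, tau in [(0.1, 0.5), (0.3, 0.5), (1.0, 0.3)]:
            x = sinusoid(f, 600, fs, noise=0.2, seed=2)
            y_vals = np.roll(x.values, int(round(tau * fs)))
            y = make_dff(y_vals, fs, cell_id="y")
            m = wavelet_coherence(x, y)
            k = np.argmin(np.abs(m.freqs - f))
            ph = np.angle(np.mean(np.exp(1j * m.phase[k, m.valid[k]])))
            assert ph == pytest.approx(2 * np.pi * f * tau, abs=0.15)

    def test_phase_antisymmetry_exact(self, fs, rng):
        a = make_dff(rng.normal(size=int(120 * fs)), fs, cell_id="a")
        b = make_dff(rng.normal(size=int(120 * fs)), fs, cell_id="b")
        m1 = wavelet_coherence(a, b)
        m2 = wavelet_coherence(b, a)
        np.testing.assert_allclose(m1.phase, -m2.phase, atol=1e-10)

    def test_independent_noise_materially_below_one(self, fs, rng):
        a = make_dff(rng.normal(size=int(300 * fs)), fs)
        b = make_dff(rng.normal(size=int(300 * fs)), fs)
        m = wavelet_coherence(a, b)
        assert time_averaged_coherence(m) < 0.6  # smoothing defeats coh==1

    def test_length_mismatch(self, fs):
        with pytest.raises(ShapeMismatchError):
            wavelet_coherence(
                make_dff(np.ones(100), fs), make_dff(np.ones(101), fs)
            )


class TestTimeAveragedCoherence:
    def test_self_is_near_one(self, fs):
        x = sinusoid(0.3, 200, fs, noise=0.3, seed=3)
        m = wavelet_coherence(x, make_dff(x.values.copy(), fs, cell_id="b"))
        assert time_averaged_coherence(m) >= 0.99

    def test_monotone_in_shared_fraction(self):
        from dynconn.synth import SynthConfig, render_traces

        means = []
        for sf in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(3):
                cfg = SynthConfig(
                    n_cells=2, duration=300.0, base_rate=0.2,
                    shared_fraction=sf, noise_sd=0.02, seed=seed,
                )
                traces, _ = render_traces(cfg)
                a = make_dff((traces[0] - 100) / 100, cfg.fs, "a")
                b = make_dff((traces[1] - 100) / 100, cfg.fs, "b")
                vals.append(time_averaged_coherence(wavelet_coherence(a, b)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestDirection:
    def test_zero_lag_undetermined(self, fs):
        x = sinusoid(0.3, 300, fs, noise=0.1, seed=4)
        m = wavelet_coherence(x, make_dff(x.values.copy(), fs, cell_id="b"))
        assert direction_estimate(m).leader == "undetermined"

    def test_delayed_copy_names_leader_and_flips_on_swap(self, fs):
        x = sinusoid(0.3, 600, fs, noise=0.2, seed=5)
        x.cell_id = "lead"
        y = make_dff(np.roll(x.values, int(0.5 * fs)), fs, cell_id="lag")
        m = wavelet_coherence(x, y)
        d = direction_estimate(m)
        assert d.leader == "lead" and d.mean_phase > 0
        d2 = direction_estimate(wavelet_coherence(y, x))
        assert d2.leader == "lead"
        assert d2.mean_phase == pytest.approx(-d.mean_phase, abs=1e-10)


class TestCoherenceConnectivityRegression:
    def test_identity_vectors(self):
        v = np.array([0.2, 0.5, 0.8])
        assert coherence_connectivity_regression(v, v) == pytest.approx(1.0)

    def test_anti_ordered(self):
        assert coherence_connectivity_regression(
            np.array([0.1, 0.5, 0.9]), np.array([0.9, 0.5, 0.1])
        ) == pytest.approx(-1.0)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            coherence_connectivity_regression(np.ones(2), np.ones(2))
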