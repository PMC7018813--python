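"""Four-metric composite weight: oracles, invariants, windowing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynconn.connectivity import (
    classify_strength,
    composite_weight,
    derivative_correlation,
    final_weights,
    pearson,
    percent_change,
    smooth_rloess,
    spectrum_correlation,
    timevarying_weights,
    windowed_mean_correlation,
)
from dynconn.errors import InvalidParameterError, ShapeMismatchError, WindowError
from conftest import make_dff


def brute_force_pearson(x, y):
    """Independent covariance-based oracle."""
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / (n - 1)
    sx = (sum((a - mx) ** 2 for a in x) / (n - 1)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / (n - 1)) ** 0.5
    return cov / (sx * sy)


class TestPearson:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=100)
        assert pearson(x, x) == 1.0
        assert pearson(x, -x) == -1.0

    def test_hand_oracle(self):
        assert pearson([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 1000))
            assert pearson(x, y) == pytest.approx(
                brute_force_pearson(x, y), abs=1e-12
            )

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(pearson(np.ones(10), np.arange(10.0)))

    def test_length_mismatch(self):
        with pytest.raises(ShapeMismatchError):
            pearson(np.ones(3), np.ones(4))

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50))
    def test_bounded_and_symmetric(self, xs):
        rng = np.random.default_rng(0)
        x = np.asarray(xs)
        y = rng.normal(size=x.size)
        r = pearson(x, y)
        if np.isfinite(r):
            assert -1.0 <= r <= 1.0
            assert r == pearson(y, x)


class TestSpectrumCorrelation:
    def test_identical_traces(self, rng):
        x = make_dff(rng.normal(size=500))
        assert spectrum_correlation(x, x) == pytest.approx(1.0)

    def test_phase_shift_invisible(self, fs):
        t = np.arange(int(60 * fs)) / fs
        x = make_dff(np.sin(2 * np.pi * 0.5 * t), fs)
        y = make_dff(np.sin(2 * np.pi * 0.5 * t + np.pi / 2), fs)
        assert spectrum_correlation(x, y) > 0.99

    def test_disjoint_frequencies_uncorrelated(self, fs):
        t = np.arange(int(600 * fs)) / fs
        x = make_dff(np.sin(2 * np.pi * 0.1 * t), fs)
        y = make_dff(np.sin(2 * np.pi * 1.0 * t), fs)
        assert spectrum_correlation(x, y) < 0.1


class TestWindowedMean:
    def test_identical(self, rng, fs):
        x = make_dff(rng.normal(size=int(60 * fs)), fs)
        assert windowed_mean_correlation(x, x) == pytest.approx(1.0)

    def test_negated(self, rng, fs):
        v = rng.normal(size=int(60 * fs))
        assert windowed_mean_correlation(
            make_dff(v, fs), make_dff(-v, fs)
        ) == pytest.approx(-1.0)

    def test_piecewise_signs_average_to_zero(self, rng, fs):
        w = int(10 * fs)
        v = rng.normal(size=6 * w)
        sign = np.repeat([1.0, -1.0, 1.0, -1.0, 1.0, -1.0], w)
        assert windowed_mean_correlation(
            make_dff(v, fs), make_dff(sign * v, fs)
        ) == pytest.approx(0.0, abs=1e-12)

    def test_too_short_raises(self, fs):
        with pytest.raises(WindowError):
            windowed_mean_correlation(
                make_dff(np.ones(10), fs), make_dff(np.ones(10), fs)
            )


class TestRloess:
    def test_constant_reproduced(self):
        np.testing.assert_allclose(smooth_rloess(np.full(100, 3.3)), 3.3)

    def test_exact_quadratic_reproduced(self):
        # local quadratic fits reproduce a quadratic exactly; tolerance is
        # relative to the signal's span (q crosses zero inside the domain)
        t = np.linspace(0, 1, 400)
        q = 3 + 2 * t - 5 * t**2
        np.testing.assert_allclose(
            smooth_rloess(q), q, atol=1e-6 * np.max(np.abs(q))
        )

    def test_gross_outlier_suppressed(self):
        t = np.linspace(0, 1, 400)
        q = 3 + 2 * t - 5 * t**2
        dirty = q.copy()
        dirty[200] += 50.0
        out = smooth_rloess(dirty)
        assert abs(out[200] - q[200]) <= 0.05 * abs(q[200])

    def test_too_short_raises(self):
        with pytest.raises(WindowError):
            smooth_rloess(np.ones(3))


class TestDerivativeCorrelation:
    def test_self(self, rng, fs):
        x = make_dff(np.cumsum(rng.normal(size=500)), fs)
        assert derivative_correlation(x, x) == pytest.approx(1.0)

    def test_offset_invariance(self, rng, fs):
        v = np.cumsum(rng.normal(size=500))
        x = make_dff(v, fs)
        y = make_dff(v + 42.0, fs)
        assert derivative_correlation(x, y) == pytest.approx(1.0, abs=1e-9)

    def test_positive_rescale_invariance(self, rng, fs):
        v = np.cumsum(rng.normal(size=500))
        r1 = derivative_correlation(make_dff(v, fs), make_dff(3.0 * v + 1.0, fs))
        assert r1 == pytest.approx(1.0, abs=1e-9)

    def test_long_delay_decorrelates_sparse_events(self, fs):
        from dynconn.events import EventTrain
        from dynconn.synth import SynthConfig, render_trace

        cfg = SynthConfig(n_cells=1, duration=300.0, noise_sd=0.0, seed=0)
        ev = np.arange(10.0, 280.0, 20.0)
        a = render_trace(EventTrain(cell_id="a", times=ev), cfg)
        b = render_trace(EventTrain(cell_id="b", times=ev + 15.0), cfg)
        r = derivative_correlation(
            make_dff((a - 100) / 100, cfg.fs), make_dff((b - 100) / 100, cfg.fs)
        )
        assert abs(r) < 0.2


class TestCompositeAndSeries:
    def test_self_composite_is_one(self, rng, fs):
        x = make_dff(rng.normal(size=int(60 * fs)), fs, cell_id="a")
        pw = composite_weight(x, x)
        assert pw.w_composite == pytest.approx(1.0)
        assert np.allclose(pw.components, 1.0)

    def test_composite_is_mean_of_components(self):
        from dynconn.connectivity import PairWeight

        pw = PairWeight("a", "b", 1.0, 1.0, 1.0, -1.0)
        assert pw.w_composite == pytest.approx(0.5)

    def test_undefined_components_excluded(self):
        from dynconn.connectivity import PairWeight

        pw = PairWeight("a", "b", 0.6, float("nan"), 0.2, float("nan"))
        assert pw.w_composite == pytest.approx(0.4)

    def test_symmetry(self, rng, fs):
        n = int(60 * fs)
        x = make_dff(rng.normal(size=n), fs, "a")
        y = make_dff(rng.normal(size=n), fs, "b")
        a = composite_weight(x, y)
        b = composite_weight(y, x)
        assert a.w_composite == pytest.approx(b.w_composite, abs=1e-12)

    def test_ten_minute_recording_gives_ten_intervals(self, fs):
        rng = np.random.default_rng(0)
        n = int(600 * fs)
        traces = [make_dff(rng.normal(size=n), fs, f"c{i}") for i in range(3)]
        series = timevarying_weights(traces)
        assert all(len(ws) == 10 for ws in series.values())
        assert len(series) == 3

    def test_stationary_identical_traces_flat_ones(self, fs):
        rng = np.random.default_rng(1)
        v = rng.normal(size=int(180 * fs))
        traces = [make_dff(v, fs, "a"), make_dff(v, fs, "b")]
        ws = timevarying_weights(traces)[("a", "b")]
        np.testing.assert_allclose(ws.weights, 1.0, atol=1e-9)

    def test_final_weights_matrix_shape_and_symmetry(self, fs):
        rng = np.random.default_rng(2)
        n = int(120 * fs)
        traces = [make_dff(rng.normal(size=n), fs, f"c{i}") for i in range(3)]
        m = final_weights(timevarying_weights(traces))
        assert m.weights.shape == (3, 3)
        np.testing.assert_allclose(m.weights, m.weights.T)
        np.testing.assert_allclose(np.diag(m.weights), 1.0)


class TestPercentChange:
    def test_flat_series_zero_percent(self):
        pc, mean = percent_change(np.full(5, 0.5), np.full(5, 0.5))
        np.testing.assert_allclose(pc, 0.0)
        assert mean == 0.0

    def test_fifty_percent_rise(self):
        pc, _ = percent_change(np.array([0.75]), np.array([0.5, 0.5]))
        assert pc[0] == pytest.approx(50.0)

    def test_epsilon_guard_near_zero_baseline(self):
        pc, _ = percent_change(np.array([0.1]), np.array([0.001]))
        # denominator clamps at 0.05 rather than 0.001
        assert pc[0] == pytest.approx(100.0 * 0.099 / 0.05)


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "w,label",
        [
            (0.0, "weak"),
            (0.29, "weak"),
            (0.3, "low"),
            (0.5, "moderate"),
            (0.7, "strong"),
            (0.85, "strong"),
            (0.9, "very strong"),
            (1.0, "very strong"),
            (-0.85, "strong"),
        ],
    )
    def test_bins(self, w, label):
        assert classify_strength(w) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidParameterError):
            classify_strength(1.5)
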