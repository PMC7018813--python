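"""Composite four-metric functional connectivity in sliding time windows.

For each pair of ΔF/F₀ traces, four Pearson-type coefficients are computed on
every 1-minute interval of the recording:

``w_time``
    plain Pearson correlation of the two traces over the interval;
``w_spectrum``
    Pearson correlation of their one-sided periodogram magnitudes (DC bin
    excluded) — spectral similarity with phase discarded;
``w_window``
    the mean of the Pearson correlations over the interval's six 10-second
    sub-windows — localized co-fluctuation that a whole-interval coefficient
    averages away;
``w_derivative``
    Pearson correlation of the first derivatives of the two traces after
    robust local-quadratic (rloess, 2.5% span) smoothing — sensitive to
    coincident onsets of activity rather than shared baseline.

The composite weight is the unweighted mean of whichever of the four are
defined (a coefficient is undefined when a window has zero variance; such
windows are skipped, not zero-filled, to avoid biasing the mean downward).
The per-interval composite series is the time-varying connectivity; its mean
over intervals is the final per-pair weight, assembled into a symmetric
unit-diagonal connectivity matrix. Percent change of the series against a
baseline window quantifies connectivity fluctuation over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .errors import InvalidParameterError, ShapeMismatchError, WindowError
from .trace_io import DffTrace

__all__ = [
    "PairWeight",
    "WeightSeries",
    "ConnectivityMatrix",
    "pearson",
    "spectrum_correlation",
    "windowed_mean_correlation",
    "smooth_rloess",
    "derivative_correlation",
    "composite_weight",
    "timevarying_weights",
    "final_weights",
    "percent_change",
    "classify_strength",
]

# ------------------------------------------------------------------ metrics


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; NaN when either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ShapeMismatchError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ShapeMismatchError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def _periodogram_magnitude(values: np.ndarray, fs: float) -> np.ndarray:
    """One-sided periodogram of the mean-removed trace, DC bin dropped."""
    _, pxx = _signal.periodogram(values, fs=fs, detrend="constant")
    return pxx[1:]


def spectrum_correlation(x: DffTrace, y: DffTrace) -> float:
    """Pearson correlation between the two traces' power spectra.

    Identical signals score 1 regardless of relative phase; signals with
    disjoint frequency content score near or below 0.
    """
    if len(x) != len(y) or x.fs != y.fs:
        raise ShapeMismatchError("traces must share length and sampling rate")
    return pearson(
        _periodogram_magnitude(x.values, x.fs),
        _periodogram_magnitude(y.values, y.fs),
    )


def windowed_mean_correlation(
    x: DffTrace,
    y: DffTrace,
    sub_window: float = 10.0,
    n_sub: int = 6,
) -> float:
    """Mean Pearson r over ``n_sub`` consecutive sub-windows of ``sub_window`` s.

    Zero-variance sub-windows are skipped; NaN if every sub-window skips.
    """
    if len(x) != len(y) or x.fs != y.fs:
        raise ShapeMismatchError("traces must share length and sampling rate")
    w = int(round(sub_window * x.fs))
    if len(x) < n_sub * w:
        raise WindowError(
            f"trace of {len(x)} samples cannot host {n_sub} sub-windows of {w}"
        )
    rs = []
    for i in range(n_sub):
        sl = slice(i * w, (i + 1) * w)
        r = pearson(x.values[sl], y.values[sl])
        if np.isfinite(r):
            rs.append(r)
    return float(np.mean(rs)) if rs else float("nan")


# ------------------------------------------------------------------ rloess


def smooth_rloess(
    values: np.ndarray, span: float = 0.025, n_robust: int = 5
) -> np.ndarray:
    """Robust local quadratic regression (rloess) over a fractional span.

    Each point is fit by a weighted 2nd-order polynomial over its
    ``round(span*N)`` nearest samples (floor 5), with tricube distance
    weights; ``n_robust`` bisquare reweighting passes suppress outliers.
    Windows are clamped at the edges so every fit uses the full span.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    w = max(5, int(round(span * n)))
    if w > n:
        raise WindowError(f"span window {w} exceeds series length {n}")
    if n < 5:
        raise WindowError("need at least 5 samples for a local quadratic")

    centers = np.arange(n)
    starts = np.clip(centers - w // 2, 0, n - w)
    idx = starts[:, None] + np.arange(w)[None, :]  # (n, w)
    t = (idx - centers[:, None]).astype(float)  # local abscissa
    dmax = np.max(np.abs(t), axis=1, keepdims=True)
    tri = (1.0 - (np.abs(t) / dmax) ** 3) ** 3
    tri = np.clip(tri, 0.0, None)
    # guard: ensure every window retains positive total weight
    tri[np.all(tri <= 0, axis=1)] = 1.0

    yw = y[idx]  # (n, w)
    X = np.stack([np.ones_like(t), t, t * t], axis=2)  # (n, w, 3)
    robust = np.ones_like(tri)

    fitted = y.copy()
    for _ in range(n_robust + 1):
        wts = tri * robust
        XtW = X.transpose(0, 2, 1) * wts[:, None, :]  # (n, 3, w)
        A = XtW @ X  # (n, 3, 3)
        b = XtW @ yw[:, :, None]  # (n, 3, 1)
        # ridge jitter keeps degenerate windows solvable
        A += 1e-12 * np.eye(3)[None]
        beta = np.linalg.solve(A, b)
        fitted = beta[:, 0, 0]
        resid = y - fitted
        # scale floor: keeps machine-precision residuals from zeroing all
        # weights when the data are locally exact polynomials
        floor = 1e-8 * (np.ptp(y) if np.ptp(y) > 0 else 1.0)
        s = max(float(np.median(np.abs(resid))), floor)
        u = np.clip(resid[idx] / (6.0 * s), -1.0, 1.0)
        robust = (1.0 - u * u) ** 2
    return fitted


def derivative_correlation(
    x: DffTrace, y: DffTrace, span: float = 0.025
) -> float:
    """Pearson r between first derivatives of the rloess-smoothed traces.

    Invariant to additive offsets and positive rescaling of either trace.
    """
    if len(x) != len(y) or x.fs != y.fs:
        raise ShapeMismatchError("traces must share length and sampling rate")
    dx = np.gradient(smooth_rloess(x.values, span=span))
    dy = np.gradient(smooth_rloess(y.values, span=span))
    return pearson(dx, dy)


# ------------------------------------------------------------- composites


@dataclass
class PairWeight:
    """The four component coefficients and their mean for one pair.

    Undefined components are NaN and excluded from the composite.
    """

    cell_a: str
    cell_b: str
    w_time: float
    w_spectrum: float
    w_window: float
    w_derivative: float

    @property
    def components(self) -> np.ndarray:
        return np.array(
            [self.w_time, self.w_spectrum, self.w_window, self.w_derivative]
        )

    @property
    def w_composite(self) -> float:
        c = self.components
        defined = c[np.isfinite(c)]
        return float(np.mean(defined)) if defined.size else float("nan")


def composite_weight(
    x: DffTrace,
    y: DffTrace,
    sub_window: float = 10.0,
    n_sub: int = 6,
    span: float = 0.025,
    _precomputed: dict | None = None,
) -> PairWeight:
    """All four coefficients for one pair on one analysis window.

    ``_precomputed`` optionally carries per-cell periodograms and smoothed
    derivatives (see :func:`timevarying_weights`) so shared per-cell work is
    done once per interval rather than once per pair.
    """
    if _precomputed is not None:
        spec_x, spec_y = _precomputed["spectrum"]
        dx, dy = _precomputed["derivative"]
        w_spec = pearson(spec_x, spec_y)
        w_der = pearson(dx, dy)
    else:
        w_spec = spectrum_correlation(x, y)
        w_der = derivative_correlation(x, y, span=span)
    w_time = pearson(x.values, y.values)
    n_fit = min(n_sub, len(x) // int(round(sub_window * x.fs)))
    if n_fit >= 1:
        w_win = windowed_mean_correlation(x, y, sub_window=sub_window, n_sub=n_fit)
    else:
        w_win = float("nan")
    return PairWeight(
        cell_a=x.cell_id,
        cell_b=y.cell_id,
        w_time=w_time,
        w_spectrum=w_spec,
        w_window=w_win,
        w_derivative=w_der,
    )


@dataclass
class WeightSeries:
    """Per-interval composite weights for one pair, intervals contiguous from 0."""

    cell_a: str
    cell_b: str
    weights: np.ndarray  # composite per interval
    pair_weights: list[PairWeight] | None = None

    def __len__(self) -> int:
        return self.weights.size


def _slice_trace(tr: DffTrace, a: int, b: int) -> DffTrace:
    return DffTrace(values=tr.values[a:b], fs=tr.fs, f0=tr.f0, cell_id=tr.cell_id)


def timevarying_weights(
    traces: list[DffTrace],
    interval: float = 60.0,
    sub_window: float = 10.0,
    n_sub: int = 6,
    span: float = 0.025,
) -> dict[tuple[str, str], WeightSeries]:
    """Composite weight of every pair on every non-overlapping interval.

    Intervals are ``interval`` seconds (paper-style 1-minute windows); a
    trailing partial interval shorter than ``interval/2`` is dropped.
    Returns a dict keyed by (cell_a, cell_b) label pairs in input order.
    """
    if not traces:
        raise InvalidParameterError("no traces")
    n = len(traces[0])
    fs = traces[0].fs
    for tr in traces:
        if len(tr) != n or tr.fs != fs:
            raise ShapeMismatchError("all traces must share length and rate")
    w = int(round(interval * fs))
    if n < w // 2:
        raise WindowError("recording shorter than half an interval")
    n_int = n // w
    if n - n_int * w >= w // 2:
        n_int += 1  # trailing partial >= interval/2 kept
    n_int = max(n_int, 1)

    pairs = [
        (i, j) for i in range(len(traces)) for j in range(i + 1, len(traces))
    ]
    series: dict[tuple[str, str], list[PairWeight]] = {
        (traces[i].cell_id, traces[j].cell_id): [] for i, j in pairs
    }
    for k in range(n_int):
        a, b = k * w, min((k + 1) * w, n)
        chunks = [_slice_trace(tr, a, b) for tr in traces]
        # shared per-cell work for this interval
        spectra = [_periodogram_magnitude(ch.values, fs) for ch in chunks]
        derivs = [np.gradient(smooth_rloess(ch.values, span=span)) for ch in chunks]
        for i, j in pairs:
            pw = composite_weight(
                chunks[i],
                chunks[j],
                sub_window=sub_window,
                n_sub=n_sub,
                span=span,
                _precomputed={
                    "spectrum": (spectra[i], spectra[j]),
                    "derivative": (derivs[i], derivs[j]),
                },
            )
            series[(traces[i].cell_id, traces[j].cell_id)].append(pw)
    return {
        key: WeightSeries(
            cell_a=key[0],
            cell_b=key[1],
            weights=np.array([pw.w_composite for pw in pws]),
            pair_weights=pws,
        )
        for key, pws in series.items()
    }


@dataclass
class ConnectivityMatrix:
    """Symmetric unit-diagonal matrix of final per-pair weights."""

    cells: list[str]
    weights: np.ndarray

    def pair(self, a: str, b: str) -> float:
        return float(
            self.weights[self.cells.index(a), self.cells.index(b)]
        )


def final_weights(
    series: dict[tuple[str, str], WeightSeries]
) -> ConnectivityMatrix:
    """Average each pair's series over intervals into one matrix."""
    cells: list[str] = []
    for a, b in series:
        for c in (a, b):
            if c not in cells:
                cells.append(c)
    n = len(cells)
    m = np.eye(n)
    for (a, b), ws in series.items():
        val = float(np.nanmean(ws.weights)) if ws.weights.size else float("nan")
        i, j = cells.index(a), cells.index(b)
        m[i, j] = m[j, i] = val
    return ConnectivityMatrix(cells=cells, weights=m)


def percent_change(
    series: WeightSeries | np.ndarray,
    baseline: WeightSeries | np.ndarray | None = None,
    eps: float = 0.05,
) -> tuple[np.ndarray, float]:
    """Per-interval percent change from a baseline mean, and its average.

    ``100 * (w_t - w̄_base) / max(|w̄_base|, eps)``; the epsilon guard keeps
    near-zero baselines from exploding the ratio. With ``baseline=None`` the
    series is referenced to its own mean — a fluctuation measure.
    Returns (per-interval %, mean %).
    """
    w = series.weights if isinstance(series, WeightSeries) else np.asarray(series)
    if baseline is None:
        base = w
    else:
        base = (
            baseline.weights
            if isinstance(baseline, WeightSeries)
            else np.asarray(baseline)
        )
    base_mean = float(np.nanmean(base))
    if not np.isfinite(base_mean):
        raise InvalidParameterError("baseline mean undefined")
    denom = max(abs(base_mean), eps)
    pc = 100.0 * (w - base_mean) / denom
    return pc, float(np.nanmean(pc))


_STRENGTH_BINS = (
    (0.3, "weak"),
    (0.5, "low"),
    (0.7, "moderate"),
    (0.9, "strong"),
    (np.inf, "very strong"),
)


def classify_strength(w: float) -> str:
    """Empirical strength label for |w|: weak <0.3 ≤ low <0.5 ≤ moderate <0.7
    ≤ strong <0.9 ≤ very strong."""
    if not np.isfinite(w) or abs(w) > 1.0:
        raise InvalidParameterError(f"coefficient must lie in [-1, 1], got {w}")
    a = abs(w)
    for upper, label in _STRENGTH_BINS:
        if a < upper:
            return label
    return "very strong"  # pragma: no cover
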