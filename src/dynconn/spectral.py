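"""Continuous wavelet transform, wavelet coherence and phase directionality.

The transform uses the analytic Morlet wavelet with centre frequency
``omega0 = 6`` — the standard compromise between time and frequency
resolution for coherence work — evaluated in the Fourier domain:
``psi_hat(s*w) = pi**-0.25 * H(w) * exp(-(s*w - omega0)**2 / 2)``. Scales are
log-spaced (12 voices per octave by default) between the quarter-Nyquist
frequency and four cycles per record length, and each coefficient inside the
cone of influence (within one e-folding time ``sqrt(2)*s`` of either edge)
is flagged unreliable.

Magnitude-squared wavelet coherence smooths the auto- and cross-spectra in
time (Gaussian of width proportional to scale) and in scale (0.6-octave
boxcar) before forming ``|S(Wx Wy*)|**2 / (S(|Wx|**2) S(|Wy|**2))``; without
that smoothing the ratio is identically 1. The phase of the smoothed
cross-spectrum encodes lead/lag: positive phase means the first trace leads
(for a common oscillation at frequency f delayed by tau, phase = 2*pi*f*tau).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    ShapeMismatchError,
    WindowError,
)
from .trace_io import DffTrace

__all__ = [
    "Scalogram",
    "CoherenceMap",
    "DirectionEstimate",
    "cwt_morlet",
    "dominant_frequency",
    "wavelet_coherence",
    "time_averaged_coherence",
    "direction_estimate",
    "coherence_connectivity_regression",
]

OMEGA0 = 6.0
# Fourier factor: frequency = _FF / scale_seconds for the omega0=6 Morlet
_FF = (OMEGA0 + np.sqrt(2.0 + OMEGA0**2)) / (4.0 * np.pi)


@dataclass
class Scalogram:
    """Complex Morlet coefficients over (scale, time)."""

    coeffs: np.ndarray  # (n_scales, n_times) complex
    freqs: np.ndarray  # Hz, strictly decreasing with scale index
    scales: np.ndarray  # seconds
    coi: np.ndarray  # per-time minimum reliable frequency, Hz
    fs: float
    cell_id: str = "cell"

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coeffs) ** 2

    @property
    def valid(self) -> np.ndarray:
        """Boolean (scale, time) mask of cells inside the cone of influence."""
        return self.freqs[:, None] >= self.coi[None, :]


def _scale_grid(
    n: int, fs: float, voices_per_octave: int
) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced scales covering fs/4 down to 4 cycles per record."""
    f_max = fs / 4.0
    f_min = 4.0 * fs / n
    if f_min >= f_max:
        raise WindowError(f"trace of {n} samples too short for a wavelet grid")
    n_oct = np.log2(f_max / f_min)
    n_scales = int(np.floor(n_oct * voices_per_octave)) + 1
    freqs = f_max * 2.0 ** (-np.arange(n_scales) / voices_per_octave)
    scales = _FF / freqs
    return scales, freqs


def _coi_freq(n: int, fs: float) -> np.ndarray:
    """Minimum reliable frequency at each time index.

    A scale s is edge-affected within its e-folding time sqrt(2)*s of either
    edge; inverting gives f_coi(d) = sqrt(2) * _FF / d for edge distance d.
    """
    d = (np.minimum(np.arange(n), np.arange(n)[::-1]) + 1) / fs
    return np.sqrt(2.0) * _FF / d


def cwt_morlet(
    x: DffTrace, voices_per_octave: int = 12
) -> Scalogram:
    """Analytic Morlet CWT of a mean-removed trace, FFT-evaluated.

    The record is zero-padded to the next power of two to limit wrap-around.
    """
    if voices_per_octave < 1:
        raise InvalidParameterError("voices_per_octave must be >= 1")
    values = np.asarray(x.values, dtype=float)
    n = values.size
    scales, freqs = _scale_grid(n, x.fs, voices_per_octave)
    n_pad = int(2 ** np.ceil(np.log2(n)))
    xv = values - values.mean()
    xh = np.fft.fft(xv, n_pad)
    w = 2.0 * np.pi * np.fft.fftfreq(n_pad, d=1.0 / x.fs)
    pos = w > 0
    coeffs = np.empty((scales.size, n), dtype=complex)
    norm = np.pi**-0.25 * np.sqrt(2.0 * np.pi * x.fs)
    for k, s in enumerate(scales):
        psi_hat = np.zeros(n_pad)
        psi_hat[pos] = norm * np.sqrt(s) * np.exp(-0.5 * (s * w[pos] - OMEGA0) ** 2)
        coeffs[k] = np.fft.ifft(xh * psi_hat)[:n]
    return Scalogram(
        coeffs=coeffs,
        freqs=freqs,
        scales=scales,
        coi=_coi_freq(n, x.fs),
        fs=x.fs,
        cell_id=x.cell_id,
    )


def dominant_frequency(
    s: Scalogram, t_start: float = 0.0, t_stop: float | None = None
) -> float:
    """Frequency of maximal COI-masked mean power inside [t_start, t_stop)."""
    n = s.coeffs.shape[1]
    a = int(round(t_start * s.fs))
    b = n if t_stop is None else int(round(t_stop * s.fs))
    if not (0 <= a < b <= n):
        raise InvalidParameterError("window outside the recording")
    power = s.power[:, a:b]
    valid = s.valid[:, a:b]
    if not valid.any():
        raise InsufficientDataError("window fully inside the cone of influence")
    profile = np.full(s.freqs.size, np.nan)
    rows = valid.any(axis=1)
    masked = np.where(valid[rows], power[rows], np.nan)
    profile[rows] = np.nanmean(masked, axis=1)
    if not np.any(np.isfinite(profile)) or np.nanmax(profile) == 0:
        raise InsufficientDataError("no power in window")
    return float(s.freqs[np.nanargmax(profile)])


@dataclass
class CoherenceMap:
    """Smoothed magnitude-squared coherence and phase for one pair."""

    coherence: np.ndarray  # (n_scales, n_times) in [0, 1]
    phase: np.ndarray  # radians in (-pi, pi]; positive = cell_a leads
    freqs: np.ndarray
    scales: np.ndarray
    coi: np.ndarray
    fs: float
    cell_a: str = "a"
    cell_b: str = "b"

    @property
    def valid(self) -> np.ndarray:
        return self.freqs[:, None] >= self.coi[None, :]


def _smooth(
    field: np.ndarray, scales: np.ndarray, fs: float, voices_per_octave: int
) -> np.ndarray:
    """Scale-dependent Gaussian in time, 0.6-octave boxcar across scales.

    The time smoothing (std = one scale) is applied in the Fourier domain
    with reflect padding — the per-scale kernels span thousands of samples
    at the lowest frequencies, where direct convolution is prohibitive.
    """
    n = field.shape[1]
    pad = n

    def gauss_time(real_field: np.ndarray) -> np.ndarray:
        from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

        ext = np.pad(real_field, ((0, 0), (pad, pad)), mode="reflect")
        m = next_fast_len(ext.shape[1])
        w = 2.0 * np.pi * rfftfreq(m, d=1.0 / fs)
        transfer = np.exp(-0.5 * (scales[:, None] * w[None, :]) ** 2)
        return irfft(rfft(ext, n=m, axis=1) * transfer, n=m, axis=1)[
            :, pad : pad + n
        ]

    width = max(1, int(round(0.6 * voices_per_octave)))

    def boxcar_scale(real_field: np.ndarray) -> np.ndarray:
        return uniform_filter1d(real_field, width, axis=0, mode="nearest")

    # real and imaginary parts go through identical real-valued paths so
    # that swapping the pair (which conjugates the cross-spectrum) negates
    # the smoothed imaginary part bit-exactly -> exact phase antisymmetry
    if np.iscomplexobj(field):
        return boxcar_scale(gauss_time(field.real)) + 1j * boxcar_scale(
            gauss_time(field.imag)
        )
    return boxcar_scale(gauss_time(field))


def wavelet_coherence(
    x: DffTrace, y: DffTrace, voices_per_octave: int = 12
) -> CoherenceMap:
    """Magnitude-squared wavelet coherence and cross-spectrum phase.

    Coherence is clipped into [0, 1] against floating-point overshoot; the
    phase is antisymmetric under argument swap.
    """
    if len(x) != len(y) or x.fs != y.fs:
        raise ShapeMismatchError("traces must share length and sampling rate")
    wx = cwt_morlet(x, voices_per_octave)
    wy = cwt_morlet(y, voices_per_octave)
    # 1/s normalisation before smoothing (energy per unit scale)
    inv_s = 1.0 / wx.scales[:, None]
    sxx = _smooth(np.abs(wx.coeffs) ** 2 * inv_s, wx.scales, x.fs, voices_per_octave)
    syy = _smooth(np.abs(wy.coeffs) ** 2 * inv_s, wx.scales, x.fs, voices_per_octave)
    # cross-spectrum assembled from real/imag parts so that swapping the
    # arguments conjugates it bit-exactly (phase antisymmetry is then exact)
    xr, xi = wx.coeffs.real, wx.coeffs.imag
    yr, yi = wy.coeffs.real, wy.coeffs.imag
    cross = (xr * yr + xi * yi) * inv_s + 1j * ((xi * yr - xr * yi) * inv_s)
    sxy = _smooth(cross, wx.scales, x.fs, voices_per_octave)
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sxy) ** 2 / denom
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)
    return CoherenceMap(
        coherence=coh,
        phase=np.angle(sxy),
        freqs=wx.freqs,
        scales=wx.scales,
        coi=wx.coi,
        fs=x.fs,
        cell_a=x.cell_id,
        cell_b=y.cell_id,
    )


def time_averaged_coherence(
    m: CoherenceMap,
    f_band: tuple[float, float] | None = None,
) -> float:
    """Mean coherence over COI-valid cells, optionally within a band (Hz)."""
    mask = m.valid
    if f_band is not None:
        lo, hi = f_band
        mask = mask & (m.freqs[:, None] >= lo) & (m.freqs[:, None] <= hi)
    if not mask.any():
        raise InsufficientDataError("no COI-valid cells in the requested band")
    return float(m.coherence[mask].mean())


@dataclass
class DirectionEstimate:
    """Lead/lag call for one pair from coherent-phase statistics."""

    leader: str  # cell label or "undetermined"
    mean_phase: float  # radians, positive = cell_a leads
    peak_freq: float  # Hz
    support_fraction: float


def direction_estimate(
    m: CoherenceMap,
    coh_threshold: float = 0.7,
    min_support: float = 0.05,
    phase_floor: float = 0.1,
) -> DirectionEstimate:
    """Circular-mean phase near the pair's peak-coherence frequency.

    Cells within half an octave of the peak frequency, COI-valid and with
    coherence above ``coh_threshold``, vote with unit weight; the call is
    "undetermined" when support is thin or the mean phase is within the
    ``phase_floor`` of zero.
    """
    valid = m.valid
    band_mean = np.full(m.freqs.size, np.nan)
    rows = valid.any(axis=1)
    band_mean[rows] = np.nanmean(
        np.where(valid[rows], m.coherence[rows], np.nan), axis=1
    )
    if not np.any(np.isfinite(band_mean)):
        return DirectionEstimate("undetermined", float("nan"), float("nan"), 0.0)
    k_peak = int(np.nanargmax(band_mean))
    f_peak = float(m.freqs[k_peak])
    in_band = (m.freqs >= f_peak / np.sqrt(2)) & (m.freqs <= f_peak * np.sqrt(2))
    cells = valid & in_band[:, None]
    n_band = int(cells.sum())
    passing = cells & (m.coherence >= coh_threshold)
    support = passing.sum() / n_band if n_band else 0.0
    if support < min_support:
        return DirectionEstimate("undetermined", float("nan"), f_peak, support)
    ph = m.phase[passing]
    mean_phase = float(np.angle(np.mean(np.exp(1j * ph))))
    if abs(mean_phase) < phase_floor:
        leader = "undetermined"
    else:
        leader = m.cell_a if mean_phase > 0 else m.cell_b
    return DirectionEstimate(leader, mean_phase, f_peak, float(support))


def coherence_connectivity_regression(
    weights: np.ndarray, coherences: np.ndarray
) -> float:
    """Pearson r between per-pair composite weights and time-averaged coherence."""
    w = np.asarray(weights, dtype=float)
    c = np.asarray(coherences, dtype=float)
    if w.shape != c.shape:
        raise ShapeMismatchError("weights and coherences must align")
    if w.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    from .connectivity import pearson

    return pearson(w, c)
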