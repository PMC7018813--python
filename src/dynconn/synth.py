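"""Synthetic calcium-imaging data with known ground truth.

Generates Poisson spike trains with controllable pairwise synchrony, renders
them into GCaMP6s-like fluorescence traces (difference-of-exponentials kernel)
and into grayscale video stacks, and records the ground truth (spike times,
synchrony, ROI positions, baselines) needed to validate every downstream stage
of the pipeline against a known answer.

Synchrony model
---------------
Cells in a group share a common "mother" event train: a fraction
``shared_fraction`` of each cell's rate comes from events that are exactly
coincident across the group, the remainder from a private Poisson train.
Binomial thinning keeps the marginal rate of every cell at ``base_rate``
regardless of ``shared_fraction``, so synchrony is a single interpretable
dial with ground truth recorded per pair.

A "stimulus" (glutamate-like bath application) is emulated as a
piecewise-constant switch at ``stimulus_time``: the firing rate is multiplied
by ``post_rate_gain`` and the shared fraction jumps to
``post_shared_fraction``. A control condition uses a mild rate gain with
unchanged synchrony (media perfusion perturbs firing but not coupling).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, LayoutError
from .events import EventTrain

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "poisson_train",
    "correlated_trains",
    "render_trace",
    "render_video",
    "control_condition",
    "glutamate_condition",
    "write_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic recording.

    Rates are per-cell event rates in Hz; ``shared_fraction`` is the fraction
    of each cell's events drawn from the common mother train (exact
    coincidences across the group). ``stimulus_time=None`` means no
    perturbation. The calcium kernel is ``A*(exp(-t/decay) - exp(-t/rise))``
    normalised to unit peak; ``amplitude`` scales it in fluorescence units.
    """

    n_cells: int = 8
    fs: float = 22.7
    duration: float = 600.0
    base_rate: float = 0.2
    shared_fraction: float = 0.3
    kernel_rise: float = 0.2
    kernel_decay: float = 1.0
    noise_sd: float = 0.02
    stimulus_time: float | None = None
    post_rate_gain: float = 1.0
    post_shared_fraction: float | None = None
    seed: int = 0
    amplitude: float = 1.0
    f0: float = 100.0
    # video rendering; paint_gain converts fluorescence units to camera
    # counts — one event (amplitude 1.0) spans 50 counts so 16-bit
    # quantisation costs only 2% of the event amplitude
    frame_shape: tuple[int, int] = (64, 64)
    disk_sigma_px: float = 2.0
    paint_gain: float = 50.0
    video_offset: float = 200.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.shared_fraction <= 1.0):
            raise InvalidParameterError("shared_fraction must lie in [0, 1]")
        if self.post_shared_fraction is not None and not (
            0.0 <= self.post_shared_fraction <= 1.0
        ):
            raise InvalidParameterError("post_shared_fraction must lie in [0, 1]")
        if self.fs <= 0 or self.duration <= 0:
            raise InvalidParameterError("fs and duration must be positive")
        if self.base_rate < 0:
            raise InvalidParameterError("base_rate must be non-negative")
        if self.post_rate_gain < 1.0:
            raise InvalidParameterError("post_rate_gain must be >= 1")
        if not (self.kernel_decay > self.kernel_rise > 0):
            raise InvalidParameterError("require kernel_decay > kernel_rise > 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be non-negative")
        if self.stimulus_time is not None and not (
            0.0 <= self.stimulus_time <= self.duration
        ):
            raise InvalidParameterError("stimulus_time must lie within the recording")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fs))


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the pipeline."""

    spike_times: list[np.ndarray]
    pair_synchrony: np.ndarray  # (n, n) symmetric, shared_fraction used pre-stimulus
    roi_centers: np.ndarray | None = None  # (n, 2) [row, col]
    background_center: tuple[int, int] | None = None
    f0_true: np.ndarray | None = None
    dff_true: np.ndarray | None = None  # (n, frames) noise-free ΔF/F0
    config: SynthConfig | None = None


def _rng(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream: one root seed, keyed per cell/segment."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def poisson_train(
    rate: float, duration: float, seed: int | np.random.Generator
) -> EventTrain:
    """Homogeneous Poisson event train on [0, duration).

    Inter-arrival times are exponential with mean ``1/rate``; ``rate=0``
    yields an empty train.
    """
    if rate < 0:
        raise InvalidParameterError("rate must be non-negative")
    if duration <= 0:
        raise InvalidParameterError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    if rate == 0:
        return EventTrain(cell_id="poisson", times=np.empty(0))
    # draw arrivals in blocks until past the horizon
    times: list[np.ndarray] = []
    t = 0.0
    block = max(16, int(rate * duration * 1.5))
    while t < duration:
        gaps = rng.exponential(1.0 / rate, size=block)
        arr = t + np.cumsum(gaps)
        times.append(arr)
        t = arr[-1]
    all_t = np.concatenate(times)
    return EventTrain(cell_id="poisson", times=all_t[all_t < duration])


def _segment_trains(
    cfg: SynthConfig,
    rate: float,
    shared: float,
    t0: float,
    t1: float,
    seg_key: int,
) -> list[np.ndarray]:
    """Per-cell spike times in [t0, t1) with the mother-train construction."""
    dur = t1 - t0
    if dur <= 0 or rate == 0:
        return [np.empty(0) for _ in range(cfg.n_cells)]
    mother = poisson_train(rate * shared, dur, _rng(cfg.seed, seg_key, 0)).times
    out = []
    for c in range(cfg.n_cells):
        private = poisson_train(
            rate * (1.0 - shared), dur, _rng(cfg.seed, seg_key, c + 1)
        ).times
        out.append(np.sort(np.concatenate([mother, private])) + t0)
    return out


def correlated_trains(cfg: SynthConfig) -> tuple[list[EventTrain], GroundTruth]:
    """Spike trains for all cells with the configured pairwise synchrony.

    Marginal rate per cell is ``base_rate`` before ``stimulus_time`` and
    ``base_rate * post_rate_gain`` after it; the shared fraction switches to
    ``post_shared_fraction`` at the same instant.
    """
    if cfg.stimulus_time is None:
        per_cell = _segment_trains(
            cfg, cfg.base_rate, cfg.shared_fraction, 0.0, cfg.duration, 1
        )
    else:
        post_sf = (
            cfg.shared_fraction
            if cfg.post_shared_fraction is None
            else cfg.post_shared_fraction
        )
        pre = _segment_trains(
            cfg, cfg.base_rate, cfg.shared_fraction, 0.0, cfg.stimulus_time, 1
        )
        post = _segment_trains(
            cfg,
            cfg.base_rate * cfg.post_rate_gain,
            post_sf,
            cfg.stimulus_time,
            cfg.duration,
            2,
        )
        per_cell = [np.concatenate([a, b]) for a, b in zip(pre, post)]
    trains = [
        EventTrain(cell_id=f"cell{c:02d}", times=t) for c, t in enumerate(per_cell)
    ]
    sync = np.full((cfg.n_cells, cfg.n_cells), cfg.shared_fraction)
    np.fill_diagonal(sync, 1.0)
    gt = GroundTruth(
        spike_times=[t.times for t in trains],
        pair_synchrony=sync,
        f0_true=np.full(cfg.n_cells, cfg.f0),
        config=cfg,
    )
    return trains, gt


def kernel_peak_time(cfg: SynthConfig) -> float:
    """Delay from spike to fluorescence peak:
    ``rise*decay/(decay-rise) * ln(decay/rise)``."""
    r, d = cfg.kernel_rise, cfg.kernel_decay
    return r * d / (d - r) * np.log(d / r)


def calcium_kernel(cfg: SynthConfig, n_samples: int | None = None) -> np.ndarray:
    """Unit-peak difference-of-exponentials kernel sampled at ``cfg.fs``.

    Peak occurs at ``t* = rise*decay/(decay-rise) * ln(decay/rise)``; the
    kernel is truncated at 8 decay constants.
    """
    r, d = cfg.kernel_rise, cfg.kernel_decay
    if n_samples is None:
        n_samples = int(np.ceil(8.0 * d * cfg.fs)) + 1
    t = np.arange(n_samples) / cfg.fs
    k = np.exp(-t / d) - np.exp(-t / r)
    t_peak = r * d / (d - r) * np.log(d / r)
    peak = np.exp(-t_peak / d) - np.exp(-t_peak / r)
    return k / peak


def render_trace(
    train: EventTrain,
    cfg: SynthConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy fluorescence trace: baseline + kernel-convolved spikes + noise.

    Returns the raw fluorescence values (length ``cfg.n_frames``); pair with
    :class:`dynconn.trace_io.RawTrace` for downstream use.
    """
    n = cfg.n_frames
    impulses = np.zeros(n)
    idx = np.round(train.times * cfg.fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    np.add.at(impulses, idx, 1.0)
    clean = cfg.f0 + cfg.amplitude * np.convolve(
        impulses, calcium_kernel(cfg), mode="full"
    )[:n]
    if cfg.noise_sd > 0:
        if rng is None:
            rng = _rng(cfg.seed, 7, 0)
        clean = clean + rng.normal(0.0, cfg.noise_sd, size=n)
    return clean


def render_traces(
    cfg: SynthConfig,
) -> tuple[np.ndarray, GroundTruth]:
    """All-cell trace matrix (n_cells, n_frames) plus ground truth."""
    trains, gt = correlated_trains(cfg)
    traces = np.empty((cfg.n_cells, cfg.n_frames))
    for c, train in enumerate(trains):
        traces[c] = render_trace(train, cfg, rng=_rng(cfg.seed, 7, c))
    gt.dff_true = np.empty_like(traces)
    quiet = replace(cfg, noise_sd=0.0)
    for c, train in enumerate(trains):
        gt.dff_true[c] = (render_trace(train, quiet) - cfg.f0) / cfg.f0
    return traces, gt


def _roi_grid(cfg: SynthConfig) -> tuple[np.ndarray, tuple[int, int]]:
    """Non-overlapping ROI centers on a grid; last grid slot is background."""
    h, w = cfg.frame_shape
    spacing = int(np.ceil(6 * cfg.disk_sigma_px))
    margin = spacing // 2 + 1
    rows = np.arange(margin, h - margin + 1, spacing)
    cols = np.arange(margin, w - margin + 1, spacing)
    slots = [(int(r), int(c)) for r in rows for c in cols]
    if len(slots) < cfg.n_cells + 1:
        raise LayoutError(
            f"frame {cfg.frame_shape} holds {len(slots)} ROI slots; "
            f"need {cfg.n_cells + 1} (cells + background)"
        )
    centers = np.array(slots[: cfg.n_cells], dtype=int).reshape(cfg.n_cells, 2)
    background = slots[-1]
    return centers, background


def render_video(cfg: SynthConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render a 16-bit grayscale stack (frames, height, width) with ground truth.

    Each cell is a Gaussian-profile disk whose brightness follows
    ``paint_gain * trace``; the background carries only the offset and noise.
    The recorded background seed is guaranteed fluorescence-free.
    """
    # paint noise-free traces; all noise enters at the pixel level
    traces, gt = render_traces(replace(cfg, noise_sd=0.0))
    gt.config = cfg
    centers, background = _roi_grid(cfg)
    h, w = cfg.frame_shape
    n = cfg.n_frames
    rr, cc = np.mgrid[0:h, 0:w]
    canvas = np.zeros((cfg.n_cells, h, w))
    for c, (r0, c0) in enumerate(centers):
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        prof = np.exp(-d2 / (2 * cfg.disk_sigma_px**2))
        prof[d2 > (3 * cfg.disk_sigma_px) ** 2] = 0.0
        canvas[c] = prof
    # frames = offset + sum_c profile_c * gain * trace_c(t) + pixel noise
    stack = np.tensordot(traces.T, canvas, axes=(1, 0)) * cfg.paint_gain
    stack += cfg.video_offset
    if cfg.noise_sd > 0:
        # pixel noise on the same relative scale as trace noise
        rng = _rng(cfg.seed, 9)
        stack += rng.normal(0.0, cfg.noise_sd * cfg.paint_gain, size=stack.shape)
    stack = np.clip(np.round(stack), 0, 2**16 - 1).astype(np.uint16)
    gt.roi_centers = centers
    gt.background_center = background
    return stack, gt


def control_condition(seed: int = 0, **overrides) -> SynthConfig:
    """Media-perfusion control: mild rate shock, unchanged synchrony."""
    base = dict(
        n_cells=7,
        duration=600.0,
        base_rate=0.2,
        shared_fraction=0.3,
        stimulus_time=300.0,
        post_rate_gain=1.3,
        post_shared_fraction=0.3,
        noise_sd=0.02,
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


def glutamate_condition(seed: int = 0, **overrides) -> SynthConfig:
    """Glutamate-like excitation: 3x rate gain and near-saturating synchrony."""
    base = dict(
        n_cells=7,
        duration=600.0,
        base_rate=0.2,
        shared_fraction=0.3,
        stimulus_time=300.0,
        post_rate_gain=3.0,
        post_shared_fraction=0.9,
        noise_sd=0.02,
        seed=seed,
    )
    base.update(overrides)
    return SynthConfig(**base)


def write_dataset(cfg: SynthConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write TIFF stack + ROI seed CSV + ground-truth JSON for a config.

    The ROI CSV has columns ``cell_id,row,col`` with a final ``background``
    row; the JSON records spike times and an echo of the config.
    """
    import pandas as pd
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack, gt = render_video(cfg)
    tiff_path = out / "stack.tif"
    tifffile.imwrite(tiff_path, stack)
    rows = [
        {"cell_id": f"cell{c:02d}", "row": int(r), "col": int(cl)}
        for c, (r, cl) in enumerate(gt.roi_centers)
    ]
    rows.append(
        {
            "cell_id": "background",
            "row": gt.background_center[0],
            "col": gt.background_center[1],
        }
    )
    roi_path = out / "rois.csv"
    pd.DataFrame(rows).to_csv(roi_path, index=False)
    truth_path = out / "ground_truth.json"
    cfg_dict = asdict(cfg)
    cfg_dict["frame_shape"] = list(cfg.frame_shape)
    truth_path.write_text(
        json.dumps(
            {
                "spike_times": [t.tolist() for t in gt.spike_times],
                "roi_centers": gt.roi_centers.tolist(),
                "background_center": list(gt.background_center),
                "stimulus_time": cfg.stimulus_time,
                "config": cfg_dict,
            },
            indent=1,
        )
    )
    return {"stack": tiff_path, "rois": roi_path, "ground_truth": truth_path}
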