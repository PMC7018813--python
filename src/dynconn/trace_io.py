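"""Video loading, 5-pixel ROI trace extraction and ΔF/F₀ normalisation.

The raw input is a grayscale video stack (multi-frame TIFF, optionally AVI)
and a table of manually placed ROI seed pixels — one per soma, plus one seed
in a fluorescence-free region that stands in for the shared background. Each
seed's signal is the per-frame mean over the plus-shaped 5-pixel
neighbourhood {centre, up, down, left, right}; the background trace is
subtracted sample-by-sample, the baseline F₀ is the mean of the lowest
fraction of samples, and ΔF/F₀ = (F − F₀)/F₀.

Stacks are read in temporal segments so arbitrarily long recordings never
need to fit in memory at once; segmented and whole-file reads are
frame-exact identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    DegenerateBaselineError,
    InvalidParameterError,
    ShapeMismatchError,
    StackIOError,
)

__all__ = [
    "FrameStack",
    "RoiSeed",
    "RawTrace",
    "DffTrace",
    "load_stack",
    "iter_segments",
    "mean_projection",
    "extract_trace",
    "subtract_background",
    "compute_f0",
    "compute_dff",
    "read_roi_csv",
    "write_traces_csv",
    "read_traces_csv",
]


@dataclass
class FrameStack:
    """A video as (frames, height, width) intensities with a frame rate."""

    pixels: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[0] < 1:
            raise InvalidParameterError("stack must be (frames, height, width)")
        if self.fs <= 0:
            raise InvalidParameterError("frame rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.pixels.shape[1], self.pixels.shape[2]


@dataclass(frozen=True)
class RoiSeed:
    """A manually chosen seed pixel: (row, col), 0-based."""

    cell_id: str
    center: tuple[int, int]
    is_background: bool = False


@dataclass
class RawTrace:
    """Per-frame fluorescence for one seed."""

    values: np.ndarray
    fs: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise InvalidParameterError("trace values must be 1-D")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs


@dataclass
class DffTrace:
    """Dimensionless ΔF/F₀ trace with its baseline."""

    values: np.ndarray
    fs: float
    f0: float
    cell_id: str = "cell"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.f0 <= 0:
            raise DegenerateBaselineError(f"F0 must be positive, got {self.f0}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("ΔF/F values must be finite")

    def __len__(self) -> int:
        return self.values.size


def _read_tiff_segment(path: Path, start: int, stop: int) -> np.ndarray:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        return tf.asarray(key=range(start, stop))


def _tiff_n_frames(path: Path) -> int:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        shape = series.shape
        return 1 if len(shape) == 2 else int(shape[0])


def _read_avi(path: Path) -> np.ndarray:
    import imageio.v3 as iio

    frames = iio.imread(path)
    if frames.ndim == 4:  # colour: first channel
        frames = frames[..., 0]
    return frames


def iter_segments(
    path: str | Path, n_segments: int = 10
) -> Iterator[np.ndarray]:
    """Yield the stack in ``n_segments`` contiguous temporal chunks.

    Chunk length is ``n_frames // n_segments``; the last chunk absorbs the
    remainder. Only TIFF is read lazily; AVI is decoded whole then sliced
    (codecs rarely support exact frame seeking).
    """
    path = Path(path)
    if n_segments < 1:
        raise InvalidParameterError("n_segments must be >= 1")
    if not path.exists():
        raise StackIOError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        try:
            n = _tiff_n_frames(path)
        except Exception as exc:  # truncated / not a TIFF
            raise StackIOError(f"cannot read TIFF {path}: {exc}") from exc
        if n == 0:
            raise StackIOError(f"stack {path} has zero frames")
        n_segments = min(n_segments, n)
        seg = n // n_segments
        for i in range(n_segments):
            start = i * seg
            stop = n if i == n_segments - 1 else (i + 1) * seg
            chunk = _read_tiff_segment(path, start, stop)
            if chunk.ndim == 2:
                chunk = chunk[None]
            yield chunk
    elif suffix == ".avi":
        frames = _read_avi(path)
        n = frames.shape[0]
        if n == 0:
            raise StackIOError(f"stack {path} has zero frames")
        n_segments = min(n_segments, n)
        seg = n // n_segments
        for i in range(n_segments):
            stop = n if i == n_segments - 1 else (i + 1) * seg
            yield frames[i * seg : stop]
    else:
        raise StackIOError(f"unsupported stack format: {path.suffix}")


def load_stack(path: str | Path, fs: float, n_segments: int = 10) -> FrameStack:
    """Load a TIFF/AVI stack via segmented reads and return the full array.

    ``fs`` must be supplied by the caller (TIFF carries no frame rate; the
    acquisition rate comes from the experiment's config).
    """
    chunks = list(iter_segments(path, n_segments=n_segments))
    return FrameStack(pixels=np.concatenate(chunks, axis=0), fs=fs)


def mean_projection(stack: FrameStack) -> np.ndarray:
    """Pixel-wise temporal mean — the image used for manual seed placement."""
    return stack.pixels.mean(axis=0)


_PLUS = np.array([[0, 0], [-1, 0], [1, 0], [0, -1], [0, 1]])


def extract_trace(stack: FrameStack, seed: RoiSeed) -> RawTrace:
    """Per-frame mean over the plus-shaped 5-pixel neighbourhood of a seed."""
    h, w = stack.frame_shape
    r, c = seed.center
    if not (1 <= r <= h - 2 and 1 <= c <= w - 2):
        raise BoundsError(
            f"seed {seed.cell_id} at {seed.center} needs a 1-pixel margin in "
            f"a {h}x{w} frame"
        )
    rows = _PLUS[:, 0] + r
    cols = _PLUS[:, 1] + c
    values = stack.pixels[:, rows, cols].mean(axis=1, dtype=float)
    return RawTrace(values=values, fs=stack.fs, cell_id=seed.cell_id)


def subtract_background(cell: RawTrace, background: RawTrace) -> RawTrace:
    """Frame-aligned subtraction of the shared background trace.

    Negative samples are kept: clipping would bias F₀ upward.
    """
    if len(cell) != len(background) or cell.fs != background.fs:
        raise ShapeMismatchError("cell and background traces must be aligned")
    return RawTrace(
        values=cell.values - background.values, fs=cell.fs, cell_id=cell.cell_id
    )


def compute_f0(trace: RawTrace, low_fraction: float = 0.10) -> float:
    """Baseline fluorescence: mean of the lowest ``low_fraction`` of samples.

    At least one sample is always used. A non-positive result signals an
    over-subtracted background and raises
    :class:`~dynconn.errors.DegenerateBaselineError`.
    """
    if len(trace) == 0:
        raise InvalidParameterError("empty trace")
    if not (0 < low_fraction <= 1):
        raise InvalidParameterError("low_fraction must lie in (0, 1]")
    k = max(1, int(round(low_fraction * len(trace))))
    lowest = np.partition(trace.values, k - 1)[:k]
    f0 = float(np.mean(lowest))
    if f0 <= 0:
        raise DegenerateBaselineError(
            f"baseline F0={f0:.4g} for {trace.cell_id}; background likely "
            "over-subtracted"
        )
    return f0


def compute_dff(trace: RawTrace, f0: float) -> DffTrace:
    """ΔF/F₀ = (F − F₀)/F₀."""
    if f0 <= 0:
        raise DegenerateBaselineError(f"F0 must be positive, got {f0}")
    return DffTrace(
        values=(trace.values - f0) / f0,
        fs=trace.fs,
        f0=f0,
        cell_id=trace.cell_id,
    )


def video_to_dff(
    stack: FrameStack,
    seeds: list[RoiSeed],
    low_fraction: float = 0.10,
) -> list[DffTrace]:
    """Full extraction pipeline: 5-pixel traces → background subtraction → ΔF/F₀.

    ``seeds`` must contain exactly one background seed; the same background
    trace is reused for every cell.
    """
    bg_seeds = [s for s in seeds if s.is_background]
    if len(bg_seeds) != 1:
        raise InvalidParameterError(
            f"need exactly one background seed, got {len(bg_seeds)}"
        )
    background = extract_trace(stack, bg_seeds[0])
    out = []
    for seed in seeds:
        if seed.is_background:
            continue
        raw = subtract_background(extract_trace(stack, seed), background)
        f0 = compute_f0(raw, low_fraction=low_fraction)
        out.append(compute_dff(raw, f0))
    return out


def read_roi_csv(path: str | Path) -> list[RoiSeed]:
    """ROI seed table: columns cell_id,row,col; cell_id 'background' flags the
    background seed."""
    df = pd.read_csv(path)
    missing = {"cell_id", "row", "col"} - set(df.columns)
    if missing:
        raise InvalidParameterError(f"ROI CSV missing columns: {sorted(missing)}")
    return [
        RoiSeed(
            cell_id=str(row.cell_id),
            center=(int(row.row), int(row.col)),
            is_background=str(row.cell_id).strip().lower() == "background",
        )
        for row in df.itertuples()
    ]


def write_traces_csv(
    traces: list[DffTrace] | list[RawTrace], path: str | Path
) -> None:
    """Wide CSV: time_s plus one column per cell."""
    if not traces:
        raise InvalidParameterError("no traces to write")
    fs = traces[0].fs
    n = len(traces[0])
    data = {"time_s": np.arange(n) / fs}
    for tr in traces:
        if len(tr) != n:
            raise ShapeMismatchError("traces differ in length")
        data[tr.cell_id] = tr.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_traces_csv(path: str | Path, fs: float | None = None) -> list[RawTrace]:
    """Read a wide traces CSV (time_s + per-cell columns).

    ``fs`` overrides the rate inferred from the time_s column.
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise InvalidParameterError("traces CSV needs a time_s column")
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])
        if dt.size == 0 or dt[0] <= 0:
            raise InvalidParameterError("cannot infer fs from time_s")
        fs = 1.0 / float(dt[0])
    return [
        RawTrace(values=df[c].to_numpy(dtype=float), fs=fs, cell_id=str(c))
        for c in df.columns
        if c != "time_s"
    ]


def write_f0_json(f0s: dict[str, float], path: str | Path) -> None:
    Path(path).write_text(json.dumps(f0s, indent=1))
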