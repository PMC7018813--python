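"""Distance–connectivity relationships and the study's statistical tests.

Intercellular distance is the Euclidean separation of ROI seed centres
converted to micrometres; the distance–connectivity relation is summarised
by a plain Pearson regression coefficient across pairs. Condition contrasts
use the two-tailed Welch's t-test (unequal variances, Satterthwaite degrees
of freedom); coefficients can be Z-scored per condition before pooling
across cultures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InvalidParameterError
from .trace_io import RoiSeed

__all__ = [
    "PairDistance",
    "centroid_distance",
    "pairwise_distances",
    "distance_connectivity_regression",
    "welch_ttest",
    "zscore",
]


@dataclass(frozen=True)
class PairDistance:
    cell_a: str
    cell_b: str
    distance_um: float


def centroid_distance(a: RoiSeed, b: RoiSeed, pixel_size: float = 1.0) -> float:
    """Euclidean distance between two seed centres, in micrometres."""
    if pixel_size <= 0:
        raise InvalidParameterError("pixel_size must be positive")
    (r1, c1), (r2, c2) = a.center, b.center
    return float(np.hypot(r1 - r2, c1 - c2) * pixel_size)


def pairwise_distances(
    seeds: list[RoiSeed], pixel_size: float = 1.0
) -> list[PairDistance]:
    """Distances for all unordered cell pairs (background seeds excluded)."""
    cells = [s for s in seeds if not s.is_background]
    return [
        PairDistance(
            cells[i].cell_id,
            cells[j].cell_id,
            centroid_distance(cells[i], cells[j], pixel_size),
        )
        for i in range(len(cells))
        for j in range(i + 1, len(cells))
    ]


def distance_connectivity_regression(
    distances: np.ndarray, weights: np.ndarray
) -> float:
    """Pearson r between per-pair distance and composite connectivity weight."""
    d = np.asarray(distances, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise InvalidParameterError("distances and weights must align")
    if d.size < 3:
        raise InsufficientDataError("need at least 3 pairs")
    from .connectivity import pearson

    return pearson(d, w)


@dataclass(frozen=True)
class WelchResult:
    t: float
    dof: float
    p: float


def welch_ttest(a: np.ndarray, b: np.ndarray) -> WelchResult:
    """Two-tailed Welch's t-test (unequal variances)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each sample needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), dof=float(res.df), p=float(res.pvalue))


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, sd 1 (n-1 denominator); affine-invariant."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("need n >= 2 to Z-score")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise InvalidParameterError("zero-variance sample cannot be Z-scored")
    return (x - np.mean(x)) / sd
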