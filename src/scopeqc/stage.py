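"""Motorised-stage repeatability and accuracy from repeated bead imaging,
plus the grid-image pass-through for the XY-galvo check.

Per frame the bead image is median filtered (disk radius 7), thresholded at
half the filtered maximum, and the original frame masked (below-threshold
pixels set to 0); the reported centroid is the intensity-weighted centroid
of the remaining pixels — intentionally different from the binary-mask
centroid used for co-registration, because here the masked original
intensities are kept.

Axis convention: commanded +X stage motion moves the bead -X in image
coordinates by default (the specimen moves opposite to the field); the
sidecar ``axes_sign`` field overrides this.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .beads import MIN_COMPONENT_VOXELS, MultipleBeadsError
from .core import ImageStack

__all__ = [
    "StageTrace",
    "RepeatabilityStats",
    "AccuracyStats",
    "track_bead",
    "repeatability_stats",
    "accuracy_stats",
    "grid_passthrough",
]

MEDIAN_FILTER_RADIUS = 7


@dataclass
class StageTrace:
    times: np.ndarray
    centroids: np.ndarray       # (T, 2) µm (x, y); nan rows for missing frames
    mean_intensity: np.ndarray  # mean of above-threshold pixels (Z-drift proxy)
    position_label: str
    missing: List[int] = field(default_factory=list)


@dataclass
class RepeatabilityStats:
    mean_position: Tuple[float, float]  # µm
    sd: Tuple[float, float]             # µm, population SD per axis
    max_excursion: float                # µm, max distance from the mean


@dataclass
class AccuracyStats:
    commanded_moves: np.ndarray   # (M, 2) µm from metadata
    measured_moves: np.ndarray    # (M, 2) µm from centroids, stage frame
    residuals: np.ndarray         # commanded - measured, per move and axis
    scalar_residuals: np.ndarray  # |commanded| - |measured| per move


def _frame_centroid(frame: np.ndarray, pixel_size: float):
    """Masked intensity-weighted centroid of one frame, or None if empty."""
    filt = ndimage.median_filter(frame.astype(float),
                                 footprint=disk(MEDIAN_FILTER_RADIUS),
                                 mode="reflect")
    peak = float(filt.max())
    if peak <= 0:
        return None
    mask = filt >= peak / 2.0
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    big = np.flatnonzero(sizes >= MIN_COMPONENT_VOXELS) + 1
    if len(big) > 1:
        raise MultipleBeadsError(
            f"{len(big)} bead-sized objects in one frame; "
            "only one bead per frame is permitted"
        )
    if len(big) == 0:
        return None
    keep = labels == big[0]
    masked = np.where(keep, frame.astype(float), 0.0)
    ys, xs = np.nonzero(masked > 0)
    w = masked[ys, xs]
    total = w.sum()
    cx = float((w * xs).sum() / total * pixel_size)
    cy = float((w * ys).sum() / total * pixel_size)
    return cx, cy, float(w.mean())


def track_bead(series: ImageStack, position_label: str = "stage") -> StageTrace:
    """Per-frame bead centroid (µm) and mean above-threshold intensity."""
    if series.size_c != 1:
        raise ValueError("bead tracking expects a single channel")
    if series.pixel_size_xy <= 0:
        raise ValueError("pixel size required for stage measurements")
    t = series.size_t
    centroids = np.full((t, 2), math.nan)
    intensity = np.full(t, math.nan)
    missing = []
    for k in range(t):
        result = _frame_centroid(series.frame(k, 0, 0), series.pixel_size_xy)
        if result is None:
            missing.append(k)
            continue
        centroids[k, 0], centroids[k, 1], intensity[k] = result
    times = np.arange(t, dtype=float) * series.frame_interval
    return StageTrace(times=times, centroids=centroids,
                      mean_intensity=intensity,
                      position_label=position_label, missing=missing)


def repeatability_stats(trace: StageTrace) -> RepeatabilityStats:
    """Scatter of revisited positions: per-axis mean/SD and max excursion."""
    valid = np.isfinite(trace.centroids).all(axis=1)
    pts = trace.centroids[valid]
    if len(pts) < 10:
        raise ValueError(f"need >= 10 valid frames, got {len(pts)}")
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0)  # population SD
    excursion = float(np.linalg.norm(pts - mean, axis=1).max())
    return RepeatabilityStats(mean_position=(float(mean[0]), float(mean[1])),
                              sd=(float(sd[0]), float(sd[1])),
                              max_excursion=excursion)


def accuracy_stats(trace: StageTrace, series: ImageStack,
                   axes_sign: Optional[Tuple[int, int]] = None) -> AccuracyStats:
    """Commanded vs executed moves: residual = commanded - measured.

    Commanded move k is ``stage_positions[k+1] - stage_positions[k]``; the
    measured move is the centroid displacement mapped back into the stage
    frame via ``axes_sign`` (default: the series' own convention).
    """
    if series.stage_positions is None:
        raise ValueError(
            "stage_positions missing: add 'stage_positions_um' to the sidecar"
        )
    if axes_sign is None:
        axes_sign = series.axes_sign
    sign = np.asarray(axes_sign, dtype=float)
    positions = np.asarray(series.stage_positions, dtype=float)
    if len(positions) != len(trace.centroids):
        raise ValueError("stage_positions length does not match frame count")
    commanded = np.diff(positions, axis=0)
    displacement = np.diff(trace.centroids, axis=0)
    measured = displacement * sign  # image frame -> stage frame (sign is ±1)
    residuals = commanded - measured
    scalar = (np.linalg.norm(commanded, axis=1)
              - np.linalg.norm(measured, axis=1))
    return AccuracyStats(commanded_moves=commanded, measured_moves=measured,
                         residuals=residuals, scalar_residuals=scalar)


def grid_passthrough(image: ImageStack, low_pct: float = 0.5,
                     high_pct: float = 99.5) -> np.ndarray:
    """Percentile contrast stretch of a grid frame (no metrics yet).

    A degenerate (constant) frame is returned unchanged.
    """
    frame = image.frame(0, 0, 0).astype(float)
    lo, hi = np.percentile(frame, [low_pct, high_pct])
    if hi <= lo:
        return frame
    return np.clip((frame - lo) / (hi - lo), 0.0, 1.0)
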