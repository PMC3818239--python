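"""Laser intensity drift and noise from transmitted-light time-lapse stacks.

Statistics conventions (stated once, applied throughout the package):

* standard deviations are population SDs (divide by N);
* percentage changes are normalised by the whole-series mean intensity,
  which is robust to near-zero individual frames;
* histogram grid: 0.5 % wide bins spanning ±10 % with open-ended overflow
  bins, so histograms are comparable across sessions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .core import ImageStack
from .profiles import IntensityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "StabilityTrace",
    "LineScanNoise",
    "NoiseHistogramSet",
    "frame_statistics",
    "linescan_noise",
    "multiscale_histograms",
    "HISTOGRAM_EDGES",
    "FRAME_TIMESCALES_S",
]

#: Inner bin edges in percent: 0.5 % wide, ±10 %, plus ±inf overflow.
HISTOGRAM_EDGES = np.concatenate(
    ([-np.inf], np.round(np.arange(-10.0, 10.0 + 0.25, 0.5), 6), [np.inf])
)

#: Frame-separation timescales (label -> nominal separation in seconds).
FRAME_TIMESCALES_S = (("20s", 20.0), ("1min", 60.0),
                      ("10min", 600.0), ("1h", 3600.0))


@dataclass
class StabilityTrace:
    times: np.ndarray            # s
    mean_intensity: np.ndarray   # counts per frame
    sd_intensity: np.ndarray     # counts per frame
    min_mean: float
    max_mean: float
    max_percent_change: float    # %


@dataclass
class LineScanNoise:
    mean: float
    sd: float
    cv: float                    # nan when the line mean is zero
    cv_defined: bool
    profile: IntensityProfile


@dataclass
class NoiseHistogramSet:
    """Per-timescale histograms of percentage intensity changes."""

    histograms: Dict[str, Tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    skipped: Dict[str, str] = field(default_factory=dict)


def frame_statistics(series: ImageStack) -> StabilityTrace:
    """Per-frame mean/SD over all pixels, plus min/max and max % change.

    ``max_percent_change = (max_mean - min_mean) / overall_mean * 100`` where
    ``overall_mean`` is the mean of the frame means.
    """
    if series.size_t < 2:
        raise ValueError("need at least 2 frames for frame statistics")
    if series.frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    frames = series.pixels[:, 0, 0].astype(float)  # (t, y, x)
    means = frames.mean(axis=(1, 2))
    sds = frames.std(axis=(1, 2))  # population SD
    overall = float(means.mean())
    min_mean = float(means.min())
    max_mean = float(means.max())
    pct = (max_mean - min_mean) / overall * 100.0 if overall != 0 else math.nan
    times = np.arange(series.size_t, dtype=float) * series.frame_interval
    return StabilityTrace(times, means, sds, min_mean, max_mean, pct)


def linescan_noise(first_frame, row_index: int,
                   pixel_size: float = 1.0) -> LineScanNoise:
    """Mean, population SD and CV of one horizontal line of the first frame."""
    frame = np.asarray(first_frame)
    if frame.ndim != 2:
        raise ValueError("first_frame must be a 2-D raster")
    if not (0 <= row_index < frame.shape[0]):
        raise ValueError(f"row {row_index} outside image of {frame.shape[0]} rows")
    line = frame[row_index, :].astype(float)
    mean = float(line.mean())
    sd = float(line.std())
    defined = mean != 0.0
    cv = sd / mean if defined else math.nan
    profile = IntensityProfile(np.arange(len(line), dtype=float) * pixel_size,
                               line, unit="px" if pixel_size == 1.0 else "um")
    return LineScanNoise(mean, sd, cv, defined, profile)


def _percent_histogram(diffs: np.ndarray, series_mean: float):
    pct = diffs / series_mean * 100.0
    counts, _ = np.histogram(pct, bins=HISTOGRAM_EDGES)
    freqs = counts / counts.sum()
    return HISTOGRAM_EDGES.copy(), freqs


def multiscale_histograms(series: ImageStack,
                          n_fast_frames: int = 100) -> NoiseHistogramSet:
    """Histograms of percentage changes between adjacent data points per scale.

    * ``us``  — adjacent-pixel differences along the centre row of the first
      ``n_fast_frames`` frames (pixel dwell time);
    * ``ms``  — adjacent-row mean differences within each of those frames
      (line time);
    * ``20s``/``1min``/``10min``/``1h`` — differences of frame means sampled
      at the nearest integer frame lag to the nominal separation.

    Scales that the series is too short for are skipped with a log entry.
    """
    frames = series.pixels[:, 0, 0].astype(float)
    t = frames.shape[0]
    frame_means = frames.mean(axis=(1, 2))
    series_mean = float(frame_means.mean())
    if series_mean == 0:
        raise ValueError("series mean intensity is zero")
    result = NoiseHistogramSet()

    if t >= n_fast_frames:
        fast = frames[:n_fast_frames]
        centre_rows = fast[:, fast.shape[1] // 2, :]          # (n, x)
        us_diffs = np.diff(centre_rows, axis=1).ravel()
        result.histograms["us"] = _percent_histogram(us_diffs, series_mean)
        row_means = fast.mean(axis=2)                         # (n, y)
        ms_diffs = np.diff(row_means, axis=1).ravel()
        result.histograms["ms"] = _percent_histogram(ms_diffs, series_mean)
    else:
        msg = f"only {t} frames, need {n_fast_frames} for the us/ms scales"
        logger.warning("multiscale_histograms: %s", msg)
        result.skipped["us"] = msg
        result.skipped["ms"] = msg

    if series.frame_interval <= 0:
        msg = "frame_interval unknown; frame-separation scales skipped"
        logger.warning("multiscale_histograms: %s", msg)
        for label, _ in FRAME_TIMESCALES_S:
            result.skipped[label] = msg
        return result

    for label, seconds in FRAME_TIMESCALES_S:
        lag = max(1, int(round(seconds / series.frame_interval)))
        sub = frame_means[::lag]
        if lag > t - 1 or len(sub) < 2:
            msg = (f"lag {lag} frames ({seconds:g} s) exceeds series duration "
                   f"of {t} frames")
            logger.warning("multiscale_histograms: %s scale skipped: %s",
                           label, msg)
            result.skipped[label] = msg
            continue
        result.histograms[label] = _percent_histogram(np.diff(sub), series_mean)
    return result
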