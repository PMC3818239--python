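"""Field-illumination uniformity from single flat-field images.

The image is smoothed with a mean filter (disk radius 5, reflect padding to
avoid darkened borders), then the horizontal and vertical profiles through
the image centre are read out with 10-pixel orthogonal averaging.  Fall-off
is reported as (max - min)/max x 100 over the two profiles' samples, with
(max - min)/mean also emitted for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import ImageStack
from .profiles import IntensityProfile, extract_profile

__all__ = ["FieldUniformity", "field_uniformity", "mean_filter_disk"]

MEAN_FILTER_RADIUS = 5
PROFILE_AVERAGING_WIDTH = 10
SATURATION_FRACTION = 0.01
MIN_EXTENT = 64


@dataclass
class FieldUniformity:
    wavelength: float
    h_profile: IntensityProfile
    v_profile: IntensityProfile
    min_intensity: float
    max_intensity: float
    percent_difference: float          # (max-min)/max * 100
    percent_difference_of_mean: float  # (max-min)/mean * 100
    saturated: bool
    smoothed: np.ndarray


def mean_filter_disk(image: np.ndarray, radius: int = MEAN_FILTER_RADIUS
                     ) -> np.ndarray:
    """Circular mean filter with reflect padding."""
    footprint = disk(radius).astype(float)
    kernel = footprint / footprint.sum()
    return ndimage.correlate(np.asarray(image, dtype=float), kernel,
                             mode="reflect")


def field_uniformity(image: ImageStack, wavelength: float) -> FieldUniformity:
    """Quantify illumination fall-off of one flat-field frame.

    A frame with >= 1 % of pixels at the bit-depth maximum is flagged
    saturated (the numbers are still reported).
    """
    frame = image.frame(0, 0, 0).astype(float)
    if frame.shape[0] < MIN_EXTENT or frame.shape[1] < MIN_EXTENT:
        raise ValueError(
            f"field image must be at least {MIN_EXTENT} px per axis, "
            f"got {frame.shape}"
        )
    max_code = 2 ** image.bit_depth - 1
    saturated = float((frame >= max_code).mean()) >= SATURATION_FRACTION

    smoothed = mean_filter_disk(frame)
    h = extract_profile(smoothed, "horizontal", frame.shape[0] // 2,
                        PROFILE_AVERAGING_WIDTH,
                        spacing=image.pixel_size_xy, unit="um")
    v = extract_profile(smoothed, "vertical", frame.shape[1] // 2,
                        PROFILE_AVERAGING_WIDTH,
                        spacing=image.pixel_size_xy, unit="um")
    samples = np.concatenate([h.intensities, v.intensities])
    lo = float(samples.min())
    hi = float(samples.max())
    mean = float(samples.mean())
    pct = (hi - lo) / hi * 100.0 if hi > 0 else 0.0
    pct_mean = (hi - lo) / mean * 100.0 if mean > 0 else math.nan
    return FieldUniformity(
        wavelength=float(wavelength), h_profile=h, v_profile=v,
        min_intensity=lo, max_intensity=hi,
        percent_difference=pct, percent_difference_of_mean=pct_mean,
        saturated=saturated, smoothed=smoothed,
    )
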