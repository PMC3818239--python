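"""Multi-channel bead co-registration and PSF metrology from 3-D stacks.

Per channel, slices are median filtered (disk radius 7), the global filtered
maximum sets a half-maximum threshold, the whole stack is binarised at that
threshold, and the centroid of the above-threshold voxels is taken in
physical units.  Co-registration reports pairwise XY (Euclidean) and |Z|
centroid distances.  PSF metrology additionally reads X/Y/Z line profiles
through the centroid voxel of the original data and fits Gaussians for the
lateral and axial FWHM.

The "one bead per stack" acquisition rule is operationalised by rejecting
stacks whose thresholded volume contains more than one 26-connected
component of at least MIN_COMPONENT_VOXELS voxels; smaller specks are
treated as noise and excluded from the centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .core import ImageStack
from .profiles import GaussianFit, IntensityProfile, fit_gaussian, peak_and_fwhm

__all__ = [
    "CentroidRecord",
    "ColocResult",
    "PsfResult",
    "MultipleBeadsError",
    "bead_centroids",
    "psf_metrics",
    "MEDIAN_FILTER_RADIUS",
    "MIN_COMPONENT_VOXELS",
]

MEDIAN_FILTER_RADIUS = 7
MIN_COMPONENT_VOXELS = 5


class MultipleBeadsError(RuntimeError):
    """More than one bead-sized object above threshold."""


@dataclass
class CentroidRecord:
    channel_wavelength: float
    centroid: Tuple[float, float, float]           # (x, y, z) µm, binary mask
    centroid_weighted: Tuple[float, float, float]  # intensity-weighted, µm
    threshold_value: float
    voxel_count: int


@dataclass
class ColocResult:
    records: List[Optional[CentroidRecord]]  # None for absent channels
    xy_distance: np.ndarray                  # C×C µm, nan for absent
    z_distance: np.ndarray                   # C×C µm
    absent: List[int] = field(default_factory=list)


@dataclass
class PsfResult:
    centroid: Tuple[float, float, float]
    lateral_fwhm_x: float
    lateral_fwhm_y: float
    axial_fwhm: float
    lateral_fwhm_mean: float
    fits: dict                      # axis -> GaussianFit
    profiles: dict                  # axis -> IntensityProfile
    fallback_axes: List[str] = field(default_factory=list)


def _median_filter_stack(volume: np.ndarray,
                         radius: int = MEDIAN_FILTER_RADIUS) -> np.ndarray:
    """Slice-wise 2-D median filter with a circular footprint."""
    footprint = disk(radius)
    out = np.empty_like(volume, dtype=float)
    for z in range(volume.shape[0]):
        out[z] = ndimage.median_filter(volume[z].astype(float),
                                       footprint=footprint, mode="reflect")
    return out


def _single_bead_mask(filtered: np.ndarray):
    """Binarise at half the global filtered maximum; enforce one bead.

    Returns (mask, threshold) with only components of at least
    MIN_COMPONENT_VOXELS voxels retained, or (None, threshold) when nothing
    bead-sized remains.
    """
    peak = float(filtered.max())
    threshold = peak / 2.0
    if peak <= 0:
        return None, threshold
    mask = filtered >= threshold
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=int))
    if n == 0:
        return None, threshold
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    big = np.flatnonzero(sizes >= MIN_COMPONENT_VOXELS) + 1
    if len(big) > 1:
        raise MultipleBeadsError(
            f"{len(big)} bead-sized objects above threshold; "
            "only one bead per stack is permitted"
        )
    if len(big) == 0:
        return None, threshold
    return labels == big[0], threshold


def _centroids_um(mask: np.ndarray, original: np.ndarray, stack: ImageStack):
    zz, yy, xx = np.nonzero(mask)
    n = len(zz)
    px, pz = stack.pixel_size_xy, stack.z_step
    binary = (float(xx.mean() * px), float(yy.mean() * px), float(zz.mean() * pz))
    w = original[zz, yy, xx].astype(float)
    total = w.sum()
    if total > 0:
        weighted = (float((w * xx).sum() / total * px),
                    float((w * yy).sum() / total * px),
                    float((w * zz).sum() / total * pz))
    else:
        weighted = binary
    return binary, weighted, n


def _channel_centroid(stack: ImageStack, c: int) -> Optional[CentroidRecord]:
    volume = stack.pixels[0, c].astype(float)  # (z, y, x)
    filtered = _median_filter_stack(volume)
    mask, threshold = _single_bead_mask(filtered)
    if mask is None:
        return None
    binary, weighted, n = _centroids_um(mask, volume, stack)
    return CentroidRecord(
        channel_wavelength=float(stack.channel_wavelengths[c]),
        centroid=binary, centroid_weighted=weighted,
        threshold_value=threshold, voxel_count=n,
    )


def bead_centroids(stack: ImageStack) -> ColocResult:
    """Per-channel 3-D centroids and pairwise XY/Z centroid distances."""
    if stack.size_c < 2:
        raise ValueError("bead co-registration needs >= 2 channels")
    if stack.size_z < 5:
        raise ValueError("bead co-registration needs >= 5 Z planes")
    if stack.pixel_size_xy <= 0 or stack.z_step <= 0:
        raise ValueError("physical calibration (pixel size, z step) required")
    records = [_channel_centroid(stack, c) for c in range(stack.size_c)]
    absent = [i for i, r in enumerate(records) if r is None]
    n = stack.size_c
    xy = np.full((n, n), math.nan)
    dz = np.full((n, n), math.nan)
    for i in range(n):
        for j in range(n):
            ri, rj = records[i], records[j]
            if ri is None or rj is None:
                continue
            xi, yi, zi = ri.centroid
            xj, yj, zj = rj.centroid
            xy[i, j] = math.hypot(xi - xj, yi - yj)
            dz[i, j] = abs(zi - zj)
    return ColocResult(records=records, xy_distance=xy, z_distance=dz,
                       absent=absent)


def _axis_profiles(volume: np.ndarray, centroid_idx, stack: ImageStack):
    iz, iy, ix = centroid_idx
    px, pz = stack.pixel_size_xy, stack.z_step
    return {
        "x": IntensityProfile(np.arange(volume.shape[2], dtype=float) * px,
                              volume[iz, iy, :].astype(float), unit="um"),
        "y": IntensityProfile(np.arange(volume.shape[1], dtype=float) * px,
                              volume[iz, :, ix].astype(float), unit="um"),
        "z": IntensityProfile(np.arange(volume.shape[0], dtype=float) * pz,
                              volume[:, iy, ix].astype(float), unit="um"),
    }


def psf_metrics(stack: ImageStack) -> PsfResult:
    """Lateral/axial FWHM of a sub-resolution bead via Gaussian fits.

    Fit failures fall back to the direct profile FWHM for that axis and are
    flagged in ``fallback_axes``.
    """
    if stack.size_c != 1:
        raise ValueError("PSF metrology expects a single channel")
    if stack.size_z < 5:
        raise ValueError("PSF metrology needs >= 5 Z planes")
    record = _channel_centroid(stack, 0)
    if record is None:
        raise ValueError("no bead found above threshold")
    cx, cy, cz = record.centroid
    volume = stack.pixels[0, 0].astype(float)
    idx = (int(round(cz / stack.z_step)),
           int(round(cy / stack.pixel_size_xy)),
           int(round(cx / stack.pixel_size_xy)))
    idx = tuple(np.clip(idx, 0, np.array(volume.shape) - 1))
    profiles = _axis_profiles(volume, idx, stack)
    fits, fwhms, fallback = {}, {}, []
    for axis, profile in profiles.items():
        fit = fit_gaussian(profile)
        fits[axis] = fit
        if fit.converged:
            fwhms[axis] = fit.fwhm
        else:
            stats = peak_and_fwhm(profile)
            fwhms[axis] = stats.fwhm if stats.has_peak else math.nan
            fallback.append(axis)
    return PsfResult(
        centroid=record.centroid,
        lateral_fwhm_x=fwhms["x"], lateral_fwhm_y=fwhms["y"],
        axial_fwhm=fwhms["z"],
        lateral_fwhm_mean=float(np.nanmean([fwhms["x"], fwhms["y"]])),
        fits=fits, profiles=profiles, fallback_axes=fallback,
    )
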