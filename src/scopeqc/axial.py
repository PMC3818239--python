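"""Axial resolution and chromatic correction from XZ mirror-reflection scans,
and Z-focus drift/vibration from XZT reflection time series.

Each channel's reflection band is reduced to a vertical profile through a
chosen column (default: image centre), averaged over 10 pixels in X, from
which the peak Z position and FWHM are measured.  Chromatic shifts are the
signed differences of the per-channel peak positions, reported both as a
full pairwise matrix and relative to the shortest-wavelength channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .core import ImageStack
from .profiles import IntensityProfile, PeakStats, extract_profile, peak_and_fwhm

__all__ = [
    "AxialChannelResult",
    "AxialAnalysis",
    "ZDriftTrace",
    "axial_channels_analysis",
    "zgalvo_drift",
    "DEFAULT_AVERAGING_WIDTH",
]

DEFAULT_AVERAGING_WIDTH = 10


@dataclass
class AxialChannelResult:
    wavelength: float      # nm
    has_peak: bool
    peak_z: float          # µm (nan if no peak)
    fwhm: float            # µm (nan if no peak)
    profile: IntensityProfile
    stats: PeakStats


@dataclass
class AxialAnalysis:
    channels: List[AxialChannelResult]
    delta_z: np.ndarray            # C×C signed matrix, µm; nan rows for absent
    reference_index: int           # shortest-wavelength channel with a peak
    delta_vs_reference: np.ndarray  # µm per channel
    line_x: int


@dataclass
class ZDriftTrace:
    times: np.ndarray        # s
    peak_z: np.ndarray       # µm, nan where no peak was found
    fwhm: np.ndarray         # µm, nan where no peak was found
    total_drift: float       # max - min of valid peak positions, µm
    drift_rate: float        # least-squares slope, µm/min
    missing: list = field(default_factory=list)


def _column_profile(plane: np.ndarray, line_x: int, z_step: float,
                    averaging_width: int) -> IntensityProfile:
    return extract_profile(plane, "vertical", line_x, averaging_width,
                           spacing=z_step, unit="um")


def axial_channels_analysis(xz: ImageStack, line_x: Optional[int] = None,
                            averaging_width: int = DEFAULT_AVERAGING_WIDTH,
                            ) -> AxialAnalysis:
    """Per-channel reflection peak position/FWHM and the chromatic Δz matrix.

    ``line_x`` selects the analysed column (the automated equivalent of a
    manually drawn perpendicular line); by default the image centre is used.
    Channels without a detectable peak are reported absent; the Δz matrix is
    antisymmetric with NaN in rows/columns of absent channels.
    """
    if xz.size_z < 5:
        raise ValueError("axial analysis needs a Z axis (>= 5 planes)")
    if xz.z_step <= 0:
        raise ValueError("z_step must be positive for axial measurements")
    if line_x is None:
        line_x = xz.size_x // 2
    channels: List[AxialChannelResult] = []
    for c in range(xz.size_c):
        plane = xz.xz_plane(0, c).astype(float)
        profile = _column_profile(plane, line_x, xz.z_step, averaging_width)
        stats = peak_and_fwhm(profile)
        channels.append(AxialChannelResult(
            wavelength=float(xz.channel_wavelengths[c]),
            has_peak=stats.has_peak,
            peak_z=stats.peak_position if stats.has_peak else math.nan,
            fwhm=stats.fwhm if stats.has_peak else math.nan,
            profile=profile,
            stats=stats,
        ))
    n = len(channels)
    peaks = np.array([ch.peak_z for ch in channels])
    delta = peaks[:, None] - peaks[None, :]
    present = [i for i, ch in enumerate(channels) if ch.has_peak]
    if not present:
        raise ValueError("no channel produced a reflection peak")
    ref = min(present, key=lambda i: channels[i].wavelength)
    delta_ref = peaks - peaks[ref]
    return AxialAnalysis(channels=channels, delta_z=delta,
                         reference_index=ref, delta_vs_reference=delta_ref,
                         line_x=line_x)


def zgalvo_drift(xzt: ImageStack, line_x: Optional[int] = None,
                 averaging_width: int = DEFAULT_AVERAGING_WIDTH) -> ZDriftTrace:
    """Track the reflection peak Z position and FWHM over time.

    The drift rate is the least-squares slope of peak position versus time
    (µm/min); ``total_drift`` is the endpoint-style max-min range.  Frames
    without a detectable peak are recorded as missing and never interpolated.
    """
    if xzt.size_t < 2:
        raise ValueError("need at least 2 time points")
    if xzt.size_c != 1:
        raise ValueError("Z-drift analysis expects a single channel")
    if xzt.z_step <= 0:
        raise ValueError("z_step must be positive")
    if line_x is None:
        line_x = xzt.size_x // 2
    times = np.arange(xzt.size_t, dtype=float) * xzt.frame_interval
    peak_z = np.full(xzt.size_t, math.nan)
    fwhm = np.full(xzt.size_t, math.nan)
    missing = []
    for t in range(xzt.size_t):
        plane = xzt.xz_plane(t, 0).astype(float)
        stats = peak_and_fwhm(
            _column_profile(plane, line_x, xzt.z_step, averaging_width))
        if stats.has_peak:
            peak_z[t] = stats.peak_position
            fwhm[t] = stats.fwhm
        else:
            missing.append(t)
    valid = np.isfinite(peak_z)
    if valid.sum() < 2:
        raise ValueError("fewer than 2 frames with a detectable peak")
    total_drift = float(np.nanmax(peak_z) - np.nanmin(peak_z))
    slope_per_s = float(np.polyfit(times[valid], peak_z[valid], 1)[0])
    return ZDriftTrace(times=times, peak_z=peak_z, fwhm=fwhm,
                       total_drift=total_drift,
                       drift_rate=slope_per_s * 60.0, missing=missing)
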