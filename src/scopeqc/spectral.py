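"""Spectral-detector (lambda-scan) accuracy: reflection-peak wavelengths,
intensities and widths per detector, matched against the laser lines used.

Peaks are local maxima of the per-step mean image intensity with prominence
of at least 10 % of the spectrum maximum; each reference line is matched to
its nearest detected peak within a 20 nm ceiling, beyond which the line is
reported absent (the diagnostic signal of a dead spectral slider).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .core import ImageStack
from .profiles import IntensityProfile, peak_and_fwhm

__all__ = [
    "SpectralPeak",
    "LineMatch",
    "SpectralResponse",
    "lambda_response",
    "PROMINENCE_FRACTION",
    "MATCH_CEILING_NM",
]

PROMINENCE_FRACTION = 0.10
MATCH_CEILING_NM = 20.0
MIN_STEPS = 20


@dataclass
class SpectralPeak:
    wavelength: float    # nm
    intensity: float     # counts
    fwhm: float          # nm (nan when the local width is unmeasurable)
    merged: bool = False  # matched by more than one reference line


@dataclass
class LineMatch:
    line_nm: float
    peak_index: Optional[int]   # into SpectralResponse.peaks, None if absent
    offset_nm: float            # peak - line, nan if absent
    absent: bool


@dataclass
class SpectralResponse:
    detector_id: str
    wavelengths: np.ndarray
    mean_intensities: np.ndarray
    peaks: List[SpectralPeak]
    reference_lines: List[float]
    matches: List[LineMatch] = field(default_factory=list)


def _local_fwhm(wl: np.ndarray, spectrum: np.ndarray, peak_idx: int,
                minima: np.ndarray) -> float:
    """FWHM of one peak measured between its flanking local minima."""
    left = minima[minima < peak_idx]
    right = minima[minima > peak_idx]
    lo = int(left.max()) if len(left) else 0
    hi = int(right.min()) if len(right) else len(wl) - 1
    # peak_and_fwhm needs >= 5 samples; widen symmetrically if needed
    while hi - lo + 1 < 5 and (lo > 0 or hi < len(wl) - 1):
        lo = max(0, lo - 1)
        hi = min(len(wl) - 1, hi + 1)
    stats = peak_and_fwhm(IntensityProfile(wl[lo:hi + 1], spectrum[lo:hi + 1],
                                           unit="nm"))
    return stats.fwhm if stats.has_peak else math.nan


def lambda_response(series: ImageStack, detector_id: str,
                    reference_lines: Sequence[float],
                    prominence_fraction: float = PROMINENCE_FRACTION,
                    match_ceiling_nm: float = MATCH_CEILING_NM,
                    ) -> SpectralResponse:
    """Detect reflection peaks in a lambda scan and match the laser lines."""
    if series.wavelength_axis is None:
        raise ValueError("lambda scan requires a wavelength_axis in the sidecar")
    wl = np.asarray(series.wavelength_axis, dtype=float)
    if len(wl) < MIN_STEPS:
        raise ValueError(f"need >= {MIN_STEPS} wavelength steps, got {len(wl)}")
    if not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength_axis must be strictly increasing")
    spectrum = series.pixels[:, 0, 0].astype(float).mean(axis=(1, 2))

    span = float(spectrum.max() - spectrum.min())
    peaks: List[SpectralPeak] = []
    if span > 0:
        floor = prominence_fraction * float(spectrum.max())
        idx, _ = find_peaks(spectrum, prominence=floor)
        minima, _ = find_peaks(-spectrum)
        for p in idx:
            peaks.append(SpectralPeak(
                wavelength=float(wl[p]),
                intensity=float(spectrum[p]),
                fwhm=_local_fwhm(wl, spectrum, int(p), minima),
            ))

    matches: List[LineMatch] = []
    hit_counts = [0] * len(peaks)
    for line in reference_lines:
        if peaks:
            dists = [abs(pk.wavelength - line) for pk in peaks]
            best = int(np.argmin(dists))
            if dists[best] <= match_ceiling_nm:
                hit_counts[best] += 1
                matches.append(LineMatch(float(line), best,
                                         peaks[best].wavelength - line,
                                         absent=False))
                continue
        matches.append(LineMatch(float(line), None, math.nan, absent=True))
    for i, count in enumerate(hit_counts):
        if count > 1:
            peaks[i].merged = True
    return SpectralResponse(detector_id=detector_id, wavelengths=wl,
                            mean_intensities=spectrum, peaks=peaks,
                            reference_lines=[float(v) for v in reference_lines],
                            matches=matches)
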