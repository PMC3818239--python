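"""1-D intensity profiles: extraction, peak/FWHM measurement, Gaussian fitting.

Shared by the axial, field, PSF, spectral and Z-focus assays.

Conventions fixed here once and used everywhere:

* the half-maximum level is measured above the profile minimum
  (baseline-corrected), not above zero — reflection and PSF profiles ride on
  detector offset;
* at equal maxima the lowest position wins (determinism);
* half-level crossings are located by linear interpolation between the
  outermost sample pair straddling the level on each side of the peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FWHM_FACTOR",
    "IntensityProfile",
    "PeakStats",
    "GaussianFit",
    "extract_profile",
    "peak_and_fwhm",
    "fit_gaussian",
]

#: FWHM of a Gaussian of unit sigma.
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass
class IntensityProfile:
    """A 1-D sequence of (position, intensity) samples with a unit tag."""

    positions: np.ndarray
    intensities: np.ndarray
    unit: str = "px"
    averaging_width: int = 1

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("positions and intensities must be 1-D")
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities differ in length")
        if len(self.positions) >= 2 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PeakStats:
    """Peak location and FWHM of a profile; ``has_peak`` is False when the
    profile is monotone or never falls back below the half level."""

    has_peak: bool
    peak_position: float = math.nan
    peak_intensity: float = math.nan
    fwhm: float = math.nan
    half_max_crossings: Optional[Tuple[float, float]] = None
    half_level: float = math.nan


@dataclass
class GaussianFit:
    """Least-squares Gaussian model ``A exp(-(x-µ)²/(2σ²)) + B``."""

    amplitude: float
    mean: float
    sigma: float
    baseline: float
    rss: float
    converged: bool

    @property
    def fwhm(self) -> float:
        return FWHM_FACTOR * self.sigma


def extract_profile(image, axis: str, center_index: int, averaging_width: int,
                    spacing: float = 1.0, unit: str = "px") -> IntensityProfile:
    """Read a line profile from a 2-D raster, averaging orthogonally.

    ``axis="horizontal"`` profiles along columns averaging over a band of
    rows centred on ``center_index``; ``axis="vertical"`` profiles along rows
    averaging over a band of columns.  The band is
    ``[center_index - w//2, center_index - w//2 + w)`` clipped to the image.
    With ``averaging_width=1`` this is exactly the raw line read-out.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D raster, got {image.ndim}-D")
    if averaging_width < 1:
        raise ValueError("averaging_width must be >= 1")
    if axis == "horizontal":
        extent = image.shape[0]
    elif axis == "vertical":
        extent = image.shape[1]
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    if averaging_width > extent:
        raise ValueError(
            f"averaging_width {averaging_width} exceeds image extent {extent}"
        )
    lo = max(0, center_index - averaging_width // 2)
    hi = min(extent, lo + averaging_width)
    lo = max(0, hi - averaging_width)
    if axis == "horizontal":
        values = image[lo:hi, :].mean(axis=0)
    else:
        values = image[:, lo:hi].mean(axis=1)
    positions = np.arange(len(values), dtype=float) * spacing
    return IntensityProfile(positions, values.astype(float), unit=unit,
                            averaging_width=averaging_width)


def _interp_crossing(p0, i0, p1, i1, level) -> float:
    if i1 == i0:
        return p1
    return p0 + (level - i0) / (i1 - i0) * (p1 - p0)


def peak_and_fwhm(profile: IntensityProfile) -> PeakStats:
    """Locate the profile maximum and its full width at half maximum.

    The peak is the maximum sample (ties broken towards the lowest
    position); the half level is ``min + (max - min)/2``; crossings are
    linearly interpolated between the outermost straddling sample pair on
    each side of the peak.  Profiles with the maximum on a boundary, or
    that never cross the half level on one side, yield ``has_peak=False``
    rather than an exception.
    """
    n = len(profile)
    if n < 5:
        raise ValueError(f"need at least 5 samples, got {n}")
    x = profile.positions
    y = profile.intensities
    idx = int(np.argmax(y))
    baseline = float(np.min(y))
    peak = float(y[idx])
    if idx == 0 or idx == n - 1 or peak == baseline:
        return PeakStats(has_peak=False)
    half = baseline + (peak - baseline) / 2.0

    left = None
    for i in range(idx):  # outermost pair first
        if y[i] <= half <= y[i + 1]:
            left = _interp_crossing(x[i], y[i], x[i + 1], y[i + 1], half)
            break
    right = None
    for j in range(n - 1, idx, -1):
        if y[j] <= half <= y[j - 1]:
            right = _interp_crossing(x[j - 1], y[j - 1], x[j], y[j], half)
            break
    if left is None or right is None:
        return PeakStats(has_peak=False, peak_position=float(x[idx]),
                         peak_intensity=peak, half_level=half)
    return PeakStats(
        has_peak=True,
        peak_position=float(x[idx]),
        peak_intensity=peak,
        fwhm=float(right - left),
        half_max_crossings=(float(left), float(right)),
        half_level=half,
    )


def _gauss(x, amplitude, mean, sigma, baseline):
    return amplitude * np.exp(-((x - mean) ** 2) / (2.0 * sigma ** 2)) + baseline


def _moment_estimate(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    baseline = float(np.min(y))
    w = np.clip(y - baseline, 0.0, None)
    total = float(w.sum())
    if total <= 0:
        mid = float(x[len(x) // 2])
        return 0.0, mid, float((x[-1] - x[0]) / 4.0) or 1.0, baseline
    mean = float((w * x).sum() / total)
    var = float((w * (x - mean) ** 2).sum() / total)
    sigma = math.sqrt(var) if var > 0 else float(x[1] - x[0])
    return float(np.max(y) - baseline), mean, sigma, baseline


def fit_gaussian(profile: IntensityProfile, max_iterations: int = 2000) -> GaussianFit:
    """Fit ``A exp(-(x-µ)²/(2σ²)) + B`` by least squares.

    Initialised from :func:`peak_and_fwhm` (µ ← peak position,
    σ ← FWHM/2.355, B ← min).  When the profile has no detectable peak or
    the optimiser fails to converge, the result carries moment-based
    estimates and ``converged=False``.
    """
    n = len(profile)
    if n < 7:
        raise ValueError(f"need at least 7 samples, got {n}")
    x = profile.positions
    y = profile.intensities
    stats = peak_and_fwhm(profile)
    amp_m, mean_m, sigma_m, base_m = _moment_estimate(x, y)

    def _failed() -> GaussianFit:
        resid = y - _gauss(x, amp_m, mean_m, sigma_m, base_m)
        return GaussianFit(amp_m, mean_m, sigma_m, base_m,
                           float((resid ** 2).sum()), converged=False)

    if not stats.has_peak:
        return _failed()
    baseline0 = float(np.min(y))
    p0 = [stats.peak_intensity - baseline0, stats.peak_position,
          stats.fwhm / FWHM_FACTOR if math.isfinite(stats.fwhm) else sigma_m,
          baseline0]
    if p0[2] <= 0:
        p0[2] = sigma_m or 1.0
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=p0, maxfev=max_iterations,
            bounds=([0.0, x[0] - (x[-1] - x[0]), 1e-12, -np.inf],
                    [np.inf, x[-1] + (x[-1] - x[0]), np.inf, np.inf]),
        )
    except (RuntimeError, ValueError):
        return _failed()
    amplitude, mean, sigma, baseline = (float(v) for v in popt)
    resid = y - _gauss(x, amplitude, mean, sigma, baseline)
    return GaussianFit(amplitude, mean, abs(sigma), baseline,
                       float((resid ** 2).sum()), converged=True)
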