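"""Seeded synthetic recordings with known ground truth for every assay.

Each generator emulates one acquisition kind — transmitted-light time
lapses, XZ mirror-reflection bands, flat-field slides, multi-colour bead
stacks, sub-resolution PSF beads, lambda scans, grid slides and stage bead
series — and returns an :class:`~scopeqc.core.ImageStack` together with a
:class:`FixtureTruth` recording the generating parameters.  Regenerating
with identical (kind, parameters, seed) is bit-identical.

Noise model: Gaussian read noise plus an optional signal-scaled
(shot-like) component; intensities are clipped to the bit depth and
quantised to uint16.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .core import ImageStack, write_stack

__all__ = ["FixtureTruth", "generate_fixture", "write_demo_dataset",
           "fixture_kinds", "DEMO_CONFIG"]


@dataclass
class FixtureTruth:
    kind: str
    parameters: dict
    seed: int


def _quantise(values: np.ndarray, bit_depth: int) -> np.ndarray:
    return np.clip(np.round(values), 0, 2 ** bit_depth - 1).astype(np.uint16)


def _add_noise(rng: np.random.Generator, signal: np.ndarray,
               read_sd: float, shot_cv: float) -> np.ndarray:
    noisy = signal.astype(float)
    if read_sd > 0:
        noisy = noisy + rng.normal(0.0, read_sd, size=signal.shape)
    if shot_cv > 0:
        noisy = noisy * (1.0 + rng.normal(0.0, shot_cv, size=signal.shape))
    return noisy


def _merge(defaults: dict, overrides: Optional[dict]) -> dict:
    merged = dict(defaults)
    if overrides:
        unknown = set(overrides) - set(defaults)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}; "
                             f"valid: {sorted(defaults)}")
        merged.update(overrides)
    return merged


# ---------------------------------------------------------------------------
# laser: constant transmitted-light frames + noise + optional drift
# ---------------------------------------------------------------------------

_LASER_DEFAULTS = dict(
    n_frames=120, height=64, width=64, level=1000.0,
    read_noise_sd=0.0, shot_cv=0.0,
    drift="none",            # none | linear | sine
    drift_rate=0.0,          # counts/s for linear
    amplitude=0.0,           # counts for sine
    period_s=600.0,
    frame_interval_s=20.0, bit_depth=16, wavelength_nm=488.0,
)


def _make_laser(params: dict, rng: np.random.Generator) -> ImageStack:
    t = params["n_frames"]
    times = np.arange(t) * params["frame_interval_s"]
    levels = np.full(t, params["level"], dtype=float)
    if params["drift"] == "linear":
        levels = levels + params["drift_rate"] * times
    elif params["drift"] == "sine":
        levels = levels + params["amplitude"] * np.sin(
            2.0 * np.pi * times / params["period_s"])
    elif params["drift"] != "none":
        raise ValueError(f"unknown drift mode {params['drift']!r}")
    frames = np.broadcast_to(
        levels[:, None, None], (t, params["height"], params["width"])).copy()
    frames = _add_noise(rng, frames, params["read_noise_sd"], params["shot_cv"])
    pixels = _quantise(frames, params["bit_depth"])[:, None, None]
    return ImageStack(pixels=pixels, pixel_size_xy=1.0,
                      frame_interval=params["frame_interval_s"],
                      channel_wavelengths=[params["wavelength_nm"]],
                      bit_depth=params["bit_depth"])


# ---------------------------------------------------------------------------
# axial / zgalvo: Gaussian reflection bands in Z
# ---------------------------------------------------------------------------

_AXIAL_DEFAULTS = dict(
    wavelengths_nm=(488.0, 561.0, 633.0),
    peak_z_um=(5.0, 5.2, 5.35),
    sigma_z_um=0.25, z_step_um=0.02, n_z=501, n_x=64,
    amplitude=3000.0, baseline=50.0, read_noise_sd=0.0, bit_depth=16,
)


def _band(z_um: np.ndarray, centre: float, sigma: float,
          amplitude: float, baseline: float) -> np.ndarray:
    return amplitude * np.exp(-((z_um - centre) ** 2) / (2.0 * sigma ** 2)) + baseline


def _make_axial(params: dict, rng: np.random.Generator) -> ImageStack:
    wavelengths = list(params["wavelengths_nm"])
    peaks = list(params["peak_z_um"])
    if len(peaks) != len(wavelengths):
        raise ValueError("peak_z_um must have one entry per wavelength")
    z = np.arange(params["n_z"]) * params["z_step_um"]
    planes = []
    for centre in peaks:
        column = _band(z, centre, params["sigma_z_um"],
                       params["amplitude"], params["baseline"])
        planes.append(np.repeat(column[:, None], params["n_x"], axis=1))
    volume = np.stack(planes)  # (c, z, x)
    volume = _add_noise(rng, volume, params["read_noise_sd"], 0.0)
    pixels = _quantise(volume, params["bit_depth"])[None, :, :, None, :]
    return ImageStack(pixels=pixels, pixel_size_xy=0.1,
                      z_step=params["z_step_um"],
                      channel_wavelengths=wavelengths,
                      bit_depth=params["bit_depth"])


_ZGALVO_DEFAULTS = dict(
    n_frames=60, frame_interval_s=2.0, z0_um=3.0,
    drift_um_per_s=0.0, sigma_z_um=0.25, width_jitter_sd_um=0.0,
    z_step_um=0.02, n_z=401, n_x=64,
    amplitude=3000.0, baseline=50.0, read_noise_sd=0.0, bit_depth=16,
    wavelength_nm=488.0,
)


def _make_zgalvo(params: dict, rng: np.random.Generator) -> ImageStack:
    z = np.arange(params["n_z"]) * params["z_step_um"]
    frames = []
    for k in range(params["n_frames"]):
        centre = params["z0_um"] + params["drift_um_per_s"] * k * params["frame_interval_s"]
        sigma = params["sigma_z_um"]
        if params["width_jitter_sd_um"] > 0:
            sigma = max(1e-3, sigma + rng.normal(0.0, params["width_jitter_sd_um"]))
        column = _band(z, centre, sigma, params["amplitude"], params["baseline"])
        frames.append(np.repeat(column[:, None], params["n_x"], axis=1))
    volume = np.stack(frames)  # (t, z, x)
    volume = _add_noise(rng, volume, params["read_noise_sd"], 0.0)
    pixels = _quantise(volume, params["bit_depth"])[:, None, :, None, :]
    return ImageStack(pixels=pixels, pixel_size_xy=0.1,
                      z_step=params["z_step_um"],
                      frame_interval=params["frame_interval_s"],
                      channel_wavelengths=[params["wavelength_nm"]],
                      bit_depth=params["bit_depth"])


# ---------------------------------------------------------------------------
# field: flat-field frame (uniform / vignette / ramp)
# ---------------------------------------------------------------------------

_FIELD_DEFAULTS = dict(
    size=128, mode="vignette",      # uniform | vignette | ramp
    peak=3000.0, vignette_sigma_px=96.0,
    ramp_low=100.0, ramp_high=200.0,
    read_noise_sd=0.0, bit_depth=16, wavelength_nm=405.0,
)


def _make_field(params: dict, rng: np.random.Generator) -> ImageStack:
    n = params["size"]
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    if params["mode"] == "uniform":
        frame = np.full((n, n), params["peak"], dtype=float)
    elif params["mode"] == "vignette":
        cy = cx = (n - 1) / 2.0
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        frame = params["peak"] * np.exp(-r2 / (2.0 * params["vignette_sigma_px"] ** 2))
    elif params["mode"] == "ramp":
        frame = params["ramp_low"] + (params["ramp_high"] - params["ramp_low"]) \
            * xx / (n - 1)
    else:
        raise ValueError(f"unknown field mode {params['mode']!r}")
    frame = _add_noise(rng, frame, params["read_noise_sd"], 0.0)
    pixels = _quantise(frame, params["bit_depth"])[None, None, None]
    return ImageStack(pixels=pixels, pixel_size_xy=0.5,
                      channel_wavelengths=[params["wavelength_nm"]],
                      bit_depth=params["bit_depth"])


# ---------------------------------------------------------------------------
# bead / psf: 3-D Gaussian blobs with sub-voxel offsets
# ---------------------------------------------------------------------------

_BEAD_DEFAULTS = dict(
    wavelengths_nm=(405.0, 488.0, 561.0, 633.0),
    offsets_um=((0.0, 0.0, 0.0),) * 4,     # per-channel (dx, dy, dz)
    sigma_um=(0.3, 0.3, 0.4),              # (x, y, z)
    voxel_um=(0.03, 0.03, 0.15),           # (x, y, z)
    shape=(21, 64, 64),                    # (z, y, x)
    amplitude=3000.0, baseline=20.0, read_noise_sd=0.0, bit_depth=16,
    n_beads=1, second_bead_offset_um=(1.2, 1.2, 0.0),
)


def _gaussian_blob(shape, centre_um, sigma_um, voxel_um) -> np.ndarray:
    nz, ny, nx = shape
    z = np.arange(nz) * voxel_um[2]
    y = np.arange(ny) * voxel_um[1]
    x = np.arange(nx) * voxel_um[0]
    gz = np.exp(-((z - centre_um[2]) ** 2) / (2.0 * sigma_um[2] ** 2))
    gy = np.exp(-((y - centre_um[1]) ** 2) / (2.0 * sigma_um[1] ** 2))
    gx = np.exp(-((x - centre_um[0]) ** 2) / (2.0 * sigma_um[0] ** 2))
    return gz[:, None, None] * gy[None, :, None] * gx[None, None, :]


def _make_bead(params: dict, rng: np.random.Generator) -> ImageStack:
    shape = tuple(params["shape"])
    voxel = tuple(params["voxel_um"])
    sigma = tuple(params["sigma_um"])
    offsets = list(params["offsets_um"])
    wavelengths = list(params["wavelengths_nm"])
    if len(offsets) != len(wavelengths):
        raise ValueError("offsets_um must have one entry per wavelength")
    nz, ny, nx = shape
    base = ((nx - 1) / 2.0 * voxel[0], (ny - 1) / 2.0 * voxel[1],
            (nz - 1) / 2.0 * voxel[2])
    channels = []
    for (dx, dy, dz) in offsets:
        centre = (base[0] + dx, base[1] + dy, base[2] + dz)
        blob = params["amplitude"] * _gaussian_blob(shape, centre, sigma, voxel)
        for k in range(1, params["n_beads"]):
            ox, oy, oz = params["second_bead_offset_um"]
            extra = (centre[0] + k * ox, centre[1] + k * oy, centre[2] + k * oz)
            blob = blob + params["amplitude"] * _gaussian_blob(
                shape, extra, sigma, voxel)
        channels.append(blob + params["baseline"])
    volume = np.stack(channels)  # (c, z, y, x)
    volume = _add_noise(rng, volume, params["read_noise_sd"], 0.0)
    pixels = _quantise(volume, params["bit_depth"])[None]
    return ImageStack(pixels=pixels, pixel_size_xy=voxel[0],
                      z_step=voxel[2], channel_wavelengths=wavelengths,
                      bit_depth=params["bit_depth"])


_PSF_DEFAULTS = dict(
    sigma_um=(0.1, 0.1, 0.3),
    voxel_um=(0.03, 0.03, 0.15),
    shape=(25, 64, 64),
    centre_offset_um=(0.0, 0.0, 0.0),
    amplitude=4000.0, baseline=20.0, read_noise_sd=0.0, bit_depth=16,
    wavelength_nm=488.0,
)


def _make_psf(params: dict, rng: np.random.Generator) -> ImageStack:
    bead_params = _merge(_BEAD_DEFAULTS, dict(
        wavelengths_nm=(params["wavelength_nm"],),
        offsets_um=(tuple(params["centre_offset_um"]),),
        sigma_um=tuple(params["sigma_um"]),
        voxel_um=tuple(params["voxel_um"]),
        shape=tuple(params["shape"]),
        amplitude=params["amplitude"], baseline=params["baseline"],
        read_noise_sd=params["read_noise_sd"], bit_depth=params["bit_depth"],
    ))
    return _make_bead(bead_params, rng)


# ---------------------------------------------------------------------------
# scanpmt: lambda-scan spectrum of Gaussian reflection peaks
# ---------------------------------------------------------------------------

_SCANPMT_DEFAULTS = dict(
    start_nm=470.0, step_nm=2.0, n_steps=101,
    peaks=((488.0, 2500.0, 4.0), (561.0, 2200.0, 4.0), (633.0, 1800.0, 4.0)),
    baseline=10.0, frame_size=8, read_noise_sd=0.0, bit_depth=16,
)


def _make_scanpmt(params: dict, rng: np.random.Generator) -> ImageStack:
    wl = params["start_nm"] + params["step_nm"] * np.arange(params["n_steps"])
    spectrum = np.full(len(wl), params["baseline"], dtype=float)
    for centre, amp, sigma in params["peaks"]:
        spectrum = spectrum + amp * np.exp(-((wl - centre) ** 2)
                                           / (2.0 * sigma ** 2))
    n = params["frame_size"]
    frames = np.broadcast_to(spectrum[:, None, None], (len(wl), n, n)).copy()
    frames = _add_noise(rng, frames, params["read_noise_sd"], 0.0)
    pixels = _quantise(frames, params["bit_depth"])[:, None, None]
    return ImageStack(pixels=pixels, pixel_size_xy=1.0,
                      channel_wavelengths=[0.0],
                      wavelength_axis=[float(v) for v in wl],
                      bit_depth=params["bit_depth"])


# ---------------------------------------------------------------------------
# grid: reflective square grid pattern
# ---------------------------------------------------------------------------

_GRID_DEFAULTS = dict(
    size=256, pitch_px=32, line_width_px=3,
    line_level=3000.0, background=100.0,
    read_noise_sd=0.0, bit_depth=16, wavelength_nm=488.0,
)


def _make_grid(params: dict, rng: np.random.Generator) -> ImageStack:
    n = params["size"]
    frame = np.full((n, n), params["background"], dtype=float)
    half = params["line_width_px"] // 2
    for start in range(0, n, params["pitch_px"]):
        lo = max(0, start - half)
        hi = min(n, start + half + 1)
        frame[lo:hi, :] = params["line_level"]
        frame[:, lo:hi] = params["line_level"]
    frame = _add_noise(rng, frame, params["read_noise_sd"], 0.0)
    pixels = _quantise(frame, params["bit_depth"])[None, None, None]
    return ImageStack(pixels=pixels, pixel_size_xy=1.0,
                      channel_wavelengths=[params["wavelength_nm"]],
                      bit_depth=params["bit_depth"])


# ---------------------------------------------------------------------------
# stage / stageacc: 2-D Gaussian bead at commanded-plus-error positions
# ---------------------------------------------------------------------------

_STAGE_DEFAULTS = dict(
    n_frames=100, height=96, width=96, pixel_size_um=0.1,
    bead_sigma_um=0.3, base_position_px=None,   # default: frame centre
    jitter_sd_um=0.0, bleach_tau_s=0.0,
    amplitude=3000.0, baseline=10.0, read_noise_sd=0.0,
    frame_interval_s=1.0, bit_depth=16, wavelength_nm=633.0,
    cluster_offsets_um=None,  # optional list of per-frame (dx, dy) offsets
)


def _render_bead_frame(shape, centre_px, sigma_px, amplitude, baseline):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    r2 = ((xx - centre_px[0]) ** 2 + (yy - centre_px[1]) ** 2)
    return amplitude * np.exp(-r2 / (2.0 * sigma_px ** 2)) + baseline


def _make_stage(params: dict, rng: np.random.Generator) -> ImageStack:
    t = params["n_frames"]
    px = params["pixel_size_um"]
    shape = (params["height"], params["width"])
    base = params["base_position_px"] or ((shape[1] - 1) / 2.0,
                                          (shape[0] - 1) / 2.0)
    sigma_px = params["bead_sigma_um"] / px
    jitter_px = params["jitter_sd_um"] / px
    frames = []
    for k in range(t):
        cx, cy = base
        if params["cluster_offsets_um"] is not None:
            ox, oy = params["cluster_offsets_um"][k % len(params["cluster_offsets_um"])]
            cx += ox / px
            cy += oy / px
        if jitter_px > 0:
            cx += rng.normal(0.0, jitter_px)
            cy += rng.normal(0.0, jitter_px)
        amp = params["amplitude"]
        if params["bleach_tau_s"] > 0:
            amp *= np.exp(-k * params["frame_interval_s"] / params["bleach_tau_s"])
        frames.append(_render_bead_frame(shape, (cx, cy), sigma_px, amp,
                                         params["baseline"]))
    volume = np.stack(frames)
    volume = _add_noise(rng, volume, params["read_noise_sd"], 0.0)
    pixels = _quantise(volume, params["bit_depth"])[:, None, None]
    positions = [(0.0, 0.0)] * t
    return ImageStack(pixels=pixels, pixel_size_xy=px,
                      frame_interval=params["frame_interval_s"],
                      channel_wavelengths=[params["wavelength_nm"]],
                      stage_positions=positions,
                      bit_depth=params["bit_depth"])


_STAGEACC_DEFAULTS = dict(
    commanded_positions_um=((0.0, 0.0), (10.0, 0.0)),  # visited cyclically
    n_visits=12, height=160, width=160, pixel_size_um=0.1,
    bead_sigma_um=0.3, execution_scale=1.0, jitter_sd_um=0.0,
    amplitude=3000.0, baseline=10.0, read_noise_sd=0.0,
    frame_interval_s=1.0, bit_depth=16, wavelength_nm=633.0,
    axes_sign=(-1, -1), metadata_axes_sign=None,  # override to corrupt metadata
)


def _make_stageacc(params: dict, rng: np.random.Generator) -> ImageStack:
    px = params["pixel_size_um"]
    shape = (params["height"], params["width"])
    pattern = [np.asarray(p, dtype=float)
               for p in params["commanded_positions_um"]]
    commanded = [pattern[k % len(pattern)] for k in range(params["n_visits"])]
    sign = np.asarray(params["axes_sign"], dtype=float)
    # keep the bead inside the frame over the whole commanded range
    image_offsets = [sign * (c - commanded[0]) * params["execution_scale"]
                     for c in commanded]
    off_px = np.array(image_offsets) / px
    base_x = (shape[1] - 1) / 2.0 - (off_px[:, 0].max() + off_px[:, 0].min()) / 2.0
    base_y = (shape[0] - 1) / 2.0 - (off_px[:, 1].max() + off_px[:, 1].min()) / 2.0
    jitter_px = params["jitter_sd_um"] / px
    frames = []
    for k in range(params["n_visits"]):
        cx = base_x + off_px[k, 0]
        cy = base_y + off_px[k, 1]
        if jitter_px > 0:
            cx += rng.normal(0.0, jitter_px)
            cy += rng.normal(0.0, jitter_px)
        frames.append(_render_bead_frame(shape, (cx, cy),
                                         params["bead_sigma_um"] / px,
                                         params["amplitude"],
                                         params["baseline"]))
    volume = _add_noise(rng, np.stack(frames), params["read_noise_sd"], 0.0)
    pixels = _quantise(volume, params["bit_depth"])[:, None, None]
    meta_sign = params["metadata_axes_sign"] or params["axes_sign"]
    return ImageStack(pixels=pixels, pixel_size_xy=px,
                      frame_interval=params["frame_interval_s"],
                      channel_wavelengths=[params["wavelength_nm"]],
                      stage_positions=[tuple(c) for c in commanded],
                      bit_depth=params["bit_depth"],
                      axes_sign=tuple(meta_sign))


# ---------------------------------------------------------------------------

_GENERATORS: Dict[str, Tuple[dict, Callable]] = {
    "laser": (_LASER_DEFAULTS, _make_laser),
    "axial": (_AXIAL_DEFAULTS, _make_axial),
    "zgalvo": (_ZGALVO_DEFAULTS, _make_zgalvo),
    "field": (_FIELD_DEFAULTS, _make_field),
    "bead": (_BEAD_DEFAULTS, _make_bead),
    "psf": (_PSF_DEFAULTS, _make_psf),
    "scanpmt": (_SCANPMT_DEFAULTS, _make_scanpmt),
    "grid": (_GRID_DEFAULTS, _make_grid),
    "stage": (_STAGE_DEFAULTS, _make_stage),
    "stageacc": (_STAGEACC_DEFAULTS, _make_stageacc),
}


def fixture_kinds():
    return sorted(_GENERATORS)


def generate_fixture(kind: str, parameters: Optional[dict] = None,
                     seed: int = 0) -> Tuple[ImageStack, FixtureTruth]:
    """Generate one synthetic recording with its ground truth."""
    if kind not in _GENERATORS:
        raise ValueError(
            f"unknown fixture kind {kind!r}; valid kinds: "
            f"{', '.join(fixture_kinds())}"
        )
    defaults, maker = _GENERATORS[kind]
    params = _merge(defaults, parameters)
    rng = np.random.default_rng(seed)
    stack = maker(params, rng)
    return stack, FixtureTruth(kind=kind, parameters=params, seed=seed)


DEMO_CONFIG = """# demo system configuration
system=DemoScope
objectives=10x
lasers.field=405,488
lasers.axial405=405,488,561
lasers.axial488=488,561,633
lasers.scan=488,561,633
"""


def write_demo_dataset(out_dir, seed: int = 0) -> Path:
    """Write a complete synthetic dataset directory (all keywords) plus a
    matching configuration file.  Returns the objective directory."""
    out_dir = Path(out_dir)
    obj_dir = out_dir / "10x"
    obj_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "scopeqc_config.txt").write_text(DEMO_CONFIG)

    rng = np.random.default_rng(seed)
    seeds = {name: int(rng.integers(0, 2 ** 31)) for name in (
        "laser", "axial405", "axial488", "field405", "field488", "bead",
        "psf", "scanpmt1", "scanpmt2", "grid", "stage1", "stage2", "stage3",
        "stageacc", "zgalvo")}

    def emit(name, kind, params=None):
        stack, _ = generate_fixture(kind, params, seed=seeds[name])
        write_stack(stack, obj_dir / f"{name}.tif")

    emit("laser", "laser", dict(read_noise_sd=3.0, drift="sine",
                                amplitude=20.0, period_s=1200.0))
    emit("axial405", "axial", dict(wavelengths_nm=(405.0, 488.0, 561.0),
                                   peak_z_um=(4.9, 5.05, 5.12),
                                   read_noise_sd=5.0))
    emit("axial488", "axial", dict(wavelengths_nm=(488.0, 561.0, 633.0),
                                   peak_z_um=(5.05, 5.12, 5.3),
                                   read_noise_sd=5.0))
    emit("field405", "field", dict(mode="vignette", wavelength_nm=405.0,
                                   read_noise_sd=5.0))
    emit("field488", "field", dict(mode="vignette", vignette_sigma_px=120.0,
                                   wavelength_nm=488.0, read_noise_sd=5.0))
    emit("bead", "bead", dict(offsets_um=((0.0, 0.0, 0.0),
                                          (0.06, -0.03, 0.15),
                                          (0.03, 0.06, 0.15),
                                          (-0.06, 0.03, 0.3)),
                              read_noise_sd=5.0))
    emit("psf", "psf", dict(read_noise_sd=5.0))
    emit("scanpmt1", "scanpmt", dict(read_noise_sd=2.0))
    emit("scanpmt2", "scanpmt",
         dict(peaks=((490.0, 2000.0, 5.0), (562.0, 1900.0, 5.0),
                     (633.0, 1500.0, 5.0)),
              read_noise_sd=2.0))
    emit("grid", "grid", dict(read_noise_sd=10.0))
    for k in (1, 2, 3):
        name = f"stage{k}"
        stack, _ = generate_fixture(
            "stage", dict(jitter_sd_um=0.3, read_noise_sd=3.0, n_frames=40),
            seed=seeds[name])
        write_stack(stack, obj_dir / f"{name}.tif")
    for k in (1, 2, 3):
        stack, _ = generate_fixture(
            "stageacc",
            dict(commanded_positions_um=((0.0, 0.0), (10.0, 0.0),
                                         (10.0, 10.0)),
                 execution_scale=0.98, n_visits=9, read_noise_sd=3.0),
            seed=seeds["stageacc"] + k)
        write_stack(stack, obj_dir / f"stageacc{k}.tif")
    emit("zgalvo", "zgalvo", dict(drift_um_per_s=0.002, read_noise_sd=5.0,
                                  n_frames=40))
    return obj_dir
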